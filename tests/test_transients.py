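"""SWR and HSE detection: thresholds, merge rules, channel selection,
overlap statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from lmaze import (
    HSEDetectorConfig,
    SWRDetectorConfig,
    detect_hses,
    detect_swrs,
    merge_candidates,
    overlap_summary,
    select_swr_channel,
)
from lmaze.core import LFPSignal
from tests.conftest import overlap_hits

FS = 1000.0


def ripple_signal(bursts, duration=60.0, z_amp=6.0, seed=0, freq=200.0,
                  envelope="tukey"):
    """Pink-ish noise with ripple bursts at given (t0, dur) pairs, calibrated
    so burst envelope peaks ~z_amp SDs above the mean."""
    rng = np.random.default_rng(seed)
    n = int(duration * FS)
    freqs = np.fft.rfftfreq(n, 1 / FS)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -1.0
    x = np.fft.irfft(amp * np.exp(1j * rng.uniform(0, 2 * np.pi, len(freqs))), n)
    x *= 30.0 / x.std()
    x += rng.normal(0, 4.0, n)
    ny = FS / 2
    b, a = sps.butter(4, [150 / ny, 250 / ny], btype="bandpass")
    env = np.abs(sps.hilbert(sps.filtfilt(b, a, x)))
    amp_uv = env.mean() + z_amp * env.std()
    for t0, dur in bursts:
        i0, i1 = int(t0 * FS), int((t0 + dur) * FS)
        m = i1 - i0
        tone = np.sin(2 * np.pi * freq * np.arange(m) / FS)
        win = sps.windows.tukey(m, 0.5) if envelope == "tukey" else np.ones(m)
        x[i0:i1] += amp_uv * win * tone
    return x


class TestMergeRules:
    def test_end_start_gap_under_5ms_merges(self):
        out = merge_candidates([[0.0, 0.025], [0.028, 0.053]], 0.005, 0.020)
        assert out == [[0.0, 0.053]]

    def test_start_start_gap_under_20ms_merges(self):
        out = merge_candidates([[0.0, 0.004], [0.015, 0.030]], 0.005, 0.020)
        assert out == [[0.0, 0.030]]

    def test_distant_events_stay_separate(self):
        out = merge_candidates([[0.0, 0.02], [0.1, 0.12]], 0.005, 0.020)
        assert len(out) == 2

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 10), st.floats(0.001, 0.1)),
                    min_size=1, max_size=12))
    def test_merge_is_idempotent_and_order_independent(self, raw):
        iv = [[s, s + d] for s, d in raw]
        merged = merge_candidates(iv, 0.005, 0.020)
        assert merge_candidates(merged, 0.005, 0.020) == merged
        assert merge_candidates(iv[::-1], 0.005, 0.020) == merged


class TestSWRDetection:
    def test_noise_alone_yields_no_events(self):
        x = ripple_signal([], duration=60.0, seed=1)
        assert len(detect_swrs(x, fs=FS)) == 0

    def test_single_burst_detected_with_overlap(self):
        x = ripple_signal([(30.0, 0.05)], seed=2)
        events = detect_swrs(x, fs=FS)
        assert len(events) == 1
        s, e = events.iloc[0][["t_start", "t_end"]]
        inter = min(e, 30.05) - max(s, 30.0)
        union = max(e, 30.05) - min(s, 30.0)
        assert inter / union >= 0.5

    def test_sub_20ms_burst_rejected(self):
        x = ripple_signal([(30.0, 0.015)], seed=3)
        assert len(detect_swrs(x, fs=FS)) == 0

    def test_bursts_split_by_3ms_gap_are_merged(self):
        """Two 25 ms ripple bursts with a 3 ms silent gap come out as one
        merged event spanning both."""
        x = ripple_signal([], seed=4)
        ny = FS / 2
        b, a = sps.butter(4, [150 / ny, 250 / ny], btype="bandpass")
        env = np.abs(sps.hilbert(sps.filtfilt(b, a, x)))
        amp = env.mean() + 8 * env.std()
        t = np.arange(len(x)) / FS
        m = (t >= 30.0) & (t < 30.053) & ~((t >= 30.025) & (t < 30.028))
        x[m] += amp * np.sin(2 * np.pi * 200 * t[m])
        events = detect_swrs(x, fs=FS)
        near = events[(events["t_start"] < 30.06) & (events["t_end"] > 30.0)]
        assert len(near) == 1
        assert near.iloc[0]["duration"] > 0.04

    def test_all_durations_exceed_minimum(self):
        x = ripple_signal([(t0, d) for t0, d in
                           zip(np.arange(5, 55, 5.0), ([0.02, 0.04, 0.08] * 4)[:10])],
                          seed=5)
        events = detect_swrs(x, fs=FS)
        assert (events["duration"] > 0.020).all()

    def test_events_are_ordered_and_disjoint(self):
        x = ripple_signal([(t0, 0.06) for t0 in np.arange(5, 55, 2.0)], seed=6)
        ev = detect_swrs(x, fs=FS)
        assert (ev["t_start"].diff().dropna() > 0).all()
        assert (ev["t_start"].to_numpy()[1:] >= ev["t_end"].to_numpy()[:-1]).all()

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_swrs(np.zeros(int(10 * FS)), fs=FS)

    def test_recall_and_precision_on_control_session(self, control_session):
        gt = control_session.ground_truth
        truth = gt.event_windows[gt.event_windows.has_swr]
        events = detect_swrs(control_session.lfp, channel=2)
        recall = overlap_hits(truth, events) / len(truth)
        precision = overlap_hits(events, truth) / len(events)
        assert recall >= 0.9 and precision >= 0.9


class TestHSEDetection:
    def _background(self, n_cells=30, duration=60.0, rate=1.0, seed=0):
        rng = np.random.default_rng(seed)
        return {c: np.sort(rng.uniform(0, duration, rng.poisson(rate * duration)))
                for c in range(n_cells)}

    def _with_burst(self, t0, dur, spikes_per_cell=3, seed=0):
        times = self._background(seed=seed)
        rng = np.random.default_rng(seed + 1)
        for c in times:
            burst = rng.uniform(t0, t0 + dur, spikes_per_cell)
            times[c] = np.sort(np.concatenate([times[c], burst]))
        return times

    def test_single_burst_covered_by_one_event(self):
        times = self._with_burst(30.0, 0.1)
        events = detect_hses(times, duration=60.0)
        hits = events[(events["t_start"] <= 30.1) & (events["t_end"] >= 30.0)]
        assert len(hits) == 1
        assert hits.iloc[0]["n_cells"] >= 25

    def test_10ms_burst_rejected(self):
        """A brief flicker of synchrony: with a 7 ms kernel, its smoothed
        footprint stays under the 20 ms minimum."""
        times = self._background(seed=0)
        rng = np.random.default_rng(1)
        for c in (0, 1):
            times[c] = np.sort(np.concatenate([times[c],
                                               rng.uniform(30.0, 30.01, 1)]))
        events = detect_hses(times, duration=60.0)
        assert not len(events[(events["t_start"] <= 30.05) & (events["t_end"] >= 29.95)])

    def test_900ms_plateau_rejected(self):
        times = self._with_burst(30.0, 0.9, spikes_per_cell=45)
        events = detect_hses(times, duration=60.0)
        long_hits = events[(events["t_start"] <= 30.9) & (events["t_end"] >= 30.0)
                           & (events["duration"] > 0.5)]
        assert not len(long_hits)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            detect_hses({}, duration=10.0)

    def test_counts_invariant_under_time_translation(self):
        times = self._with_burst(20.0, 0.1, seed=5)
        ev1 = detect_hses(times, duration=60.0)
        shifted = {c: v + 100.0 for c, v in times.items()}
        ev2 = detect_hses(shifted, duration=160.0)
        # same bursts, same threshold statistics up to padding zeros: the
        # translated burst is still found
        hits = ev2[(ev2["t_start"] <= 120.1) & (ev2["t_end"] >= 120.0)]
        assert len(hits) == len(ev1[(ev1["t_start"] <= 20.1) & (ev1["t_end"] >= 20.0)])

    def test_recall_and_precision_on_control_session(self, control_session):
        from lmaze import classify_pyramidal
        gt = control_session.ground_truth
        truth = gt.event_windows[gt.event_windows.has_hse]
        pyramidal = classify_pyramidal(control_session.spikes.metrics)
        ids = [int(c) for c in
               control_session.spikes.metrics.loc[pyramidal, "cell_id"]]
        events = detect_hses(control_session.spikes,
                             duration=control_session.trajectory.t[-1],
                             cell_ids=ids)
        recall = overlap_hits(truth, events) / len(truth)
        precision = overlap_hits(events, truth) / len(events)
        assert recall >= 0.9 and precision >= 0.9


class TestChannelSelection:
    def test_bump_channel_wins(self):
        rng = np.random.default_rng(0)
        n = int(120 * FS)
        chans = []
        for c in range(3):
            freqs = np.fft.rfftfreq(n, 1 / FS)
            amp = np.zeros_like(freqs)
            amp[1:] = freqs[1:] ** -1.0
            x = np.fft.irfft(amp * np.exp(1j * rng.uniform(0, 2 * np.pi, len(freqs))), n)
            x *= 30 / x.std()
            chans.append(x)
        t = np.arange(n) / FS
        chans[1] = chans[1] + 3.0 * np.sin(2 * np.pi * 200 * t)
        lfp = LFPSignal(samples=np.array(chans), fs=FS)
        assert select_swr_channel(lfp) == {0: 1}

    def test_single_channel_returned(self):
        rng = np.random.default_rng(1)
        lfp = LFPSignal(samples=rng.normal(0, 10, (1, int(30 * FS))), fs=FS)
        assert select_swr_channel(lfp) == {0: 0}

    def test_identical_channels_tiebreak_to_lowest_id(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 10, int(30 * FS))
        lfp = LFPSignal(samples=np.array([x, x, x]), fs=FS)
        assert select_swr_channel(lfp) == {0: 0}

    def test_designated_generator_channel_selected(self, control_session):
        assert select_swr_channel(control_session.lfp) == {0: 2}

    def test_all_flat_rejected(self):
        lfp = LFPSignal(samples=np.zeros((2, int(10 * FS))), fs=FS)
        with pytest.raises(ValueError):
            select_swr_channel(lfp)


class TestOverlapSummary:
    def _df(self, pairs):
        return pd.DataFrame([{"t_start": s, "t_end": e} for s, e in pairs])

    def test_identical_lists(self):
        ev = self._df([(0, 1), (2, 3)])
        out = overlap_summary(ev, ev.copy())
        assert out["pct_swr_overlapping"] == 100.0
        assert out["pct_hse_overlapping"] == 100.0

    def test_disjoint_lists(self):
        out = overlap_summary(self._df([(0, 1)]), self._df([(5, 6)]))
        assert out["pct_swr_overlapping"] == 0.0
        assert out["pct_hse_overlapping"] == 0.0

    def test_hand_counted_toy(self):
        """3 SWRs of which 2 intersect HSEs; 4 of 5 HSEs intersect SWRs."""
        swrs = self._df([(0.0, 1.0), (10.0, 11.0), (20.0, 21.0)])
        hses = self._df([(0.2, 0.4), (0.6, 0.8), (10.5, 10.7), (10.8, 11.5),
                         (30.0, 31.0)])
        out = overlap_summary(swrs, hses)
        assert out["pct_swr_overlapping"] == pytest.approx(2 / 3 * 100, abs=0.1)
        assert out["pct_hse_overlapping"] == pytest.approx(80.0, abs=0.1)
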