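"""One-step Bayesian decoding: posterior math, gates, zone masses,
HSE cross-decoding, theta half-cycle decoding and matched controls."""

import numpy as np
import pandas as pd
import pytest

from lmaze import (
    ArenaGeometry,
    DecoderConfig,
    TaskConfig,
    TuningBinGrid,
    TuningCurves,
    build_tuning_curves,
    decode_hse_events,
    decode_posterior,
    decode_theta_cycles,
    detect_hses,
    generate_session,
    match_control_cycles,
    zone_mass,
)

GEOM = ArenaGeometry()


def make_curves(A, occupancy=None, floorable=True):
    """Wrap an (n_cells, n_pos) outbound-only rate matrix as TuningCurves."""
    n_cells, n_pos = A.shape
    grid = TuningBinGrid(track_length=float(n_pos) if n_pos != 64 else 111.0,
                         n_pos=n_pos)
    rates = np.full((n_cells, 3, n_pos), 0.011)
    rates[:, 0, :] = A
    occ = occupancy if occupancy is not None else np.ones((3, n_pos))
    return TuningCurves(grid=grid, cell_ids=list(range(n_cells)), rates=rates,
                        occupancy=occ, spike_counts=np.full(n_cells, 100.0))


def brute_force_posterior(counts, A, tau, n_rows=3, floor=0.01):
    """Direct product evaluation of the Poisson-independence posterior over
    an outbound-row grid with flat floor rates on the other rows."""
    n_cells, n_pos = A.shape
    rows = [np.maximum(A, floor)] + [np.full_like(A, max(0.011, floor))] * (n_rows - 1)
    p = []
    for row in rows:
        for x in range(n_pos):
            val = 1.0 / (n_rows * n_pos)
            for i in range(n_cells):
                val *= row[i, x] ** counts[i]
            val /= np.exp(tau * row[:, x].sum())
            p.append(val)
    p = np.asarray(p)
    return p / p.sum()


class TestPosterior:
    def test_matches_brute_force_on_toy_instances(self):
        """Log-space evaluation equals the direct product on all small
        instances (<=5 bins, <=3 cells, counts <=3), to 1e-9."""
        rng = np.random.default_rng(7)
        cfg = DecoderConfig(min_ensemble=1)
        for trial in range(300):
            n_pos = int(rng.integers(2, 6))
            n_cells = int(rng.integers(1, 4))
            A = rng.uniform(0.02, 6.0, (n_cells, n_pos))
            counts = rng.integers(0, 4, n_cells).astype(float)
            tau = float(rng.uniform(0.01, 0.5))
            curves = make_curves(A)
            post = decode_posterior(counts, curves, tau, cfg)
            expect = brute_force_posterior(counts, A, tau)
            # compare over the outbound row and the flat rows jointly
            assert np.max(np.abs(np.sort(post.p)[::-1][:n_pos]
                                 - np.sort(expect)[::-1][:n_pos])) < 1e-9
            # and exactly on the outbound row
            impl_out = post.p.reshape(3, n_pos)[0]
            exp_out = expect.reshape(3, n_pos)[0]
            assert np.max(np.abs(impl_out - exp_out)) < 1e-9

    def test_posterior_normalizes_to_one(self):
        rng = np.random.default_rng(1)
        cfg = DecoderConfig(min_ensemble=1)
        for _ in range(50):
            A = rng.uniform(0.0, 20.0, (12, 64))
            counts = rng.integers(0, 6, 12).astype(float)
            post = decode_posterior(counts, make_curves(A), 0.1, cfg)
            assert abs(post.p.sum() - 1.0) < 1e-9
            assert (post.p >= 0).all()

    def test_flat_identical_curves_give_uniform_posterior(self):
        A = np.full((10, 64), 3.0)
        post = decode_posterior(np.ones(10), make_curves(A), 0.1)
        out_row = post.p.reshape(3, 64)[0]
        assert np.allclose(out_row, out_row[0])

    def test_zero_spikes_follow_the_closed_form(self):
        """With no spikes the posterior is proportional to exp(-tau*sum A)."""
        rng = np.random.default_rng(2)
        A = rng.uniform(0.1, 10.0, (10, 64))
        tau = 0.2
        post = decode_posterior(np.zeros(10), make_curves(A), tau)
        assert "zero_spikes" in post.flags
        out_row = post.p.reshape(3, 64)[0]
        expect = np.exp(-tau * np.maximum(A, 0.01).sum(axis=0))
        ratio = out_row / expect
        assert np.allclose(ratio / ratio[0], 1.0)
        # maximal where the summed expected rate is minimal
        assert np.argmax(out_row) == np.argmin(A.sum(axis=0))

    def test_small_ensembles_are_refused_at_the_gate(self):
        A = np.full((9, 64), 3.0)
        with pytest.raises(ValueError, match="9"):
            decode_posterior(np.ones(9), make_curves(A), 0.1, DecoderConfig())
        A10 = np.full((10, 64), 3.0)
        post = decode_posterior(np.ones(10), make_curves(A10), 0.1, DecoderConfig())
        assert abs(post.p.sum() - 1.0) < 1e-9

    def test_undefined_bins_receive_zero_mass(self):
        A = np.full((10, 64), 3.0)
        occ = np.ones((3, 64))
        occ[:, 10:20] = 0.0
        post = decode_posterior(np.ones(10), make_curves(A, occ), 0.1)
        assert np.all(post.p.reshape(3, 64)[:, 10:20] == 0.0)
        assert abs(post.p.sum() - 1.0) < 1e-9


class TestZoneMass:
    def test_uniform_posterior_gives_zone_share(self):
        A = np.full((10, 64), 3.0)
        post = decode_posterior(np.ones(10), make_curves(A), 0.1)
        bins = post.grid.zone_pos_bins(GEOM, "feeder")
        assert zone_mass(post, GEOM, "feeder") == pytest.approx(len(bins) / 64,
                                                                abs=1e-9)

    def test_zone_masses_partition_to_one(self):
        from lmaze.core import ZONE_NAMES
        rng = np.random.default_rng(3)
        A = rng.uniform(0.1, 10, (10, 64))
        post = decode_posterior(rng.integers(0, 4, 10).astype(float),
                                make_curves(A), 0.1)
        total = sum(zone_mass(post, GEOM, z) for z in ZONE_NAMES)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_unknown_zone_rejected(self):
        A = np.full((10, 64), 3.0)
        post = decode_posterior(np.ones(10), make_curves(A), 0.1)
        with pytest.raises(ValueError):
            zone_mass(post, GEOM, "lava_pit")


@pytest.fixture(scope="module")
def decode_session():
    """Attack session (no LFP; ground-truth theta) for decoding tests."""
    cfg = TaskConfig(session_type="attack", seed=77)
    sess = generate_session(cfg, n_laps=40, include_lfp=False)
    assert sess.ground_truth.attack_times
    return sess


class TestHSECrossDecoding:
    def test_identical_curves_give_identical_rows(self, decode_session):
        sess = decode_session
        gt = sess.ground_truth
        split = gt.first_attack_time
        t_end = sess.trajectory.t[-1]
        from lmaze import classify_pyramidal
        pyr = classify_pyramidal(sess.spikes.metrics)
        ids = [int(c) for c in sess.spikes.metrics.loc[pyr, "cell_id"]]
        curves = build_tuning_curves(sess.spikes, sess.trajectory,
                                     gt.theta_cycles, cell_ids=ids)
        hses = detect_hses(sess.spikes, duration=t_end, cell_ids=ids)
        events, table = decode_hse_events(
            hses, sess.spikes, curves, curves, split, sess.trajectory, GEOM)
        piv_r = table.pivot(index="epoch", columns="curve_epoch",
                            values="robot_mass")
        piv_f = table.pivot(index="epoch", columns="curve_epoch",
                            values="feeder_mass")
        assert np.allclose(piv_r["pre"], piv_r["post"], equal_nan=True)
        assert np.allclose(piv_f["pre"], piv_f["post"], equal_nan=True)

    def test_only_in_nest_events_are_decoded(self, decode_session):
        sess = decode_session
        gt = sess.ground_truth
        from lmaze import classify_pyramidal
        pyr = classify_pyramidal(sess.spikes.metrics)
        ids = [int(c) for c in sess.spikes.metrics.loc[pyr, "cell_id"]]
        curves = build_tuning_curves(sess.spikes, sess.trajectory,
                                     gt.theta_cycles, cell_ids=ids)
        hses = detect_hses(sess.spikes, duration=sess.trajectory.t[-1],
                           cell_ids=ids)
        events, _ = decode_hse_events(
            hses, sess.spikes, curves, curves, gt.first_attack_time,
            sess.trajectory, GEOM)
        x_at = np.interp(events["t_mid"], sess.trajectory.t, sess.trajectory.x)
        assert (x_at < GEOM.doorway_end).all()


class TestThetaDecoding:
    def test_descending_decode_tracks_the_animal(self, decode_session):
        sess = decode_session
        gt = sess.ground_truth
        from lmaze import classify_pyramidal
        pyr = classify_pyramidal(sess.spikes.metrics)
        ids = [int(c) for c in sess.spikes.metrics.loc[pyr, "cell_id"]]
        curves = build_tuning_curves(sess.spikes, sess.trajectory,
                                     gt.theta_cycles, cell_ids=ids)
        cyc, maps = decode_theta_cycles(gt.theta_cycles, sess.spikes, curves,
                                        sess.trajectory)
        err_bins = (cyc["com_desc"] - cyc["pos_desc"]).abs() / curves.grid.bin_width
        assert err_bins.median() < 2.0
        # local spiking in both phases would give a flat difference map; the
        # generator's ascending look-ahead makes it dip ahead for descending
        assert maps["n_cycles"] == len(cyc)

    def test_decoding_error_shrinks_with_ensemble_size(self):
        sess = generate_session(TaskConfig(session_type="linear_track", seed=55),
                                n_laps=50, n_cells=100, remap_fraction=0.0,
                                include_lfp=False)
        gt = sess.ground_truth
        cycles = gt.theta_cycles.iloc[::3]
        errs = []
        rng = np.random.default_rng(0)
        for n in (10, 30, 100):
            ids = sorted(rng.choice(100, size=n, replace=False).tolist())
            curves = build_tuning_curves(sess.spikes, sess.trajectory,
                                         gt.theta_cycles, cell_ids=ids)
            cyc, _ = decode_theta_cycles(cycles, sess.spikes, curves,
                                         sess.trajectory)
            errs.append(float((cyc["com_desc"] - cyc["pos_desc"]).abs().median()))
        assert errs[0] > errs[1] > errs[2]


class TestMatchedControls:
    def _annotate(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "t_mid": np.sort(rng.uniform(0, 600, n)),
            "pos_bin": rng.integers(0, 8, n),
            "dir_sign": rng.choice([-1.0, 1.0], n),
            "epoch": rng.choice(["pre", "post"], n),
        })

    def test_single_cycle_has_no_controls(self):
        cycles = self._annotate(1)
        out = match_control_cycles(cycles, cycles)
        assert out == {0: []}

    def test_controls_match_target_keys(self):
        cycles = self._annotate(400, seed=1)
        targets = cycles.iloc[:20]
        out = match_control_cycles(targets, cycles, cap=5, seed=3)
        for tid, ctrl in out.items():
            trow = cycles.loc[tid]
            assert len(ctrl) <= 5
            for c in ctrl:
                crow = cycles.loc[c]
                assert crow["pos_bin"] == trow["pos_bin"]
                assert crow["dir_sign"] == trow["dir_sign"]
                assert crow["epoch"] == trow["epoch"]
                assert c != tid

    def test_event_windows_are_excluded(self):
        cycles = self._annotate(200, seed=2)
        cycles.loc[:, "pos_bin"] = 3
        cycles.loc[:, "dir_sign"] = 1.0
        cycles.loc[:, "epoch"] = "pre"
        windows = np.array([[100.0, 400.0]])
        out = match_control_cycles(cycles.iloc[:3], cycles, windows,
                                   margin=1.0, cap=100, seed=0)
        t = cycles["t_mid"]
        for ctrl in out.values():
            for c in ctrl:
                assert not (99.0 <= t.loc[c] <= 401.0)
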