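"""Sharp-wave ripple (SWR) and high-synchrony event (HSE) detection.

SWRs: the ripple-band (150-250 Hz) Hilbert envelope of the best ripple
channel is z-normalized over the session; supra-threshold (4 SD) intervals
are merged when the gap between one event's end and the next one's start is
under 5 ms, or when two starts fall within 20 ms, and events not exceeding
20 ms are discarded.

HSEs: putative pyramidal spiking is summed in 1 ms bins, smoothed with a
7 ms SD Gaussian kernel, and z-normalized over the session; supra-threshold
(3 SD) intervals lasting more than 20 ms and less than 750 ms are kept.

Channel selection: per shank, the channel with the largest 120-250 Hz power
after removal of the aperiodic (1/f) component, fit robustly over
80-400 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .core import LFPSignal, SpikeEnsemble
from .lfpstate import PSDCurve, compute_psd, fit_aperiodic_residual

EVENT_COLUMNS = ["kind", "t_start", "t_end", "duration", "peak_z", "channel", "n_cells"]


@dataclass(frozen=True)
class SWRDetectorConfig:
    band: tuple[float, float] = (150.0, 250.0)
    z_threshold: float = 4.0
    min_duration: float = 0.020          # s, events must exceed this
    merge_gap_end_start: float = 0.005   # s
    merge_gap_start_start: float = 0.020  # s
    filter_order: int = 4


@dataclass(frozen=True)
class HSEDetectorConfig:
    bin_size: float = 0.001     # s
    kernel_sd: float = 0.007    # s
    z_threshold: float = 3.0
    min_duration: float = 0.020  # s, exclusive
    max_duration: float = 0.750  # s, exclusive

    def __post_init__(self) -> None:
        if self.min_duration >= self.max_duration:
            raise ValueError("min_duration must be below max_duration")


def select_swr_channel(
    lfp: LFPSignal,
    shanks: dict[int, list[int]] | None = None,
    fit_band: tuple[float, float] = (80.0, 400.0),
    power_band: tuple[float, float] = (120.0, 250.0),
) -> dict[int, int]:
    """Best ripple channel per shank: the one maximizing aperiodic-residual
    power integrated over ``power_band``.  Ties break to the lowest channel
    id.  With no shank map, all channels form one shank (key 0)."""
    if lfp.n_channels < 1:
        raise ValueError("need at least one channel")
    shanks = shanks or {0: list(lfp.channel_ids)}
    out: dict[int, int] = {}
    for shank, chans in shanks.items():
        best_id, best_score = None, -np.inf
        for cid in sorted(chans):
            x = lfp.channel(cid)
            if np.allclose(x, x[0]):
                continue
            psd = compute_psd(x, lfp.fs)
            residual, _ = fit_aperiodic_residual(psd, fit_band)
            sel = (residual.freqs >= power_band[0]) & (residual.freqs <= power_band[1])
            score = float(residual.power[sel].sum())
            if score > best_score + 1e-15:
                best_id, best_score = cid, score
        if best_id is None:
            raise ValueError(f"all channels on shank {shank} are flat")
        out[shank] = best_id
    return out


def _supra_threshold_intervals(z: np.ndarray, threshold: float, dt: float
                               ) -> list[list[float]]:
    above = z > threshold
    if not above.any():
        return []
    m = above.astype(int)
    edges = np.flatnonzero(np.diff(m))
    starts = list(edges[m[edges] == 0] + 1)
    ends = list(edges[m[edges] == 1] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(z))
    return [[s * dt, e * dt] for s, e in zip(starts, ends)]


def merge_candidates(
    intervals: list[list[float]],
    gap_end_start: float,
    gap_start_start: float,
) -> list[list[float]]:
    """Merge candidate events until fixpoint under both gap rules: an
    end-to-next-start gap under ``gap_end_start``, or two starts within
    ``gap_start_start``.  Iterating to fixpoint makes the result independent
    of rule ordering; the merge is idempotent."""
    iv = sorted([list(map(float, p)) for p in intervals])
    while True:
        out: list[list[float]] = []
        for s, e in iv:
            if out and (
                s - out[-1][1] < gap_end_start or s - out[-1][0] < gap_start_start
            ):
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        if len(out) == len(iv):
            return out
        iv = out


def detect_swrs(
    lfp: LFPSignal | np.ndarray,
    cfg: SWRDetectorConfig | None = None,
    fs: float | None = None,
    channel: int = 0,
) -> pd.DataFrame:
    """Detect SWRs on one channel; returns events sorted and non-overlapping."""
    cfg = cfg or SWRDetectorConfig()
    if isinstance(lfp, LFPSignal):
        fs = lfp.fs
        x = lfp.channel(channel)
    else:
        x = np.asarray(lfp, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a raw signal")
    if fs < 2 * cfg.band[1]:
        raise ValueError(f"sampling rate {fs} cannot represent {cfg.band[1]} Hz")
    ny = fs / 2.0
    b, a = signal.butter(cfg.filter_order, [cfg.band[0] / ny, cfg.band[1] / ny],
                         btype="bandpass")
    filt = signal.filtfilt(b, a, x)
    env = np.abs(signal.hilbert(filt))
    mu, sd = env.mean(), env.std()
    if sd == 0:
        raise ValueError("ripple-band envelope has zero variance")
    z = (env - mu) / sd

    dt = 1.0 / fs
    candidates = _supra_threshold_intervals(z, cfg.z_threshold, dt)
    merged = merge_candidates(candidates, cfg.merge_gap_end_start,
                              cfg.merge_gap_start_start)
    rows = []
    for s, e in merged:
        if e - s <= cfg.min_duration:
            continue
        i0, i1 = int(s * fs), max(int(e * fs), int(s * fs) + 1)
        rows.append({
            "kind": "swr", "t_start": s, "t_end": e, "duration": e - s,
            "peak_z": float(z[i0:i1].max()), "channel": channel, "n_cells": -1,
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def detect_hses(
    spikes: SpikeEnsemble | dict[int, np.ndarray],
    cfg: HSEDetectorConfig | None = None,
    duration: float | None = None,
    cell_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Detect HSEs from the smoothed multiunit rate of the given cells
    (callers should pass putative pyramidal cells only)."""
    cfg = cfg or HSEDetectorConfig()
    times = spikes.spike_times if isinstance(spikes, SpikeEnsemble) else spikes
    if cell_ids is not None:
        times = {c: times[c] for c in cell_ids}
    if not times:
        raise ValueError("empty ensemble")
    allspk = np.concatenate([v for v in times.values()]) if any(
        len(v) for v in times.values()) else np.array([])
    if len(allspk) == 0:
        raise ValueError("no spikes in ensemble")
    t_max = duration if duration is not None else float(allspk.max()) + cfg.bin_size
    n_bins = int(np.ceil(t_max / cfg.bin_size))
    counts = np.bincount(
        np.clip((allspk / cfg.bin_size).astype(int), 0, n_bins - 1), minlength=n_bins
    ).astype(float)
    smoothed = gaussian_filter1d(counts, sigma=cfg.kernel_sd / cfg.bin_size)
    mu, sd = smoothed.mean(), smoothed.std()
    if sd == 0:
        raise ValueError("smoothed population rate has zero variance")
    z = (smoothed - mu) / sd

    rows = []
    # participating cells per event are counted over [t_start, t_end]
    sorted_cells = {c: np.sort(v) for c, v in times.items()}
    for s, e in _supra_threshold_intervals(z, cfg.z_threshold, cfg.bin_size):
        dur = e - s
        if not (cfg.min_duration < dur < cfg.max_duration):
            continue
        i0, i1 = int(s / cfg.bin_size), max(int(e / cfg.bin_size), int(s / cfg.bin_size) + 1)
        n_cells = sum(
            1 for v in sorted_cells.values()
            if np.searchsorted(v, e) > np.searchsorted(v, s)
        )
        rows.append({
            "kind": "hse", "t_start": s, "t_end": e, "duration": dur,
            "peak_z": float(z[i0:i1].max()), "channel": -1, "n_cells": n_cells,
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def overlap_summary(swrs: pd.DataFrame, hses: pd.DataFrame) -> dict:
    """Counts and percentages of events from each set that intersect any
    event of the other set in time."""
    def _overlaps(a: pd.DataFrame, b: pd.DataFrame) -> int:
        if not len(a) or not len(b):
            return 0
        bs = b["t_start"].to_numpy()
        be = b["t_end"].to_numpy()
        n = 0
        for s, e in a[["t_start", "t_end"]].to_numpy():
            if np.any((bs <= e) & (be >= s)):
                n += 1
        return n

    n_swr, n_hse = len(swrs), len(hses)
    swr_olap = _overlaps(swrs, hses)
    hse_olap = _overlaps(hses, swrs)
    return {
        "n_swr": n_swr,
        "n_hse": n_hse,
        "swr_overlapping": swr_olap,
        "hse_overlapping": hse_olap,
        "pct_swr_overlapping": 100.0 * swr_olap / n_swr if n_swr else float("nan"),
        "pct_hse_overlapping": 100.0 * hse_olap / n_hse if n_hse else float("nan"),
    }
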