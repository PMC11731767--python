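"""Occupancy-normalized directional tuning curves and pre/post shift maps.

The track long axis is split into 64 equal positional bins crossed with 3
direction-of-travel bins (toward the robot, stationary, toward the nest),
giving the 192-bin grid used throughout decoding.  Tuning uses only spikes
emitted while the LFP is theta-dominated and on the descending theta phase —
the phase carrying current-position coding — and normalizes by the occupancy
accumulated under the same mask, so rates are spikes per second of included
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import DIRECTIONS, ArenaGeometry, SpikeEnsemble, Trajectory, ZONE_NAMES
from .lfpstate import StateSeries


def classify_pyramidal(metrics: pd.DataFrame) -> pd.Series:
    """Putative pyramidal flag: mean rate < 10 spikes/s AND peak-to-valley
    duration ratio > 0.4 (both strict)."""
    required = {"mean_rate_hz", "peak_valley_ratio"}
    if required - set(metrics.columns):
        raise ValueError(f"metrics table missing {required - set(metrics.columns)}")
    if metrics[list(required)].isna().any().any():
        raise ValueError("metrics contain missing values")
    return (metrics["mean_rate_hz"] < 10.0) & (metrics["peak_valley_ratio"] > 0.4)


@dataclass(frozen=True)
class TuningBinGrid:
    """64 positional bins x 3 direction bins = 192 tuning bins."""

    track_length: float = 111.0
    n_pos: int = 64
    directions: tuple[str, ...] = DIRECTIONS

    @property
    def n_bins(self) -> int:
        return self.n_pos * len(self.directions)

    @property
    def bin_width(self) -> float:
        return self.track_length / self.n_pos

    @property
    def pos_centers(self) -> np.ndarray:
        return (np.arange(self.n_pos) + 0.5) * self.bin_width

    def pos_bin(self, x: np.ndarray) -> np.ndarray:
        return np.clip((np.asarray(x) / self.bin_width).astype(int), 0, self.n_pos - 1)

    def zone_pos_bins(self, geom: ArenaGeometry, zone: str) -> np.ndarray:
        lo, hi = geom.zone_bounds(zone)
        c = self.pos_centers
        return np.flatnonzero((c >= lo) & (c < hi))


@dataclass
class TuningCurves:
    """Per-cell expected rate A_i over the grid, with the occupancy used to
    normalize.  Bins never occupied under the inclusion mask are NaN (an
    undefined marker, never zero)."""

    grid: TuningBinGrid
    cell_ids: list[int]
    rates: np.ndarray         # (n_cells, 3, n_pos); NaN where occupancy == 0
    occupancy: np.ndarray     # (3, n_pos) seconds of included time
    spike_counts: np.ndarray  # (n_cells,) spikes inside the mask
    epoch: str = "whole"

    @property
    def defined(self) -> np.ndarray:
        return self.occupancy > 0

    def rates_flat(self) -> np.ndarray:
        return self.rates.reshape(len(self.cell_ids), self.grid.n_bins)

    def occupancy_flat(self) -> np.ndarray:
        return self.occupancy.reshape(self.grid.n_bins)

    def subset(self, cell_ids: list[int]) -> "TuningCurves":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return TuningCurves(
            grid=self.grid, cell_ids=list(cell_ids), rates=self.rates[idx],
            occupancy=self.occupancy, spike_counts=self.spike_counts[idx],
            epoch=self.epoch,
        )


def direction_signs(
    traj: Trajectory,
    stationary_band: float = 5.0,
    lowpass_cutoff: float = 2.0,
) -> np.ndarray:
    """Per-sample direction: +1 toward the robot, -1 toward the nest, 0 when
    the smoothed along-track speed is inside the stationary band (cm/s)."""
    fs = 1.0 / traj.dt
    b, a = sps.butter(3, lowpass_cutoff / (fs / 2.0), btype="lowpass")
    v = np.gradient(sps.filtfilt(b, a, traj.x), traj.t)
    out = np.zeros(len(traj), dtype=np.int8)
    out[v > stationary_band] = 1
    out[v < -stationary_band] = -1
    return out


def _descending_mask(times: np.ndarray, theta_cycles: pd.DataFrame) -> np.ndarray:
    """True where t falls in a [t_peak, t_trough) descending half-cycle."""
    if not len(theta_cycles):
        return np.zeros(len(times), dtype=bool)
    tp = theta_cycles["t_peak"].to_numpy()
    tt = theta_cycles["t_trough"].to_numpy()
    idx = np.searchsorted(tp, times, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(times), dtype=bool)
    res[ok] = times[ok] < tt[idx[ok]]
    return res


_DIR_ROW = {1: 0, 0: 1, -1: 2}  # dirsign -> grid direction row


def _smoothing_matrix(n: int, sd_bins: float) -> np.ndarray:
    """Mass-preserving Gaussian redistribution matrix.

    Each source bin's mass is spread over its neighbors with truncated-kernel
    weights renormalized inside the support, so column sums of the input are
    preserved exactly (spike counts and occupancy seconds are conserved)."""
    idx = np.arange(n)
    k = np.exp(-0.5 * ((idx[None, :] - idx[:, None]) / sd_bins) ** 2)
    return k / k.sum(axis=1, keepdims=True)


def build_tuning_curves(
    spikes: SpikeEnsemble,
    traj: Trajectory,
    theta_cycles: pd.DataFrame,
    state: StateSeries | None = None,
    grid: TuningBinGrid | None = None,
    epoch: tuple[float, float] | None = None,
    cell_ids: list[int] | None = None,
    epoch_label: str = "whole",
    occupancy_mode: str = "matched",
    stationary_band: float = 5.0,
    smooth_sd_bins: float = 1.0,
) -> TuningCurves:
    """Occupancy-normalized directional tuning curves.

    Both spikes and occupancy are restricted to theta-state (when a state
    series is given), descending-phase time within the epoch interval; with
    ``occupancy_mode="direction_time"`` the occupancy instead uses all tracked
    time in each direction bin within the epoch (the alternative reading of
    the occupancy normalization).

    Counts and occupancy are kernel-smoothed along the positional axis
    (``smooth_sd_bins`` Gaussian SD, 0 disables) with a mass-preserving
    kernel, so the conservation identity sum(A * occupancy) = included spike
    count holds exactly with or without smoothing.
    """
    grid = grid or TuningBinGrid()
    if occupancy_mode not in ("matched", "direction_time"):
        raise ValueError(f"unknown occupancy mode {occupancy_mode!r}")
    cell_ids = list(cell_ids) if cell_ids is not None else spikes.cell_ids
    t = traj.t
    dt = traj.dt

    dirsign = direction_signs(traj, stationary_band)
    dir_row = np.array([_DIR_ROW[d] for d in dirsign.tolist()], dtype=int)
    pos_bin = grid.pos_bin(traj.x)

    include = traj.tracked.copy()
    if epoch is not None:
        include &= (t >= epoch[0]) & (t < epoch[1])
    spike_gate = include.copy()
    desc = _descending_mask(t, theta_cycles)
    theta_ok = state.theta_at(t) if state is not None else np.ones(len(t), dtype=bool)
    include_masked = include & desc & theta_ok
    spike_gate &= desc & theta_ok
    occ_mask = include_masked if occupancy_mode == "matched" else include

    if not occ_mask.any():
        raise ValueError("no included time under the tuning mask")

    occupancy = np.zeros((3, grid.n_pos))
    np.add.at(occupancy, (dir_row[occ_mask], pos_bin[occ_mask]), dt)

    n_cells = len(cell_ids)
    counts = np.zeros((n_cells, 3, grid.n_pos))
    total = np.zeros(n_cells)
    for i, cid in enumerate(cell_ids):
        st = spikes.spike_times[cid]
        if len(st) == 0:
            continue
        # nearest-sample assignment (a floor would lag the animal by half a
        # position sample on average)
        si = np.clip(np.searchsorted(t, st, side="right") - 1, 0, len(t) - 2)
        si += (st - t[si]) > (t[si + 1] - st)
        keep = spike_gate[si]
        si = si[keep]
        np.add.at(counts[i], (dir_row[si], pos_bin[si]), 1.0)
        total[i] = len(si)

    if smooth_sd_bins > 0:
        W = _smoothing_matrix(grid.n_pos, smooth_sd_bins)
        occupancy = occupancy @ W
        counts = counts @ W

    with np.errstate(invalid="ignore", divide="ignore"):
        rates = counts / occupancy[None, :, :]
    rates[:, occupancy == 0] = np.nan
    return TuningCurves(
        grid=grid, cell_ids=cell_ids, rates=rates, occupancy=occupancy,
        spike_counts=total, epoch=epoch_label,
    )


@dataclass
class TuningShift:
    """Post-minus-pre change in occupancy-normalized spatial tuning."""

    grid: TuningBinGrid
    cell_ids: list[int]
    per_cell: np.ndarray       # (n_cells, n_pos), NaN where undefined
    mean_shift: np.ndarray     # (n_pos,), cross-cell mean
    zones: pd.DataFrame        # zone, mean_shift, n_bins
    n_cells_used: int = 0


def _direction_marginal(curves: TuningCurves) -> np.ndarray:
    """Occupancy-weighted direction marginal per cell: (n_cells, n_pos)."""
    occ = curves.occupancy          # (3, n_pos)
    rates = curves.rates            # (n_cells, 3, n_pos)
    w = np.where(np.isnan(rates), 0.0, occ[None, :, :])
    num = np.nansum(rates * w, axis=1)
    den = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        marg = num / den
    marg[den == 0] = np.nan
    return marg


def compute_tuning_shift(
    pre: TuningCurves,
    post: TuningCurves,
    geom: ArenaGeometry | None = None,
    min_spikes: int = 10,
) -> TuningShift:
    """Per-cell (post - pre) tuning difference per positional bin, direction
    bins collapsed by occupancy weighting; cross-cell mean and per-zone
    aggregates.  Cells need ``min_spikes`` included spikes in each epoch to
    enter the average; identical inputs give an all-zero map."""
    geom = geom or ArenaGeometry()
    if pre.cell_ids != post.cell_ids:
        unmatched = set(pre.cell_ids) ^ set(post.cell_ids)
        raise ValueError(f"mismatched cell sets: {sorted(unmatched)}")
    if pre.grid.n_bins != post.grid.n_bins:
        raise ValueError("mismatched tuning grids")

    marg_pre = _direction_marginal(pre)
    marg_post = _direction_marginal(post)
    diff = marg_post - marg_pre
    keep = (pre.spike_counts >= min_spikes) & (post.spike_counts >= min_spikes)
    diff[~keep] = np.nan

    with np.errstate(invalid="ignore"):
        mean_shift = np.nanmean(diff, axis=0)

    rows = []
    for zone in ZONE_NAMES:
        bins = pre.grid.zone_pos_bins(geom, zone)
        vals = mean_shift[bins]
        rows.append({
            "zone": zone,
            "mean_shift": float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan,
            "n_bins": len(bins),
        })
    return TuningShift(
        grid=pre.grid, cell_ids=list(pre.cell_ids), per_cell=diff,
        mean_shift=mean_shift, zones=pd.DataFrame(rows),
        n_cells_used=int(keep.sum()),
    )
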