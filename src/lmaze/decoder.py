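"""One-step Bayesian decoding of position from ensemble spike counts.

Under Poisson-independent firing with a uniform spatial prior, the posterior
over the 192 tuning bins for a window of duration tau with counts n_i is

    P(x | n) ∝ prod_i A_i(x)^{n_i} * (1/X) * exp(-tau * sum_i A_i(x)),

normalized to sum to one over defined bins.  Evaluation is done in log space
for numerical stability.  Decoding is applied to high-synchrony events (with
the pre/post-attack 2x2 tuning-curve cross design) and to ascending versus
descending theta half-cycles (with position-re-centered difference maps and
matched-pass controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ArenaGeometry, SpikeEnsemble, Trajectory
from .lfpstate import StateSeries
from .tuning import TuningBinGrid, TuningCurves


@dataclass(frozen=True)
class DecoderConfig:
    """Decoding gates and numerical policy.

    Sessions with fewer than ``min_ensemble`` putative pyramidal cells are
    refused.  Defined bins where a cell's tuning is exactly zero receive a
    small ``rate_floor`` before exponentiation so a single silent cell cannot
    zero out the posterior; undefined (never-occupied) bins get zero mass and
    are excluded from normalization.
    """

    min_ensemble: int = 10
    rate_floor: float = 0.01  # spikes/s

    def __post_init__(self) -> None:
        if self.min_ensemble < 1:
            raise ValueError("min_ensemble must be >= 1")


@dataclass
class Posterior:
    p: np.ndarray             # (n_bins,) over the full grid; zeros where undefined
    grid: TuningBinGrid
    tau: float
    n_cells: int
    n_spikes: int
    provenance: str = "arbitrary"
    flags: list[str] = field(default_factory=list)

    def position_marginal(self) -> np.ndarray:
        return self.p.reshape(len(self.grid.directions), self.grid.n_pos).sum(axis=0)

    def center_of_mass(self) -> float:
        """Posterior center of mass along the track, cm."""
        m = self.position_marginal()
        return float(np.dot(m, self.grid.pos_centers))


def decode_posterior(
    counts: np.ndarray,
    curves: TuningCurves,
    tau: float,
    cfg: DecoderConfig | None = None,
    provenance: str = "arbitrary",
) -> Posterior:
    """Poisson-independence posterior for one decode window."""
    cfg = cfg or DecoderConfig()
    counts = np.asarray(counts, dtype=float)
    n_cells = len(counts)
    if n_cells != len(curves.cell_ids):
        raise ValueError("count vector does not match the curve cell set")
    if n_cells < cfg.min_ensemble:
        raise ValueError(
            f"ensemble of {n_cells} cells is below the minimum of {cfg.min_ensemble}"
        )
    if tau <= 0:
        raise ValueError("window duration must be positive")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("spike counts must be non-negative integers")

    A = curves.rates_flat()
    defined = curves.occupancy_flat() > 0
    if not defined.any():
        raise ValueError("tuning curves are undefined on every bin")

    A_def = A[:, defined]
    A_def = np.where(np.isnan(A_def), cfg.rate_floor, A_def)
    A_def = np.maximum(A_def, cfg.rate_floor)

    logp = counts @ np.log(A_def) - tau * A_def.sum(axis=0)
    logp -= logp.max()
    p_def = np.exp(logp)
    p_def /= p_def.sum()

    p = np.zeros(curves.grid.n_bins)
    p[defined] = p_def
    flags = [] if counts.sum() > 0 else ["zero_spikes"]
    return Posterior(
        p=p, grid=curves.grid, tau=tau, n_cells=n_cells,
        n_spikes=int(counts.sum()), provenance=provenance, flags=flags,
    )


def zone_mass(
    posterior: Posterior, geom: ArenaGeometry, zone: str
) -> float:
    """Position-marginal posterior mass over a zone's positional bins."""
    bins = posterior.grid.zone_pos_bins(geom, zone)
    return float(posterior.position_marginal()[bins].sum())


def _window_counts(
    spikes: SpikeEnsemble, cell_ids: list[int], t0: float, t1: float
) -> np.ndarray:
    out = np.empty(len(cell_ids))
    for i, cid in enumerate(cell_ids):
        st = spikes.spike_times[cid]
        out[i] = np.searchsorted(st, t1) - np.searchsorted(st, t0)
    return out


def decode_hse_events(
    hses: pd.DataFrame,
    spikes: SpikeEnsemble,
    curves_pre: TuningCurves,
    curves_post: TuningCurves,
    split_time: float,
    traj: Trajectory,
    geom: ArenaGeometry | None = None,
    cfg: DecoderConfig | None = None,
    state: StateSeries | None = None,
    in_nest_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-decoding of in-nest HSEs against pre- and post-attack curves.

    Each HSE (restricted to nest occupancy and, when a state series is given,
    to LIA bins) is decoded with tau equal to the event duration under both
    curve epochs; robot-zone and feeder-zone posterior masses are recorded.
    Events are partitioned by the first-attack (or yoked) ``split_time``.
    Returns the per-event table and the 2x2 summary table.
    """
    geom = geom or ArenaGeometry()
    cfg = cfg or DecoderConfig()
    if curves_pre.cell_ids != curves_post.cell_ids:
        raise ValueError("pre and post curves must share one cell set")
    cell_ids = curves_pre.cell_ids

    rows = []
    for eid, ev in hses.iterrows():
        t0, t1 = float(ev["t_start"]), float(ev["t_end"])
        mid = (t0 + t1) / 2.0
        i = int(np.clip(np.searchsorted(traj.t, mid), 0, len(traj.t) - 1))
        if in_nest_only and traj.x[i] >= geom.doorway_end:
            continue
        if state is not None and state.theta_at(np.array([mid]))[0]:
            continue
        counts = _window_counts(spikes, cell_ids, t0, t1)
        epoch = "pre" if mid < split_time else "post"
        for curve_epoch, curves in (("pre", curves_pre), ("post", curves_post)):
            post = decode_posterior(counts, curves, tau=t1 - t0, cfg=cfg,
                                    provenance="hse")
            rows.append({
                "event": eid, "t_mid": mid, "epoch": epoch,
                "curve_epoch": curve_epoch,
                "robot_mass": zone_mass(post, geom, "robot"),
                "feeder_mass": zone_mass(post, geom, "feeder"),
                "n_cells": post.n_cells, "n_spikes": post.n_spikes,
                "tau": t1 - t0,
            })
    events = pd.DataFrame(rows, columns=[
        "event", "t_mid", "epoch", "curve_epoch", "robot_mass", "feeder_mass",
        "n_cells", "n_spikes", "tau",
    ])

    cells = []
    for epoch in ("pre", "post"):
        for curve_epoch in ("pre", "post"):
            sel = events[(events["epoch"] == epoch)
                         & (events["curve_epoch"] == curve_epoch)]
            cells.append({
                "epoch": epoch, "curve_epoch": curve_epoch,
                "n_events": len(sel),
                "robot_mass": float(sel["robot_mass"].mean()) if len(sel) else np.nan,
                "feeder_mass": float(sel["feeder_mass"].mean()) if len(sel) else np.nan,
                "empty": not len(sel),
            })
    return events, pd.DataFrame(cells)


def decode_theta_cycles(
    cycles: pd.DataFrame,
    spikes: SpikeEnsemble,
    curves: TuningCurves,
    traj: Trajectory,
    cfg: DecoderConfig | None = None,
    min_speed: float = 5.0,
) -> tuple[pd.DataFrame, dict]:
    """Decode each theta half-cycle separately.

    For every cycle the descending ([peak, trough)) and ascending
    ([trough, next peak)) windows are decoded with tau equal to the half-cycle
    duration.  Returns a per-cycle table with posterior centers of mass and
    signed-ahead offsets (positive = ahead of the animal along the current
    running direction), plus re-centered average posterior maps and their
    descending-minus-ascending difference.
    """
    from .tuning import direction_signs

    cfg = cfg or DecoderConfig()
    grid = curves.grid
    cell_ids = curves.cell_ids
    n_rel = 2 * grid.n_pos - 1
    maps = {
        "descending": np.zeros(n_rel), "ascending": np.zeros(n_rel),
        "n_cycles": 0,
    }
    dirsign = direction_signs(traj, stationary_band=min_speed)

    rows = []
    for _, cyc in cycles.iterrows():
        tp, tt, te = float(cyc["t_peak"]), float(cyc["t_trough"]), float(cyc["t_end"])
        mid = (tp + te) / 2.0
        i = int(np.clip(np.searchsorted(traj.t, mid), 0, len(traj.t) - 1))
        ds = int(dirsign[i])
        if ds == 0:
            continue
        sign = float(ds)
        pos = float(np.interp(mid, traj.t, traj.x))
        pos_bin = int(grid.pos_bin(np.array([pos]))[0])

        rec = {"t_mid": mid, "pos": pos, "dir_sign": sign, "pos_bin": pos_bin}
        for phase, (t0, t1) in (("desc", (tp, tt)), ("asc", (tt, te))):
            counts = _window_counts(spikes, cell_ids, t0, t1)
            post = decode_posterior(counts, curves, tau=t1 - t0, cfg=cfg,
                                    provenance="theta_half_cycle")
            com = post.center_of_mass()
            # reference the animal at this half-cycle's own center
            pos_phase = float(np.interp((t0 + t1) / 2.0, traj.t, traj.x))
            rec[f"com_{phase}"] = com
            rec[f"n_spikes_{phase}"] = post.n_spikes
            rec[f"pos_{phase}"] = pos_phase
            rec[f"ahead_{phase}"] = (com - pos_phase) * sign
            marg = post.position_marginal()
            ref_bin = int(grid.pos_bin(np.array([pos_phase]))[0])
            # re-center: index (bin - ref_bin)*sign + (n_pos - 1)
            rel = ((np.arange(grid.n_pos) - ref_bin) * ds
                   + grid.n_pos - 1).astype(int)
            target = "descending" if phase == "desc" else "ascending"
            np.add.at(maps[target], rel, marg)
        maps["n_cycles"] += 1
        rows.append(rec)

    df = pd.DataFrame(rows)
    if maps["n_cycles"] > 0:
        maps["descending"] /= maps["n_cycles"]
        maps["ascending"] /= maps["n_cycles"]
    maps["difference"] = maps["descending"] - maps["ascending"]
    maps["rel_axis_cm"] = (np.arange(n_rel) - (grid.n_pos - 1)) * grid.bin_width
    return df, maps


def match_control_cycles(
    targets: pd.DataFrame,
    all_cycles: pd.DataFrame,
    event_windows: np.ndarray | None = None,
    margin: float = 1.0,
    cap: int = 10,
    seed: int = 0,
) -> dict[int, list[int]]:
    """Matched-pass controls for selected theta cycles.

    Both frames must carry ``pos_bin``, ``dir_sign``, ``epoch`` and ``t_mid``
    columns (as produced by annotating the decode table).  For each target,
    controls share (positional bin, direction, epoch), fall outside every
    target event window padded by ``margin`` seconds, and are sampled without
    replacement up to ``cap`` per target.  Targets with no eligible control
    map to an empty list.
    """
    rng = np.random.default_rng(seed)
    windows = np.asarray(event_windows if event_windows is not None else []).reshape(-1, 2)
    t_all = all_cycles["t_mid"].to_numpy()
    excluded = np.zeros(len(all_cycles), dtype=bool)
    for a, b in windows:
        excluded |= (t_all >= a - margin) & (t_all <= b + margin)

    out: dict[int, list[int]] = {}
    for tid, trow in targets.iterrows():
        elig = (
            (all_cycles["pos_bin"] == trow["pos_bin"])
            & (all_cycles["dir_sign"] == trow["dir_sign"])
            & (all_cycles["epoch"] == trow["epoch"])
            & ~excluded
            & (all_cycles.index != tid)
        )
        idx = list(all_cycles.index[elig])
        if len(idx) > cap:
            idx = list(rng.choice(idx, size=cap, replace=False))
        out[tid] = sorted(int(i) for i in idx)
    return out
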