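"""Synthetic L-maze session generator.

Produces complete sessions — trajectory, place-cell spike trains, multichannel
LFP and full ground-truth labels — with the statistical structure the
downstream analyses assume:

* lap running between a nest feeder and a far feeder guarded by a robot, with
  scripted hesitations, mid-track aborts (MTAs), on-track pauses, and
  stochastic robot attacks (by default a 20% chance per eligible lap, eligible
  from lap 15 onward, inclusive);
* direction-selective Gaussian place fields emitting inhomogeneous Poisson
  spikes, gated to the descending phase of theta for the local component and
  shifted ahead of the animal during the ascending phase (a fixed look-ahead
  offset emulating forward theta sweeps); a configurable fraction of cells
  additionally gains robot-zone fields once the first attack has occurred;
* composite LFP with movement-locked asymmetric theta, stillness-locked
  delta/LIA, a 1/f background, and 150-250 Hz ripple bursts injected into
  nest-event windows that coincide with scripted population bursts (HSEs).

One master seed is split into labeled per-component streams, so regenerating
any one component never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    ArenaGeometry,
    LFPSignal,
    SpikeEnsemble,
    TaskConfig,
    Trajectory,
    derive_rng,
)

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryConfig:
    """Scripted-behavior rates and kinematics for the trajectory generator.

    Event rates are per-lap probabilities; durations in seconds.  The rat
    runs at ``run_speed`` and retreats from attacks at ``retreat_speed``.
    """

    run_speed: float = 35.0          # cm/s
    retreat_speed: float = 60.0      # cm/s
    feeder_approach_speed: float = 12.0  # cm/s over the last stretch to a feeder
    feeder_slow_zone: float = 8.0        # cm of decelerated approach/departure
    position_noise_sd: float = 0.25  # cm, iid Gaussian on x and y
    mta_probability: float = 0.15           # outbound stretch-abort per lap
    inbound_mta_probability: float = 0.05   # return-to-feeder abort per lap
    pause_probability: float = 0.30         # per journey, each direction
    pause_duration: tuple[float, float] = (0.8, 2.0)
    hesitation_duration: tuple[float, float] = (1.5, 4.0)  # doorway staging
    feeder_dwell: tuple[float, float] = (0.6, 1.2)
    mta_turn_dwell: float = 0.3


@dataclass(frozen=True)
class FieldConfig:
    """Generative place-field population parameters."""

    peak_rate: tuple[float, float] = (8.0, 16.0)    # spikes/s
    width: tuple[float, float] = (4.0, 7.0)          # cm (Gaussian SD)
    approach_rate: tuple[float, float] = (2.0, 3.0)  # threat cells, pre-attack
    approach_width: tuple[float, float] = (4.0, 6.0)
    remap_peak_rate: tuple[float, float] = (8.0, 16.0)  # post-attack robot fields
    center_jitter: float = 2.0                       # cm around even spacing
    preference_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)
    # weights over (outbound, inbound, both)


@dataclass(frozen=True)
class SpikeConfig:
    """Spike-emission parameters."""

    baseline_rate: float = 0.2     # spikes/s, ungated
    lookahead_cm: float = 7.0      # ascending-phase forward offset
    hse_gain: float = 8.0          # multiplier on field value at HSE content
    hse_content_width: float = 3.0  # cm, extra recruitment width around content
    hse_population_rate: float = 4.0  # spikes/s per cell, content-independent
    n_interneurons: int = 3
    interneuron_rate: tuple[float, float] = (12.0, 25.0)
    bin_ms: float = 1.0


@dataclass(frozen=True)
class ThetaConfig:
    """Movement-locked theta waveform: phase-warped sinusoid whose
    ascending:descending duration ratio is ``asymmetry_ratio``."""

    f0: float = 8.0                 # Hz
    freq_jitter: float = 0.2        # Hz, per-cycle SD
    asymmetry_ratio: float = 1.2    # ascending / descending duration
    amplitude: float = 200.0        # µV


@dataclass(frozen=True)
class LFPConfig:
    fs: float = 1000.0
    n_channels: int = 4
    ripple_channel: int = 2         # designated high-ripple channel
    ripple_freq: float = 180.0      # Hz, per-event jitter applied
    ripple_freq_jitter: float = 15.0
    ripple_amplitude_sd: float = 6.0  # target envelope z at event peak
    off_channel_ripple_scale: float = 0.3
    delta_freq: float = 2.5         # Hz, stillness oscillation
    delta_amplitude: float = 140.0  # µV
    noise_rms: float = 40.0         # µV, 1/f background
    noise_exponent: float = 2.0     # power ∝ f^-exponent
    white_rms: float = 4.0          # µV


@dataclass(frozen=True)
class EventConfig:
    """Scheduling of nest transient events (coincident SWR + HSE windows).

    A ``threat_probability`` share of events carry robot-zone content
    expressed by the threat ensemble (the cells that gain robot fields);
    the rest replay ordinary locations through the regular spatial map, with
    a ``reward_content_probability`` bias toward the far-feeder area (reward
    replay).  Ordinary content avoids the robot-zone interior: there, spatial
    content is carried by the threat ensemble.
    """

    rate_per_dwell_second: float = 0.6
    duration: tuple[float, float] = (0.075, 0.120)  # s
    edge_margin: float = 0.08                        # s from dwell edges
    swr_probability: float = 0.9
    hse_probability: float = 0.9
    threat_probability: float = 0.4
    reward_content_probability: float = 0.2
    threat_content_margin: float = 10.0  # cm kept clear of zone boundaries


@dataclass(frozen=True)
class GenerativePlaceField:
    """One Gaussian field component of one cell."""

    cell_id: int
    center: float          # cm
    width: float           # cm, Gaussian SD
    peak_rate: float       # spikes/s
    preference: str        # outbound | inbound | both | stationary
    post_attack_only: bool = False

    def __post_init__(self) -> None:
        if self.peak_rate < 0:
            raise ValueError("peak rate must be >= 0")
        if self.preference not in ("outbound", "inbound", "both", "stationary"):
            raise ValueError(f"unknown preference {self.preference!r}")


@dataclass
class GroundTruth:
    """Everything the generator scripted, for round-trip validation."""

    n_laps: int
    laps: pd.DataFrame             # lap, t_start, t_complete
    attack_laps: list[int]
    attack_times: list[float]
    hesitations: pd.DataFrame      # t_start, t_end, duration_excl, lap
    mtas: pd.DataFrame             # t_start, t_end, t_turn, lap, direction
    pauses: pd.DataFrame           # t_start, t_end, lap, direction
    movement_intervals: np.ndarray  # (n, 2) seconds
    nest_dwells: np.ndarray         # (n, 2) seconds, stillness in nest
    theta_cycles: pd.DataFrame      # t_peak, t_trough, t_end
    event_windows: pd.DataFrame     # t_start, t_end, content_x, has_swr, has_hse
    fields: list[GenerativePlaceField] = field(default_factory=list)

    @property
    def first_attack_time(self) -> float | None:
        return self.attack_times[0] if self.attack_times else None

    @property
    def first_attack_lap(self) -> int | None:
        return self.attack_laps[0] if self.attack_laps else None


@dataclass
class SyntheticSession:
    trajectory: Trajectory
    spikes: SpikeEnsemble
    lfp: LFPSignal | None
    ground_truth: GroundTruth
    task: TaskConfig
    geometry: ArenaGeometry


# --------------------------------------------------------------------------
# Attack schedule
# --------------------------------------------------------------------------


def generate_attack_schedule(
    cfg: TaskConfig, n_laps: int, rng: np.random.Generator | None = None
) -> list[int]:
    """Lap indices (1-based) on which the robot attacks.

    Non-attack session types yield an empty schedule.  On attack sessions,
    every lap from ``first_eligible_lap`` (inclusive) onward independently
    attacks with ``attack_probability``.
    """
    if n_laps < 0:
        raise ValueError("n_laps must be non-negative")
    if cfg.session_type != "attack":
        return []
    if rng is None:
        rng = derive_rng(cfg.seed, "attacks")
    laps = np.arange(cfg.first_eligible_lap, n_laps + 1)
    hits = rng.random(len(laps)) < cfg.attack_probability
    return [int(k) for k in laps[hits]]


# --------------------------------------------------------------------------
# Trajectory
# --------------------------------------------------------------------------


class _Script:
    """Accumulates a 30 Hz piecewise-linear position script.

    Records the scripted (noise-free) velocity per sample so that ground
    truth never depends on tracking noise.
    """

    def __init__(self, fs: float, x0: float, y0: float):
        self.fs = fs
        self.x = [x0]
        self.y = [y0]
        self.v = [0.0]

    @property
    def idx(self) -> int:
        return len(self.x) - 1

    @property
    def t(self) -> float:
        return self.idx / self.fs

    def dwell(self, duration: float) -> tuple[int, int]:
        i0 = self.idx
        n = max(1, round(duration * self.fs))
        self.x.extend([self.x[-1]] * n)
        self.y.extend([self.y[-1]] * n)
        self.v.extend([0.0] * n)
        return i0, self.idx

    def move_to(self, x_target: float, speed: float) -> tuple[int, int]:
        i0 = self.idx
        dist = x_target - self.x[-1]
        if abs(dist) < 1e-9:
            return i0, i0
        step = speed / self.fs
        n = max(1, math.ceil(abs(dist) / step))
        sgn = math.copysign(1.0, dist)
        xs = self.x[-1] + sgn * step * np.arange(1, n + 1)
        xs[-1] = x_target
        self.x.extend(xs.tolist())
        self.y.extend([self.y[-1]] * n)
        self.v.extend([sgn * speed] * n)
        return i0, self.idx


def _crossing_time(xs: np.ndarray, i0: int, i1: int, level: float, fs: float) -> float:
    """Time of the first sample at or beyond `level` within [i0, i1]."""
    seg = xs[i0 : i1 + 1]
    if seg[-1] >= seg[0]:
        hits = np.nonzero(seg >= level)[0]
    else:
        hits = np.nonzero(seg <= level)[0]
    return (i0 + int(hits[0])) / fs


def generate_trajectory(
    cfg: TaskConfig,
    geom: ArenaGeometry,
    behavior: TrajectoryConfig | None = None,
    n_laps: int | None = None,
    attack_laps: list[int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Script a lap-running trajectory with labeled behavioral events.

    Laps alternate between the nest feeder and the far (track) feeder.  All
    scripted events satisfy the downstream detection criteria with margin:
    MTAs stay on the track > 0.5 s and > 5 cm, pauses move < 1 cm for
    > 0.5 s, hesitations occupy the nest/doorway zones.  Attack laps cross
    the attack threshold and immediately retreat to the nest.
    """
    behavior = behavior or TrajectoryConfig()
    if rng is None:
        rng = derive_rng(cfg.seed, "trajectory")
    if attack_laps is None:
        # upper bound on laps for schedule purposes
        max_laps = n_laps if n_laps is not None else int(cfg.session_duration / 6) + 1
        attack_laps = generate_attack_schedule(cfg, max_laps, derive_rng(cfg.seed, "attacks"))
    attack_set = set(attack_laps)

    fs = geom.position_rate
    nest_x = geom.feeder_nest_x
    staging_x = geom.doorway_end - 5.0        # inside doorway/nest, clear of track
    feeder_x = geom.feeder_track_x
    thr = geom.attack_threshold
    sc = _Script(fs, nest_x, geom.track_width / 2.0)

    slow0 = feeder_x - behavior.feeder_slow_zone

    def run_to_feeder():
        # decelerate over the last stretch so the feeder area is sampled
        # during movement (theta), as a real approach would
        sc.move_to(slow0, behavior.run_speed)
        sc.move_to(feeder_x, behavior.feeder_approach_speed)

    def leave_feeder(target, speed):
        sc.move_to(slow0, behavior.feeder_approach_speed)
        sc.move_to(target, speed)

    hesit_rows: list[tuple] = []   # (i_start, i_end, lap) -- filled post hoc
    mta_rows: list[dict] = []
    pause_rows: list[dict] = []
    dwell_rows: list[tuple[int, int]] = []     # still nest dwells (sample idx)
    lap_rows: list[dict] = []
    attack_times: list[float] = []
    realized_attacks: list[int] = []

    duration_cap = cfg.session_duration
    lap = 0
    while True:
        lap += 1
        if n_laps is not None and lap > n_laps:
            break
        if sc.t > duration_cap - 15.0:
            break
        t_lap_start = sc.t

        # --- nest phase: feeder visit then doorway staging dwell
        sc.move_to(nest_x, behavior.run_speed)
        sc.dwell(rng.uniform(*behavior.feeder_dwell))
        sc.move_to(staging_x, behavior.run_speed)
        dwell_rows.append(sc.dwell(rng.uniform(*behavior.hesitation_duration)))

        # --- optional outbound mid-track abort (stretch onto track, retreat)
        if rng.random() < behavior.mta_probability:
            x_turn = rng.uniform(geom.doorway_end + 12.0, thr - 4.0)
            sc.move_to(x_turn, behavior.run_speed)
            d0, d1 = sc.dwell(behavior.mta_turn_dwell)
            t_turn = (d0 + d1) / 2.0 / fs
            sc.move_to(staging_x, behavior.run_speed)
            mta_rows.append(
                {"lap": lap, "direction": "outbound", "t_turn": t_turn,
                 "x_turn": x_turn}
            )
            dwell_rows.append(sc.dwell(rng.uniform(1.0, 2.0)))

        # --- outbound run (attack laps retreat at the threshold, then re-run)
        is_attack = lap in attack_set
        pause_out = (not is_attack) and rng.random() < behavior.pause_probability
        if is_attack:
            i0, i1 = sc.move_to(thr + 4.0, behavior.run_speed)
            attack_times.append(_crossing_time(np.asarray(sc.x), i0, i1, thr, fs))
            realized_attacks.append(lap)
            sc.move_to(staging_x, behavior.retreat_speed)
            sc.move_to(nest_x + 4.0, behavior.retreat_speed)
            dwell_rows.append(sc.dwell(rng.uniform(2.0, 3.5)))
            run_to_feeder()
        elif pause_out:
            x_p = rng.uniform(40.0, 90.0)
            sc.move_to(x_p, behavior.run_speed)
            p0, p1 = sc.dwell(rng.uniform(*behavior.pause_duration))
            pause_rows.append(
                {"lap": lap, "direction": "outbound",
                 "t_start": p0 / fs, "t_end": p1 / fs}
            )
            run_to_feeder()
        else:
            run_to_feeder()
        t_feeder = sc.t

        # --- far feeder dwell
        sc.dwell(rng.uniform(*behavior.feeder_dwell))

        # --- optional inbound return-to-feeder abort
        if rng.random() < behavior.inbound_mta_probability:
            x_turn = rng.uniform(geom.feeder_zone_start - 20.0,
                                 geom.feeder_zone_start - 8.0)
            leave_feeder(x_turn, behavior.run_speed)
            d0, d1 = sc.dwell(behavior.mta_turn_dwell)
            mta_rows.append(
                {"lap": lap, "direction": "inbound",
                 "t_turn": (d0 + d1) / 2.0 / fs, "x_turn": x_turn}
            )
            run_to_feeder()
            sc.dwell(0.8)

        # --- inbound run
        if rng.random() < behavior.pause_probability:
            x_p = rng.uniform(40.0, 90.0)
            leave_feeder(x_p, behavior.run_speed)
            p0, p1 = sc.dwell(rng.uniform(*behavior.pause_duration))
            pause_rows.append(
                {"lap": lap, "direction": "inbound",
                 "t_start": p0 / fs, "t_end": p1 / fs}
            )
            sc.move_to(nest_x, behavior.run_speed)
        else:
            leave_feeder(nest_x, behavior.run_speed)
        lap_rows.append({"lap": lap, "t_start": t_lap_start,
                         "t_feeder": t_feeder, "t_complete": sc.t})

    # final settle in the nest so the session ends in stillness
    dwell_rows.append(sc.dwell(2.0))

    xs = np.asarray(sc.x)
    ys = np.asarray(sc.y)
    vs = np.asarray(sc.v)
    n = len(xs)
    t = np.arange(n) / fs

    x_noisy = np.clip(xs + rng.normal(0.0, behavior.position_noise_sd, n),
                      0.0, geom.track_length)
    y_noisy = ys + rng.normal(0.0, behavior.position_noise_sd, n)
    traj = Trajectory(t=t, x=x_noisy, y=y_noisy)

    # --- hesitations: maximal nest+doorway occupancy intervals of the script,
    # excluding the session-boundary intervals (no entry from / exit to track)
    in_nest = xs < geom.doorway_end
    edges = np.flatnonzero(np.diff(in_nest.astype(int)))
    starts = edges[~in_nest[edges]] + 1    # False -> True transitions
    ends = edges[in_nest[edges]] + 1       # True -> False transitions (exclusive)
    # pair entries with the following exit; drop unpaired boundary intervals
    feeder_pos = np.array([geom.feeder_nest_x, geom.track_width / 2.0])
    dist_feeder = np.hypot(x_noisy - feeder_pos[0], y_noisy - feeder_pos[1])
    hes = []
    for s in starts:
        nxt = ends[ends > s]
        if len(nxt) == 0:
            continue
        e = int(nxt[0])
        dur = (e - s) / fs
        excl = np.count_nonzero(dist_feeder[s:e] <= 2.0) / fs
        lap_idx = int(np.searchsorted([r["t_complete"] for r in lap_rows], s / fs) + 1)
        hes.append({"t_start": s / fs, "t_end": e / fs,
                    "duration_excl": dur - excl, "lap": lap_idx})
    hesitations = pd.DataFrame(hes, columns=["t_start", "t_end", "duration_excl", "lap"])

    # --- attach exact track-interval bounds to scripted MTAs
    on_track = ~in_nest
    tr_edges = np.flatnonzero(np.diff(on_track.astype(int)))
    tr_starts = (tr_edges[~on_track[tr_edges]] + 1) / fs
    tr_ends = (tr_edges[on_track[tr_edges]] + 1) / fs
    for row in mta_rows:
        if row["direction"] == "outbound":
            i = int(np.searchsorted(tr_starts, row["t_turn"]) - 1)
            row["t_start"] = tr_starts[i] if i >= 0 else 0.0
            j = np.searchsorted(tr_ends, row["t_turn"])
            row["t_end"] = tr_ends[j] if j < len(tr_ends) else t[-1]
        else:
            # inbound aborts live inside a completed track interval; bound the
            # event by the dip below the feeder threshold around the turn
            below = xs < geom.feeder_zone_start
            k = int(round(row["t_turn"] * fs))
            s = k
            while s > 0 and below[s - 1]:
                s -= 1
            e = k
            while e < n - 1 and below[e + 1]:
                e += 1
            row["t_start"], row["t_end"] = s / fs, e / fs
    mtas = pd.DataFrame(
        mta_rows, columns=["lap", "direction", "t_turn", "x_turn", "t_start", "t_end"]
    )

    pauses = pd.DataFrame(pause_rows, columns=["lap", "direction", "t_start", "t_end"])
    laps_df = pd.DataFrame(lap_rows, columns=["lap", "t_start", "t_feeder", "t_complete"])

    # --- movement intervals from the scripted velocity
    moving = np.abs(vs) > 5.0
    mv_edges = np.flatnonzero(np.diff(moving.astype(int)))
    mv_starts = (mv_edges[~moving[mv_edges]] + 1) / fs
    mv_ends = (mv_edges[moving[mv_edges]] + 1) / fs
    if moving[0]:
        mv_starts = np.insert(mv_starts, 0, 0.0)
    if moving[-1]:
        mv_ends = np.append(mv_ends, t[-1] + 1.0 / fs)
    movement = np.column_stack([mv_starts, mv_ends])

    nest_dwells = np.array(
        [[(a + 1) / fs, b / fs] for a, b in dwell_rows if b - a >= int(0.5 * fs)]
    ).reshape(-1, 2)

    gt = GroundTruth(
        n_laps=len(laps_df),
        laps=laps_df,
        attack_laps=realized_attacks,
        attack_times=attack_times,
        hesitations=hesitations,
        mtas=mtas,
        pauses=pauses,
        movement_intervals=movement,
        nest_dwells=nest_dwells,
        theta_cycles=pd.DataFrame(columns=["t_peak", "t_trough", "t_end"]),
        event_windows=pd.DataFrame(
            columns=["t_start", "t_end", "content_x", "has_swr", "has_hse"]
        ),
    )
    # store the scripted velocity for downstream generators
    gt.scripted_velocity = vs  # type: ignore[attr-defined]
    return traj, gt


# --------------------------------------------------------------------------
# Theta cycle schedule and nest event windows
# --------------------------------------------------------------------------


def plan_theta_cycles(
    movement_intervals: np.ndarray,
    theta_cfg: ThetaConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Ground-truth theta cycle schedule covering the movement epochs.

    Each cycle runs peak -> trough (descending) -> next peak (ascending) with
    durations in the configured ascending:descending ratio.
    """
    r = theta_cfg.asymmetry_ratio
    rows = []
    for start, end in np.asarray(movement_intervals).reshape(-1, 2):
        tcur = start
        while True:
            f = theta_cfg.f0 + theta_cfg.freq_jitter * rng.standard_normal()
            f = max(f, 1.0)
            period = 1.0 / f
            desc = period / (1.0 + r)
            if tcur + period > end:
                break
            rows.append({"t_peak": tcur, "t_trough": tcur + desc,
                         "t_end": tcur + period})
            tcur += period
    return pd.DataFrame(rows, columns=["t_peak", "t_trough", "t_end"])


def schedule_nest_events(
    nest_dwells: np.ndarray,
    geom: ArenaGeometry,
    event_cfg: EventConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Schedule coincident SWR/HSE windows inside still nest dwells.

    Each window carries a content location (what the population burst
    encodes) and a threat flag: threat windows encode the robot-zone
    interior, ordinary windows encode safe-track or feeder locations.
    """
    rob_lo, rob_hi = geom.zone_bounds("robot")
    margin = event_cfg.threat_content_margin
    rows = []
    for start, end in np.asarray(nest_dwells).reshape(-1, 2):
        usable = (end - start) - 2 * event_cfg.edge_margin
        if usable <= event_cfg.duration[1]:
            continue
        k = rng.poisson(event_cfg.rate_per_dwell_second * usable)
        k = min(k, int(usable // (2 * event_cfg.duration[1])))
        if k == 0:
            continue
        anchors = np.sort(rng.uniform(0.0, 1.0, k))
        for a in anchors:
            dur = rng.uniform(*event_cfg.duration)
            t0 = start + event_cfg.edge_margin + a * (usable - dur)
            if rows and rows[-1]["t_end"] > t0 - 0.05 and rows[-1]["t_start"] >= start:
                continue  # keep windows in a dwell disjoint
            threat = bool(rng.random() < event_cfg.threat_probability)
            if threat:
                content = rng.uniform(rob_lo + 2.0, rob_hi - margin)
            elif rng.random() < event_cfg.reward_content_probability:
                content = rng.uniform(rob_hi + 2.0, geom.feeder_track_x)
            else:
                content = rng.uniform(geom.doorway_end + 2.0, rob_lo - margin)
            rows.append({
                "t_start": t0,
                "t_end": t0 + dur,
                "content_x": content,
                "threat": threat,
                "has_swr": bool(rng.random() < event_cfg.swr_probability),
                "has_hse": bool(rng.random() < event_cfg.hse_probability),
            })
    return pd.DataFrame(
        rows,
        columns=["t_start", "t_end", "content_x", "threat", "has_swr", "has_hse"],
    )


# --------------------------------------------------------------------------
# Place fields
# --------------------------------------------------------------------------


def generate_place_fields(
    n_cells: int,
    geom: ArenaGeometry,
    remap_fraction: float = 0.3,
    rng: np.random.Generator | None = None,
    field_cfg: FieldConfig | None = None,
) -> list[GenerativePlaceField]:
    """Generative fields.

    ``round(remap_fraction * n_cells)`` cells carry post-attack-only fields
    centered in the Robot or Robot-Side Track zones; these cells are
    spatially untuned before the first attack (new threat fields emerge
    largely from previously weakly tuned cells).  The remaining cells' fields
    evenly tile the running portion of the track — from just beyond the
    doorway to the far feeder — in both epochs.
    """
    if not 0.0 <= remap_fraction <= 1.0:
        raise ValueError("remap_fraction must lie in [0, 1]")
    if n_cells == 0:
        return []
    rng = rng or np.random.default_rng(0)
    fc = field_cfg or FieldConfig()

    n_remap = round(remap_fraction * n_cells)
    n_regular = n_cells - n_remap
    remap_cells = set(int(c) for c in rng.choice(n_cells, size=n_remap, replace=False))
    regular_cells = [c for c in range(n_cells) if c not in remap_cells]

    # fields tile from just beyond the doorway to the end wall (boundary
    # cells can sit slightly beyond the feeder the animal stops at)
    lo = geom.doorway_end + 2.0
    hi = geom.track_length - 1.0
    centers = lo + (np.arange(n_regular) + 0.5) / max(n_regular, 1) * (hi - lo)
    centers = centers + rng.uniform(-fc.center_jitter, fc.center_jitter, n_regular)
    centers = np.clip(centers, lo, hi)
    rng.shuffle(centers)
    prefs = rng.choice(
        ["outbound", "inbound", "both"], size=n_regular, p=fc.preference_weights
    )
    fields = [
        GenerativePlaceField(
            cell_id=cid,
            center=float(centers[i]),
            width=float(rng.uniform(*fc.width)),
            peak_rate=float(rng.uniform(*fc.peak_rate)),
            preference=str(prefs[i]),
        )
        for i, cid in enumerate(regular_cells)
    ]

    rob_lo, rob_hi = geom.zone_bounds("robot")
    for cid in sorted(remap_cells):
        # before the attack, threat cells carry broad low-rate tuning around
        # the far feeder (reward-approach activity); afterwards they express
        # a sharp robot-zone field: the representation trades the feeder for
        # the threat
        fields.append(
            GenerativePlaceField(
                cell_id=cid,
                center=float(rng.uniform(geom.feeder_zone_start + 1.0,
                                         geom.track_length - 2.0)),
                width=float(rng.uniform(*fc.approach_width)),
                peak_rate=float(rng.uniform(*fc.approach_rate)),
                preference="outbound",
            )
        )
        fields.append(
            GenerativePlaceField(
                cell_id=cid,
                center=float(rng.uniform(rob_lo + 2.0, rob_hi - 8.0)),
                width=float(rng.uniform(*fc.width)),
                peak_rate=float(rng.uniform(*fc.remap_peak_rate)),
                preference="both",
                post_attack_only=True,
            )
        )
    return fields


def _gauss(x: np.ndarray, c: float, w: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - c) / w) ** 2)


def _pref_matches(pref: str, dirsign: np.ndarray) -> np.ndarray:
    if pref == "outbound":
        return dirsign > 0
    if pref == "inbound":
        return dirsign < 0
    if pref == "both":
        return dirsign != 0
    return dirsign == 0  # stationary


def movement_rate(
    comps: list[GenerativePlaceField],
    x: np.ndarray,
    dirsign: np.ndarray,
    post_active: np.ndarray,
) -> np.ndarray:
    """Instantaneous field rate of one cell given position and direction."""
    out = np.zeros_like(x, dtype=float)
    for comp in comps:
        m = _pref_matches(comp.preference, dirsign)
        if comp.post_attack_only:
            m = m & post_active
        if not m.any():
            continue
        out[m] += comp.peak_rate * _gauss(x[m], comp.center, comp.width)
    return out


def content_rate(
    comps: list[GenerativePlaceField], content_x: float, extra_width: float = 0.0
) -> float:
    """Direction-agnostic field value of one cell at a replay content
    location, with an optional recruitment broadening (population bursts
    recruit cells with fields near, not only at, the content location).
    Post-attack-only components participate throughout: the threat-associated
    ensemble is expressed in nest events in both epochs."""
    if not comps:
        return 0.0
    return max(
        c.peak_rate * float(_gauss(
            np.array([content_x]), c.center,
            math.hypot(c.width, extra_width))[0])
        for c in comps
    )


def generative_tuning(
    fields: list[GenerativePlaceField],
    bin_centers: np.ndarray,
    baseline_rate: float = 0.2,
    epoch: str = "post",
) -> dict[int, np.ndarray]:
    """Expected (3, n_pos) rate map per cell, for parameter-recovery checks.

    Direction rows follow (toward_robot, stationary, toward_nest).  ``epoch``
    selects whether post-attack-only components contribute.
    """
    by_cell: dict[int, list[GenerativePlaceField]] = {}
    for f in fields:
        by_cell.setdefault(f.cell_id, []).append(f)
    dirsigns = np.array([1, 0, -1])
    out = {}
    for cid, comps in by_cell.items():
        m = np.full((3, len(bin_centers)), baseline_rate)
        for comp in comps:
            if comp.post_attack_only and epoch != "post":
                continue
            for row, ds in enumerate(dirsigns):
                if _pref_matches(comp.preference, np.array([ds]))[0]:
                    m[row] += comp.peak_rate * _gauss(bin_centers, comp.center, comp.width)
        out[cid] = m
    return out


# --------------------------------------------------------------------------
# Spike trains
# --------------------------------------------------------------------------


def generate_spike_trains(
    traj: Trajectory,
    fields: list[GenerativePlaceField],
    theta_cycles: pd.DataFrame,
    event_windows: pd.DataFrame,
    rng: np.random.Generator,
    spike_cfg: SpikeConfig | None = None,
    first_attack_time: float | None = None,
    scripted_velocity: np.ndarray | None = None,
) -> SpikeEnsemble:
    """Inhomogeneous Poisson emission from the generative fields.

    During movement, local field rates apply on the descending theta phase;
    on the ascending phase the field is evaluated ``lookahead_cm`` ahead of
    the animal (signed by running direction), emulating forward sweeps.
    During HSE windows each cell fires in proportion to its field value at
    the window's content location.  A small ungated baseline rate applies
    throughout.  Expected in-field spike count equals rate x occupancy time.
    """
    sc = spike_cfg or SpikeConfig()
    n_place = (max(f.cell_id for f in fields) + 1) if fields else 0
    by_cell: dict[int, list[GenerativePlaceField]] = {i: [] for i in range(n_place)}
    for f in fields:
        if f.cell_id not in by_cell:
            raise ValueError(f"field references unknown cell id {f.cell_id}")
        by_cell[f.cell_id].append(f)

    dt = sc.bin_ms / 1000.0
    t_end = traj.t[-1]
    n_bins = int(math.ceil(t_end / dt))
    t_ms = (np.arange(n_bins) + 0.5) * dt

    x_ms = np.interp(t_ms, traj.t, traj.x)
    if scripted_velocity is not None:
        v_ms = np.interp(t_ms, traj.t, scripted_velocity)
    else:
        v_ms = np.interp(t_ms, traj.t, np.gradient(traj.x, traj.t))
    dirsign = np.zeros(n_bins, dtype=np.int8)
    dirsign[v_ms > 5.0] = 1
    dirsign[v_ms < -5.0] = -1

    desc = np.zeros(n_bins, dtype=bool)
    asc = np.zeros(n_bins, dtype=bool)
    if len(theta_cycles):
        tp = theta_cycles["t_peak"].to_numpy()
        tt = theta_cycles["t_trough"].to_numpy()
        te = theta_cycles["t_end"].to_numpy()
        for a, b in zip(tp, tt):
            desc[int(a / dt): int(b / dt)] = True
        for a, b in zip(tt, te):
            asc[int(a / dt): int(b / dt)] = True

    post_active = (
        t_ms >= first_attack_time if first_attack_time is not None
        else np.zeros(n_bins, dtype=bool)
    )
    x_ahead = np.clip(x_ms + sc.lookahead_cm * dirsign, 0.0, None)

    hse_rows = (
        event_windows[event_windows["has_hse"]] if len(event_windows) else event_windows
    )

    spike_times: dict[int, np.ndarray] = {}
    ratio_rng = rng  # consumed in a fixed order: cells then metrics
    for cid in range(n_place):
        comps = by_cell[cid]
        rate = np.full(n_bins, sc.baseline_rate)
        rate[desc] += movement_rate(comps, x_ms[desc], dirsign[desc], post_active[desc])
        rate[asc] += movement_rate(comps, x_ahead[asc], dirsign[asc], post_active[asc])
        if len(hse_rows):
            for _, w in hse_rows.iterrows():
                if "threat" in hse_rows.columns:
                    if bool(w["threat"]):
                        # threat replay is carried by the threat ensemble
                        expr = [c for c in comps if c.post_attack_only]
                    else:
                        # ordinary replay expresses the stable spatial map;
                        # threat cells join through their reward-approach
                        # fields
                        expr = [c for c in comps if not c.post_attack_only]
                else:
                    expr = comps
                if not expr:
                    continue  # cell is not part of this event's ensemble
                amp = (sc.hse_gain
                       * content_rate(expr, float(w["content_x"]),
                                      sc.hse_content_width)
                       + sc.hse_population_rate)
                rate[int(w["t_start"] / dt): int(w["t_end"] / dt)] += amp
        counts = rng.poisson(rate * dt)
        hit = np.nonzero(counts)[0]
        reps = np.repeat(hit, counts[hit])
        times = reps * dt + rng.random(len(reps)) * dt
        spike_times[cid] = np.sort(times)

    # tonic interneurons (excluded by pyramidal classification downstream)
    inter_meta = []
    for j in range(sc.n_interneurons):
        cid = n_place + j
        r = float(rng.uniform(*sc.interneuron_rate))
        k = rng.poisson(r * t_end)
        spike_times[cid] = np.sort(rng.uniform(0.0, t_end, k))
        inter_meta.append((cid, float(rng.uniform(0.1, 0.35))))

    rows = []
    for cid in range(n_place):
        rows.append({
            "cell_id": cid,
            "mean_rate_hz": len(spike_times[cid]) / t_end,
            "peak_valley_ratio": float(ratio_rng.uniform(0.5, 0.95)),
        })
    for cid, ratio in inter_meta:
        rows.append({
            "cell_id": cid,
            "mean_rate_hz": len(spike_times[cid]) / t_end,
            "peak_valley_ratio": ratio,
        })
    metrics = pd.DataFrame(rows, columns=["cell_id", "mean_rate_hz", "peak_valley_ratio"])
    return SpikeEnsemble(spike_times=spike_times, metrics=metrics)


# --------------------------------------------------------------------------
# LFP
# --------------------------------------------------------------------------


def _pink_noise(n: int, fs: float, exponent: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phase)
    sig = np.fft.irfft(spec, n)
    sd = sig.std()
    return sig * (rms / sd) if sd > 0 else sig


def _theta_phase(n: int, fs: float, cycles: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous warped theta phase (0 at peaks, pi at troughs) and the
    gate marking samples inside a cycle."""
    phase = np.zeros(n)
    gate = np.zeros(n, dtype=bool)
    for tp, tt, te in cycles[["t_peak", "t_trough", "t_end"]].to_numpy():
        i0, i1, i2 = int(tp * fs), int(tt * fs), int(te * fs)
        i2 = min(i2, n)
        if i1 > i0:
            phase[i0:i1] = np.pi * (np.arange(i0, i1) / fs - tp) / (tt - tp)
        if i2 > i1:
            phase[i1:i2] = np.pi + np.pi * (np.arange(i1, i2) / fs - tt) / (te - tt)
        gate[i0:i2] = True
    return phase, gate


def generate_lfp(
    traj: Trajectory,
    event_windows: pd.DataFrame,
    rng: np.random.Generator,
    movement_intervals: np.ndarray,
    theta_cycles: pd.DataFrame,
    lfp_cfg: LFPConfig | None = None,
    theta_cfg: ThetaConfig | None = None,
) -> LFPSignal:
    """Composite multichannel LFP.

    Movement epochs carry the phase-warped theta waveform; stillness carries
    an elevated delta oscillation (LIA proxy).  All channels share a 1/f
    background; ripple bursts (tapered-cosine envelope, ~180 Hz) are injected
    into SWR-flagged event windows, strongest on the designated channel, with
    amplitude calibrated so the ripple-band envelope peaks near the
    configured z-score.
    """
    lc = lfp_cfg or LFPConfig()
    tc = theta_cfg or ThetaConfig()
    if lc.fs < 600.0:
        raise ValueError("LFP sampling rate must be >= 600 Hz for the ripple band")
    fs = lc.fs
    n = int(math.ceil(traj.t[-1] * fs))
    t = np.arange(n) / fs

    from scipy.ndimage import gaussian_filter1d

    phase, gate = _theta_phase(n, fs, theta_cycles)
    # taper the regime gates (~20 ms) so state transitions do not inject
    # broadband steps into the ripple band
    gate_sm = gaussian_filter1d(gate.astype(float), 0.02 * fs)
    theta_sig = tc.amplitude * np.cos(phase) * gate_sm

    still = np.ones(n, dtype=float)
    for a, b in np.asarray(movement_intervals).reshape(-1, 2):
        still[int(a * fs): int(b * fs)] = 0.0
    still_sm = gaussian_filter1d(still, 0.02 * fs)
    delta_sig = lc.delta_amplitude * np.sin(
        2.0 * np.pi * lc.delta_freq * t + rng.uniform(0.0, 2.0 * np.pi)
    ) * still_sm

    chans = np.empty((lc.n_channels, n))
    for c in range(lc.n_channels):
        bg = _pink_noise(n, fs, lc.noise_exponent, lc.noise_rms, rng)
        white = rng.normal(0.0, lc.white_rms, n)
        scale = rng.uniform(0.85, 1.15)
        chans[c] = bg + white + scale * (theta_sig + delta_sig)

    swr_rows = event_windows[event_windows["has_swr"]] if len(event_windows) else event_windows
    if len(swr_rows):
        # calibrate amplitude against the ripple-band envelope of the
        # ripple channel's background (pre-injection)
        ny = fs / 2.0
        b, a = signal.butter(4, [150.0 / ny, 250.0 / ny], btype="bandpass")
        base = signal.filtfilt(b, a, chans[lc.ripple_channel])
        env = np.abs(signal.hilbert(base))
        mu, sd = env.mean(), env.std()
        amp = mu + lc.ripple_amplitude_sd * sd
        for _, w in swr_rows.iterrows():
            i0, i1 = int(w["t_start"] * fs), int(w["t_end"] * fs)
            m = i1 - i0
            if m < 8:
                continue
            f_r = lc.ripple_freq + rng.uniform(-1, 1) * lc.ripple_freq_jitter
            tone = np.sin(2.0 * np.pi * f_r * (np.arange(m) / fs)
                          + rng.uniform(0.0, 2.0 * np.pi))
            envlp = signal.windows.tukey(m, alpha=0.5)
            burst = amp * envlp * tone
            chans[lc.ripple_channel, i0:i1] += burst
            for c in range(lc.n_channels):
                if c != lc.ripple_channel:
                    chans[c, i0:i1] += lc.off_channel_ripple_scale * burst
    return LFPSignal(samples=chans, fs=fs, channel_ids=list(range(lc.n_channels)))


# --------------------------------------------------------------------------
# Session composition
# --------------------------------------------------------------------------


def generate_session(
    cfg: TaskConfig,
    geom: ArenaGeometry | None = None,
    n_laps: int | None = None,
    n_cells: int = 50,
    remap_fraction: float = 0.3,
    behavior: TrajectoryConfig | None = None,
    field_cfg: FieldConfig | None = None,
    spike_cfg: SpikeConfig | None = None,
    theta_cfg: ThetaConfig | None = None,
    lfp_cfg: LFPConfig | None = None,
    event_cfg: EventConfig | None = None,
    include_lfp: bool = True,
) -> SyntheticSession:
    """Compose trajectory, fields, spikes and LFP into one session.

    All randomness derives from labeled streams of ``cfg.seed``; equal
    configurations and seeds produce identical sessions.
    """
    geom = geom or ArenaGeometry()
    theta_cfg = theta_cfg or ThetaConfig()
    event_cfg = event_cfg or EventConfig()

    traj, gt = generate_trajectory(
        cfg, geom, behavior=behavior, n_laps=n_laps,
        rng=derive_rng(cfg.seed, "trajectory"),
    )
    gt.theta_cycles = plan_theta_cycles(
        gt.movement_intervals, theta_cfg, derive_rng(cfg.seed, "theta")
    )
    gt.event_windows = schedule_nest_events(
        gt.nest_dwells, geom, event_cfg, derive_rng(cfg.seed, "events")
    )
    gt.fields = generate_place_fields(
        n_cells, geom, remap_fraction, derive_rng(cfg.seed, "fields"), field_cfg
    )
    spikes = generate_spike_trains(
        traj, gt.fields, gt.theta_cycles, gt.event_windows,
        derive_rng(cfg.seed, "spikes"), spike_cfg,
        first_attack_time=gt.first_attack_time,
        scripted_velocity=getattr(gt, "scripted_velocity", None),
    )
    lfp = None
    if include_lfp:
        lfp = generate_lfp(
            traj, gt.event_windows, derive_rng(cfg.seed, "lfp"),
            gt.movement_intervals, gt.theta_cycles, lfp_cfg, theta_cfg,
        )
    return SyntheticSession(
        trajectory=traj, spikes=spikes, lfp=lfp, ground_truth=gt,
        task=cfg, geometry=geom,
    )
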