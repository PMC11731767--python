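"""Behavioral event classification on the L-maze.

Segments the position trace into journeys and laps, and detects the three
approach-avoidance ("worry") behaviors: hesitations in the nest/doorway,
mid-track aborts (MTAs), and on-track pauses.  Also provides the yoked
pre/post split used to compare attack sessions with control sessions, and
within-subject z-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import ArenaGeometry, Trajectory

JOURNEY_COLUMNS = [
    "journey", "lap", "direction", "t_start", "t_end",
    "completed", "contains_attack",
]
EVENT_COLUMNS = ["kind", "t_start", "t_end", "lap", "direction", "duration", "flag"]


@dataclass(frozen=True)
class BehaviorConfig:
    """Detection thresholds.

    MTAs require ``mta_min_track_time`` seconds on the track and a
    ``mta_min_distance`` cm excursion beyond the doorway; pauses are
    < ``pause_max_displacement`` cm of long-axis motion (after a
    ``pause_lowpass_cutoff`` Hz zero-phase low-pass) for more than
    ``pause_min_duration`` s; hesitation durations omit time within
    ``feeder_exclusion_radius`` cm of the nest feeder.
    """

    feeder_exclusion_radius: float = 2.0
    mta_min_track_time: float = 0.5
    mta_min_distance: float = 5.0
    pause_lowpass_cutoff: float = 2.0
    pause_max_displacement: float = 1.0
    pause_min_duration: float = 0.5
    max_bridge_gap: float = 0.5   # s of tracking loss bridged by interpolation
    turn_speed_eps: float = 2.0   # cm/s deadband for the head-turn proxy


def bridge_tracking(traj: Trajectory, max_gap: float = 0.5):
    """Interpolate tracking-loss samples up to ``max_gap`` seconds.

    Returns the repaired trajectory and an (n, 2) array of longer loss
    intervals that remain uncertain.
    """
    tracked = traj.tracked.copy()
    x, y = traj.x.copy(), traj.y.copy()
    if tracked.all():
        return Trajectory(traj.t, x, y, tracked), np.empty((0, 2))
    lost = ~tracked
    edges = np.flatnonzero(np.diff(lost.astype(int)))
    starts = edges[~lost[edges]] + 1
    ends = edges[lost[edges]] + 1
    if lost[0]:
        starts = np.insert(starts, 0, 0)
    if lost[-1]:
        ends = np.append(ends, len(lost))
    uncertain = []
    good = tracked.nonzero()[0]
    for s, e in zip(starts, ends):
        if traj.t[min(e, len(lost) - 1)] - traj.t[max(s - 1, 0)] <= max_gap and len(good):
            idx = np.arange(s, e)
            x[idx] = np.interp(traj.t[idx], traj.t[good], traj.x[good])
            y[idx] = np.interp(traj.t[idx], traj.t[good], traj.y[good])
            tracked[idx] = True
        else:
            uncertain.append([traj.t[s], traj.t[min(e, len(lost) - 1)]])
    return Trajectory(traj.t, x, y, tracked), np.asarray(uncertain).reshape(-1, 2)


def _maximal_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs of maximal True runs; end is exclusive."""
    m = mask.astype(int)
    edges = np.flatnonzero(np.diff(m))
    starts = list(edges[m[edges] == 0] + 1)
    ends = list(edges[m[edges] == 1] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def segment_journeys(
    traj: Trajectory,
    geom: ArenaGeometry,
    attack_times: np.ndarray | list[float] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Split the trajectory into outbound/inbound journeys and count laps.

    A track entry begins when the animal leaves the nest+doorway region.  If
    the entry reaches the far feeder threshold it yields a completed outbound
    journey (entry to first feeder crossing) and a completed inbound journey
    (last feeder crossing back to the nest), and increments the lap count;
    otherwise it yields a single incomplete outbound journey (an abort or
    attack retreat).
    """
    attack_times = np.asarray(attack_times if attack_times is not None else [])
    x, t = traj.x, traj.t
    on_track = x >= geom.doorway_end
    rows = []
    lap = 0
    jid = 0
    for s, e in _maximal_runs(on_track):
        if s == 0:
            continue  # session started on the track; not an entry
        seg = x[s:e]
        tseg = t[s:e]
        has_attack = bool(
            len(attack_times)
            and np.any((attack_times >= tseg[0]) & (attack_times <= tseg[-1]))
        )
        at_feeder = seg >= geom.feeder_zone_start
        if at_feeder.any():
            lap += 1
            i_feed = int(np.argmax(at_feeder))
            j_feed = len(seg) - 1 - int(np.argmax(at_feeder[::-1]))
            out_attack = bool(
                len(attack_times)
                and np.any((attack_times >= tseg[0]) & (attack_times <= tseg[i_feed]))
            )
            rows.append({
                "journey": jid, "lap": lap, "direction": "outbound",
                "t_start": tseg[0], "t_end": tseg[i_feed],
                "completed": True, "contains_attack": out_attack,
            })
            jid += 1
            rows.append({
                "journey": jid, "lap": lap, "direction": "inbound",
                "t_start": tseg[j_feed], "t_end": tseg[-1],
                "completed": e < len(x),
                "contains_attack": bool(
                    len(attack_times)
                    and np.any((attack_times >= tseg[j_feed]) & (attack_times <= tseg[-1]))
                ),
            })
            jid += 1
        else:
            rows.append({
                "journey": jid, "lap": lap + 1, "direction": "outbound",
                "t_start": tseg[0], "t_end": tseg[-1],
                "completed": False, "contains_attack": has_attack,
            })
            jid += 1
    return pd.DataFrame(rows, columns=JOURNEY_COLUMNS), lap


def measure_hesitation(
    traj: Trajectory,
    geom: ArenaGeometry,
    cfg: BehaviorConfig | None = None,
    uncertain_intervals: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Hesitation events: contiguous nest+doorway occupancy entered from the
    track and exited onto it.

    Reported durations omit time within ``feeder_exclusion_radius`` of the
    nest feeder.  Returns the events plus a time-accounting dict (hesitation,
    feeder-excluded, on-track, and session-boundary nest time sum to the
    session duration within one sample per boundary).
    """
    cfg = cfg or BehaviorConfig()
    x, y, t = traj.x, traj.y, traj.t
    dt = traj.dt
    in_nest = x < geom.doorway_end
    dist = np.hypot(x - geom.feeder_nest_x, y - geom.track_width / 2.0)
    near_feeder = dist <= cfg.feeder_exclusion_radius
    uncertain_intervals = (
        np.empty((0, 2)) if uncertain_intervals is None else uncertain_intervals
    )

    rows = []
    boundary_time = 0.0
    feeder_excl_total = 0.0
    for s, e in _maximal_runs(in_nest):
        dur = (e - s) * dt
        if s == 0 or e == len(x):
            boundary_time += dur
            continue
        excl = float(np.count_nonzero(near_feeder[s:e])) * dt
        feeder_excl_total += excl
        flag = "ok"
        for a, b in uncertain_intervals:
            if a < t[e - 1] and b > t[s]:
                flag = "uncertain"
        rows.append({
            "kind": "hesitation", "t_start": t[s], "t_end": t[e - 1] + dt,
            "lap": -1, "direction": "", "duration": dur - excl, "flag": flag,
        })
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    accounting = {
        "hesitation": float(events["duration"].sum()) if len(events) else 0.0,
        "feeder_excluded": feeder_excl_total,
        "track": float(np.count_nonzero(~in_nest)) * dt,
        "session_boundary_nest": boundary_time,
        "total": len(x) * dt,
    }
    return events, accounting


def _smoothed_velocity(traj: Trajectory, cutoff: float) -> np.ndarray:
    fs = 1.0 / traj.dt
    b, a = signal.butter(3, cutoff / (fs / 2.0), btype="lowpass")
    xf = signal.filtfilt(b, a, traj.x)
    return np.gradient(xf, traj.t)


def detect_mtas(
    traj: Trajectory,
    journeys: pd.DataFrame,
    attack_times: np.ndarray | list[float] | None,
    cfg: BehaviorConfig | None = None,
    geom: ArenaGeometry | None = None,
) -> pd.DataFrame:
    """Mid-track aborts: track entries that return to the door.

    Outbound MTAs are incomplete journeys that spent at least
    ``mta_min_track_time`` on the track and penetrated at least
    ``mta_min_distance`` beyond the doorway; journeys containing an attack
    (retreats from attacks) are excluded.  The event time is a head-turn
    proxy: the first sample where the smoothed along-track velocity changes
    sign inside the abort.  Inbound MTAs (return-to-feeder reorientations)
    use the same distance/time criteria on dips below the feeder threshold,
    without the turn-time refinement.
    """
    cfg = cfg or BehaviorConfig()
    geom = geom or ArenaGeometry()
    x, t = traj.x, traj.t
    v = _smoothed_velocity(traj, cfg.pause_lowpass_cutoff)
    rows = []

    incomplete = journeys[
        (~journeys["completed"]) & (journeys["direction"] == "outbound")
    ]
    for _, j in incomplete.iterrows():
        if j["contains_attack"]:
            continue
        s = int(np.searchsorted(t, j["t_start"]))
        e = int(np.searchsorted(t, j["t_end"], side="right"))
        dur = j["t_end"] - j["t_start"]
        depth = float(np.max(x[s:e]) - geom.doorway_end)
        if dur < cfg.mta_min_track_time or depth < cfg.mta_min_distance:
            continue
        vseg = v[s:e]
        # head-turn proxy: first sample whose smoothed velocity goes negative
        # after the outbound advance
        adv = np.flatnonzero(vseg > cfg.turn_speed_eps)
        t_turn = j["t_start"]
        if len(adv):
            after = np.flatnonzero(vseg[adv[0]:] < -cfg.turn_speed_eps)
            if len(after):
                t_turn = t[s + adv[0] + after[0]]
        rows.append({
            "kind": "mta", "t_start": j["t_start"], "t_end": j["t_end"],
            "lap": int(j["lap"]), "direction": "outbound",
            "duration": dur, "flag": f"turn={t_turn:.3f}",
        })

    # inbound return-to-feeder aborts: dips below the feeder threshold inside
    # the far-feeder span of completed laps
    comp = journeys[journeys["completed"]]
    attack_times = np.asarray(attack_times if attack_times is not None else [])
    for lap_id, grp in comp.groupby("lap"):
        if {"outbound", "inbound"} - set(grp["direction"]):
            continue
        t_out_end = float(grp[grp["direction"] == "outbound"]["t_end"].iloc[0])
        t_in_start = float(grp[grp["direction"] == "inbound"]["t_start"].iloc[0])
        s = int(np.searchsorted(t, t_out_end))
        e = int(np.searchsorted(t, t_in_start, side="right"))
        if e - s < 2:
            continue
        below = x[s:e] < geom.feeder_zone_start
        for a, b in _maximal_runs(below) if below.any() else []:
            dur = (b - a) * traj.dt
            depth = geom.feeder_zone_start - float(np.min(x[s + a: s + b]))
            if dur < cfg.mta_min_track_time or depth < cfg.mta_min_distance:
                continue
            if len(attack_times) and np.any(
                (attack_times >= t[s + a]) & (attack_times <= t[s + b - 1])
            ):
                continue
            rows.append({
                "kind": "mta", "t_start": t[s + a], "t_end": t[s + b - 1],
                "lap": int(lap_id), "direction": "inbound",
                "duration": dur, "flag": "ok",
            })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def detect_pauses(
    traj: Trajectory,
    journeys: pd.DataFrame,
    cfg: BehaviorConfig | None = None,
) -> pd.DataFrame:
    """On-track pauses: maximal intervals of a journey during which the
    low-pass-filtered long-axis position moves by less than
    ``pause_max_displacement`` for longer than ``pause_min_duration``."""
    cfg = cfg or BehaviorConfig()
    fs = 1.0 / traj.dt
    b, a = signal.butter(3, cfg.pause_lowpass_cutoff / (fs / 2.0), btype="lowpass")
    xf = signal.filtfilt(b, a, traj.x)
    t = traj.t
    rows = []
    for _, j in journeys.iterrows():
        s = int(np.searchsorted(t, j["t_start"]))
        e = int(np.searchsorted(t, j["t_end"], side="right"))
        i = s
        while i < e - 1:
            lo = hi = xf[i]
            k = i
            while k + 1 < e:
                nlo, nhi = min(lo, xf[k + 1]), max(hi, xf[k + 1])
                if nhi - nlo >= cfg.pause_max_displacement:
                    break
                lo, hi = nlo, nhi
                k += 1
            if t[k] - t[i] > cfg.pause_min_duration:
                rows.append({
                    "kind": "pause", "t_start": t[i], "t_end": t[k],
                    "lap": int(j["lap"]), "direction": j["direction"],
                    "duration": t[k] - t[i], "flag": "ok",
                })
                i = k + 1
            else:
                i += 1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def yoke_split(
    attack_first_laps: list[int],
    non_attack_sessions: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each non-attack session a pre/post split lap drawn by seeded
    permutation from the attack sessions' first-attack laps."""
    if len(attack_first_laps) != len(non_attack_sessions):
        raise ValueError(
            f"need equal session counts: {len(attack_first_laps)} attack first-laps "
            f"vs {len(non_attack_sessions)} non-attack sessions"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(attack_first_laps))
    return pd.DataFrame({
        "session_id": list(non_attack_sessions),
        "split_lap": [int(attack_first_laps[i]) for i in perm],
        "provenance": "yoked",
    })


def normalize_by_subject(values: pd.DataFrame, value_col: str = "value",
                         subject_col: str = "subject") -> pd.DataFrame:
    """Within-subject z-scores: subtract the subject mean, divide by the
    subject SD (n-1 denominator)."""
    out = values.copy()
    for subject, grp in values.groupby(subject_col):
        if len(grp) < 2:
            raise ValueError(f"subject {subject!r} has fewer than 2 values")
        sd = grp[value_col].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"subject {subject!r} has zero within-subject spread")
        out.loc[grp.index, value_col] = (grp[value_col] - grp[value_col].mean()) / sd
    return out
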