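"""Session-bundle I/O and end-to-end orchestration.

A session bundle on disk is a directory with::

    positions.csv     t_s, x_cm, y_cm, tracked
    spikes.csv        cell_id, t_s
    cells.csv         cell_id, mean_rate_hz, peak_valley_ratio
    lfp.h5            one dataset per channel (µV), attrs: fs_hz, t0_s
    session.yaml      session type, subject, seed, attack lap/time log
    ground_truth.json synthetic ground truth (optional, synthetic bundles)

``run_session`` executes behavior -> LFP state -> transients -> tuning ->
decoding in dependency order, skipping stages whose preconditions fail (for
example fewer than 10 pyramidal cells) with an explicit report entry.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import lfpstate, transients, tuning
from . import decoder as dec
from .core import ArenaGeometry, LFPSignal, SpikeEnsemble, Trajectory
from .synthgen import SyntheticSession

logger = logging.getLogger("lmaze")

__version__ = "0.1.0"


@dataclass
class SessionBundle:
    path: Path
    session_type: str
    subject: str
    trajectory: Trajectory
    spikes: SpikeEnsemble
    lfp: LFPSignal | None
    metadata: dict
    ground_truth: dict | None = None

    @property
    def attack_times(self) -> list[float]:
        return list(self.metadata.get("attack_times", []))

    @property
    def attack_laps(self) -> list[int]:
        return list(self.metadata.get("attack_laps", []))


@dataclass
class AnalysisReport:
    session_id: str
    scalars: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)     # name -> DataFrame
    skipped: dict = field(default_factory=dict)    # stage -> reason
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "scalars": _jsonify(self.scalars),
            "tables": {k: _jsonify(v.to_dict(orient="list")) for k, v in self.tables.items()},
            "skipped": dict(self.skipped),
            "provenance": dict(self.provenance),
        }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(_jsonify(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def default_config() -> dict:
    """All analysis thresholds under named keys, at their standard values."""
    return {
        "behavior": {
            "feeder_exclusion_radius": 2.0,
            "mta_min_track_time": 0.5,
            "mta_min_distance": 5.0,
            "pause_lowpass_cutoff": 2.0,
            "pause_max_displacement": 1.0,
            "pause_min_duration": 0.5,
        },
        "state": {"threshold": 0.5, "bin_length": 1.0},
        "swr": {"z_threshold": 4.0, "min_duration": 0.020},
        "hse": {"z_threshold": 3.0, "min_duration": 0.020, "max_duration": 0.750},
        "tuning": {"n_pos": 64, "min_spikes": 10, "stationary_band": 5.0},
        "decoder": {"min_ensemble": 10, "rate_floor": 0.01},
        "max_theta_cycles": 3000,
    }


# --------------------------------------------------------------------------
# Bundle I/O
# --------------------------------------------------------------------------


def write_bundle(session: SyntheticSession, path: str | Path,
                 subject: str = "synthetic") -> Path:
    """Write a synthetic session to disk in the bundle layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trajectory.to_frame().to_csv(path / "positions.csv", index=False)
    session.spikes.to_frame().to_csv(path / "spikes.csv", index=False)
    session.spikes.metrics.to_csv(path / "cells.csv", index=False)

    if session.lfp is not None:
        with h5py.File(path / "lfp.h5", "w") as f:
            f.attrs["fs_hz"] = session.lfp.fs
            f.attrs["t0_s"] = session.lfp.t0
            for i, cid in enumerate(session.lfp.channel_ids):
                f.create_dataset(f"ch_{cid:02d}", data=session.lfp.samples[i])

    gt = session.ground_truth
    meta = {
        "session_type": session.task.session_type,
        "subject": subject,
        "seed": session.task.seed,
        "attack_laps": list(gt.attack_laps),
        "attack_times": [float(t) for t in gt.attack_times],
        "n_laps": int(gt.n_laps),
        "zone_edges": list(session.geometry.zone_edges),
        "position_rate": session.geometry.position_rate,
    }
    (path / "session.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))

    gt_json = {
        "n_laps": int(gt.n_laps),
        "attack_laps": list(gt.attack_laps),
        "attack_times": [float(t) for t in gt.attack_times],
        "laps": gt.laps.to_dict(orient="list"),
        "hesitations": gt.hesitations.to_dict(orient="list"),
        "mtas": gt.mtas.to_dict(orient="list"),
        "pauses": gt.pauses.to_dict(orient="list"),
        "movement_intervals": gt.movement_intervals.tolist(),
        "nest_dwells": gt.nest_dwells.tolist(),
        "event_windows": gt.event_windows.to_dict(orient="list"),
        "theta_cycles": gt.theta_cycles.to_dict(orient="list"),
        "fields": [vars(f) for f in gt.fields],
    }
    (path / "ground_truth.json").write_text(json.dumps(_jsonify(gt_json)))
    return path


def read_bundle(path: str | Path) -> SessionBundle:
    """Load and validate a session bundle; schema violations name the file
    and offending column/line."""
    path = Path(path)
    problems = []
    for fname in ("positions.csv", "spikes.csv", "cells.csv", "session.yaml"):
        if not (path / fname).exists():
            problems.append(f"{fname}: missing")
    if problems:
        raise ValueError("invalid bundle: " + "; ".join(problems))

    meta = yaml.safe_load((path / "session.yaml").read_text())
    pos = pd.read_csv(path / "positions.csv")
    for col in ("t_s", "x_cm", "y_cm"):
        if col not in pos.columns:
            problems.append(f"positions.csv: missing column {col}")
    if not problems:
        bad = np.flatnonzero(np.diff(pos["t_s"].to_numpy()) <= 0)
        if len(bad):
            problems.append(
                f"positions.csv: non-monotone t_s at line {int(bad[0]) + 2}"
            )
    spk = pd.read_csv(path / "spikes.csv")
    for col in ("cell_id", "t_s"):
        if col not in spk.columns:
            problems.append(f"spikes.csv: missing column {col}")
    cells = pd.read_csv(path / "cells.csv")
    for col in ("cell_id", "mean_rate_hz", "peak_valley_ratio"):
        if col not in cells.columns:
            problems.append(f"cells.csv: missing column {col}")
    if problems:
        raise ValueError("invalid bundle: " + "; ".join(problems))

    tracked = pos["tracked"].to_numpy(bool) if "tracked" in pos.columns else None
    traj = Trajectory(pos["t_s"].to_numpy(), pos["x_cm"].to_numpy(),
                      pos["y_cm"].to_numpy(), tracked)
    spike_times = {
        int(cid): np.sort(grp["t_s"].to_numpy())
        for cid, grp in spk.groupby("cell_id")
    }
    for cid in cells["cell_id"].astype(int):
        spike_times.setdefault(int(cid), np.array([]))
    spikes = SpikeEnsemble(spike_times=spike_times, metrics=cells)

    lfp = None
    if (path / "lfp.h5").exists():
        with h5py.File(path / "lfp.h5", "r") as f:
            if "fs_hz" not in f.attrs:
                raise ValueError("invalid bundle: lfp.h5 missing fs_hz attribute")
            keys = sorted(f.keys())
            samples = np.stack([f[k][()] for k in keys])
            lfp = LFPSignal(
                samples=samples, fs=float(f.attrs["fs_hz"]),
                channel_ids=[int(k.split("_")[1]) for k in keys],
                t0=float(f.attrs.get("t0_s", 0.0)),
            )

    gt = None
    if (path / "ground_truth.json").exists():
        gt = json.loads((path / "ground_truth.json").read_text())

    return SessionBundle(
        path=path, session_type=meta.get("session_type", "linear_track"),
        subject=meta.get("subject", "unknown"), trajectory=traj,
        spikes=spikes, lfp=lfp, metadata=meta, ground_truth=gt,
    )


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------


def _geometry_from(meta: dict) -> ArenaGeometry:
    kwargs = {}
    if "zone_edges" in meta:
        kwargs["zone_edges"] = tuple(meta["zone_edges"])
        kwargs["track_length"] = float(meta["zone_edges"][-1])
    if "position_rate" in meta:
        kwargs["position_rate"] = float(meta["position_rate"])
    return ArenaGeometry(**kwargs)


def run_session(
    bundle: SessionBundle,
    config: dict | None = None,
    seed: int = 0,
    yoke_lap: int | None = None,
) -> AnalysisReport:
    """Run every analysis stage on one session bundle.

    ``yoke_lap`` supplies the pre/post split lap for non-attack sessions; on
    attack sessions the split is the first attack.  Stages whose
    preconditions fail are recorded under ``skipped``, never silently
    omitted.
    """
    config = config or default_config()
    geom = _geometry_from(bundle.metadata)
    report = AnalysisReport(session_id=str(bundle.path))
    report.provenance = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "lmaze_version": __version__,
        "numpy_version": np.__version__,
    }

    # ---- behavior -------------------------------------------------------
    bcfg = beh.BehaviorConfig(**config["behavior"])
    traj, uncertain = beh.bridge_tracking(bundle.trajectory, bcfg.max_bridge_gap)
    attack_times = np.asarray(bundle.attack_times)
    journeys, n_laps = beh.segment_journeys(traj, geom, attack_times)
    hesitations, accounting = beh.measure_hesitation(traj, geom, bcfg, uncertain)
    mtas = beh.detect_mtas(traj, journeys, attack_times, bcfg, geom)
    pauses = beh.detect_pauses(traj, journeys, bcfg)
    logger.info("behavior: %d laps, %d journeys, %d hesitations, %d MTAs, %d pauses",
                n_laps, len(journeys), len(hesitations), len(mtas), len(pauses))
    report.tables["journeys"] = journeys
    report.tables["behavior_events"] = pd.concat(
        [hesitations, mtas, pauses], ignore_index=True
    )
    report.scalars.update({
        "n_laps": n_laps,
        "n_hesitations": len(hesitations),
        "n_mtas": len(mtas),
        "n_pauses": len(pauses),
        "hesitation_total_s": accounting["hesitation"],
    })

    # ---- pre/post split -------------------------------------------------
    if bundle.session_type == "attack" and len(attack_times):
        split_time = float(attack_times[0])
        report.scalars["split_provenance"] = "first_attack"
    elif yoke_lap is not None and len(journeys):
        lap_rows = journeys[journeys["lap"] == yoke_lap]
        split_time = float(lap_rows["t_start"].min()) if len(lap_rows) \
            else float(traj.t[-1])
        report.scalars["split_provenance"] = "yoked"
    else:
        split_time = float(traj.t[-1])
        report.scalars["split_provenance"] = "none"
    report.scalars["split_time_s"] = split_time
    t_end = float(traj.t[-1])

    # ---- LFP state ------------------------------------------------------
    state = None
    theta_cycles = pd.DataFrame()
    swr_channel = None
    if bundle.lfp is not None:
        lfp = lfpstate.preprocess_lfp(bundle.lfp)
        swr_channel = transients.select_swr_channel(lfp)[0]
        state = lfpstate.classify_state(
            lfp, channel=swr_channel,
            threshold=config["state"]["threshold"],
            bin_length=config["state"]["bin_length"],
        )
        theta_cycles = lfpstate.segment_theta_cycles(lfp, state=state,
                                                     channel=swr_channel)
        report.tables["theta_cycles"] = theta_cycles
        report.scalars.update({
            "swr_channel": int(swr_channel),
            "theta_fraction": float(state.is_theta.mean()),
            "n_theta_cycles": len(theta_cycles),
            "median_asymmetry": float(theta_cycles["asymmetry"].median())
            if len(theta_cycles) else np.nan,
        })
    else:
        report.skipped["lfpstate"] = "bundle has no LFP"

    # ---- transients -----------------------------------------------------
    pyramidal = tuning.classify_pyramidal(bundle.spikes.metrics)
    pyr_ids = [int(c) for c in
               bundle.spikes.metrics.loc[pyramidal, "cell_id"]]
    report.scalars["n_pyramidal"] = len(pyr_ids)

    swrs = pd.DataFrame(columns=transients.EVENT_COLUMNS)
    if bundle.lfp is not None:
        swrs = transients.detect_swrs(
            lfp, transients.SWRDetectorConfig(
                z_threshold=config["swr"]["z_threshold"],
                min_duration=config["swr"]["min_duration"],
            ), channel=swr_channel,
        )
    hses = pd.DataFrame(columns=transients.EVENT_COLUMNS)
    if pyr_ids:
        hses = transients.detect_hses(
            bundle.spikes, transients.HSEDetectorConfig(
                z_threshold=config["hse"]["z_threshold"],
                min_duration=config["hse"]["min_duration"],
                max_duration=config["hse"]["max_duration"],
            ), duration=t_end, cell_ids=pyr_ids,
        )
    else:
        report.skipped["hse_detection"] = "no putative pyramidal cells"
    report.tables["swr_events"] = swrs
    report.tables["hse_events"] = hses
    overlap = transients.overlap_summary(swrs, hses)
    report.scalars.update({
        "n_swrs": len(swrs), "n_hses": len(hses),
        "pct_swr_overlapping": overlap["pct_swr_overlapping"],
        "pct_hse_overlapping": overlap["pct_hse_overlapping"],
        "swr_rate_pre": float((swrs["t_start"] < split_time).sum())
        / max(split_time, 1e-9),
        "swr_rate_post": float((swrs["t_start"] >= split_time).sum())
        / max(t_end - split_time, 1e-9),
    })
    logger.info("transients: %d SWRs, %d HSEs", len(swrs), len(hses))

    # ---- tuning ---------------------------------------------------------
    grid = tuning.TuningBinGrid(track_length=geom.track_length,
                                n_pos=config["tuning"]["n_pos"])
    curves_pre = curves_post = None
    if not pyr_ids:
        report.skipped["tuning"] = "no putative pyramidal cells"
    elif not len(theta_cycles):
        report.skipped["tuning"] = "no theta cycles available"
    else:
        try:
            curves_pre = tuning.build_tuning_curves(
                bundle.spikes, traj, theta_cycles, state, grid,
                epoch=(0.0, split_time), cell_ids=pyr_ids, epoch_label="pre",
                stationary_band=config["tuning"]["stationary_band"],
            )
            curves_post = tuning.build_tuning_curves(
                bundle.spikes, traj, theta_cycles, state, grid,
                epoch=(split_time, t_end + 1.0), cell_ids=pyr_ids,
                epoch_label="post",
                stationary_band=config["tuning"]["stationary_band"],
            )
            shift = tuning.compute_tuning_shift(
                curves_pre, curves_post, geom,
                min_spikes=config["tuning"]["min_spikes"],
            )
            report.tables["tuning_shift_zones"] = shift.zones
            report.scalars["n_cells_in_shift"] = shift.n_cells_used
        except ValueError as exc:
            report.skipped["tuning"] = str(exc)

    # ---- decoding -------------------------------------------------------
    dcfg = dec.DecoderConfig(**config["decoder"])
    if len(pyr_ids) < dcfg.min_ensemble:
        report.skipped["decoding"] = (
            f"{len(pyr_ids)} pyramidal cells < minimum ensemble of "
            f"{dcfg.min_ensemble}"
        )
    elif curves_pre is None or curves_post is None:
        report.skipped["decoding"] = "tuning curves unavailable"
    else:
        events, table = dec.decode_hse_events(
            hses, bundle.spikes, curves_pre, curves_post, split_time,
            traj, geom, dcfg, state=state,
        )
        report.tables["hse_decoding"] = events
        report.tables["cross_decoding"] = table

        cycles = theta_cycles
        cap = int(config.get("max_theta_cycles", 3000))
        if len(cycles) > cap:
            step = len(cycles) / cap
            cycles = cycles.iloc[(np.arange(cap) * step).astype(int)]
        curves_whole = tuning.build_tuning_curves(
            bundle.spikes, traj, theta_cycles, state, grid,
            cell_ids=pyr_ids, epoch_label="whole",
            stationary_band=config["tuning"]["stationary_band"],
        )
        cycle_df, maps = dec.decode_theta_cycles(
            cycles, bundle.spikes, curves_whole, traj, dcfg)
        report.tables["theta_decoding"] = cycle_df
        if len(cycle_df):
            report.scalars.update({
                "theta_median_err_desc_cm": float(
                    (cycle_df["com_desc"] - cycle_df["pos"]).abs().median()),
                "theta_mean_ahead_asc_cm": float(cycle_df["ahead_asc"].mean()),
            })
    return report


def write_report(report: AnalysisReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    return path


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
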