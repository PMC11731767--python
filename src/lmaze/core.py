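"""Shared data containers for L-maze session analysis.

The task arena is an L-shaped linear track: a nest at one end, a food feeder
at the far end, and a robot bay guarding the approach to the far feeder.
Positions are expressed in cm along the track long axis (x), with the nest at
x = 0 and the far feeder at x = track_length.  All times are seconds from
session start.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Canonical zone names, ordered from the nest to the far feeder.
ZONE_NAMES = (
    "nest",
    "doorway",
    "nest_side_track",
    "robot_side_track",
    "robot",
    "feeder",
)

# Direction bins for tuning/decoding: movement toward the robot end (+x),
# stationary, movement toward the nest (-x).
DIRECTIONS = ("toward_robot", "stationary", "toward_nest")

OUTBOUND, INBOUND = "outbound", "inbound"


def derive_rng(master_seed: int, label: str) -> np.random.Generator:
    """Deterministic per-component random stream from one master seed.

    Each component (trajectory, spikes, LFP, ...) draws from its own labeled
    stream so that regenerating one component never perturbs the others.
    """
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


@dataclass(frozen=True)
class ArenaGeometry:
    """Zone layout of the L-maze along its long axis.

    Default boundaries are proportional to the published arena dimensions
    (19 cm nest, 67 cm track, 22 cm robot bay frontage on a 111 cm long
    axis); exact coordinates are configurable because they are not published.
    ``attack_threshold`` is the nest-side/robot-side track boundary whose
    crossing can trigger a robot attack.
    """

    track_length: float = 111.0
    zone_edges: tuple[float, ...] = (0.0, 19.0, 26.0, 58.0, 82.0, 104.0, 111.0)
    position_rate: float = 30.0
    track_width: float = 26.0
    feeder_nest_x: float = 9.5
    feeder_track_x: float = 108.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.zone_edges, dtype=float)
        if len(edges) != len(ZONE_NAMES) + 1:
            raise ValueError(
                f"need {len(ZONE_NAMES) + 1} zone edges, got {len(edges)}"
            )
        if edges[0] != 0.0 or not np.isclose(edges[-1], self.track_length):
            raise ValueError("zones must tile [0, track_length]")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("zone edges must be strictly increasing")

    @property
    def attack_threshold(self) -> float:
        """Boundary between nest-side and robot-side track."""
        return self.zone_edges[3]

    @property
    def doorway_end(self) -> float:
        """Track side of the doorway: the nest+doorway / track boundary."""
        return self.zone_edges[2]

    @property
    def feeder_zone_start(self) -> float:
        return self.zone_edges[5]

    def zone_bounds(self, name: str) -> tuple[float, float]:
        i = ZONE_NAMES.index(name)
        return self.zone_edges[i], self.zone_edges[i + 1]

    def zone_of(self, x: np.ndarray) -> np.ndarray:
        """Zone index per sample (last zone is closed on the right)."""
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.zone_edges, x, side="right") - 1
        return np.clip(idx, 0, len(ZONE_NAMES) - 1)


@dataclass(frozen=True)
class TaskConfig:
    """Session-level task parameters.

    On attack sessions each eligible threshold crossing independently carries
    ``attack_probability`` of triggering the robot; eligibility starts at
    ``first_eligible_lap`` (1-based, inclusive).
    """

    session_type: str = "attack"  # linear_track | novelty | attack
    attack_probability: float = 0.20
    first_eligible_lap: int = 15
    session_duration: float = 3600.0
    pellet_count_per_feeder: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_type not in ("linear_track", "novelty", "attack"):
            raise ValueError(f"unknown session type {self.session_type!r}")
        if not 0.0 <= self.attack_probability <= 1.0:
            raise ValueError("attack_probability must lie in [0, 1]")
        if self.first_eligible_lap < 1:
            raise ValueError("first_eligible_lap must be >= 1")


@dataclass
class Trajectory:
    """Timestamped 2-D head position samples (nominally 30 Hz)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    tracked: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.tracked is None:
            self.tracked = np.ones_like(self.t, dtype=bool)
        else:
            self.tracked = np.asarray(self.tracked, dtype=bool)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "x_cm": self.x, "y_cm": self.y, "tracked": self.tracked}
        )


@dataclass
class SpikeEnsemble:
    """Spike times per cell plus waveform-derived cell metrics.

    ``metrics`` carries one row per cell: cell_id, mean_rate_hz and the
    waveform peak-to-valley duration ratio used for pyramidal classification.
    """

    spike_times: dict[int, np.ndarray]
    metrics: pd.DataFrame

    def __post_init__(self) -> None:
        self.spike_times = {
            int(c): np.asarray(ts, dtype=float) for c, ts in self.spike_times.items()
        }
        missing = set(self.spike_times) - set(self.metrics["cell_id"].astype(int))
        if missing:
            raise ValueError(f"cells missing from metrics table: {sorted(missing)}")

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.spike_times)

    def n_spikes(self) -> int:
        return sum(len(ts) for ts in self.spike_times.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cid, t) for cid in self.cell_ids for t in self.spike_times[cid]
        ]
        df = pd.DataFrame(rows, columns=["cell_id", "t_s"])
        return df.sort_values(["t_s", "cell_id"], kind="stable").reset_index(drop=True)


@dataclass
class LFPSignal:
    """Multichannel local field potential in microvolts."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_ids: list[int] | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.channel_ids is None:
            self.channel_ids = list(range(self.samples.shape[0]))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, channel_id: int) -> np.ndarray:
        return self.samples[self.channel_ids.index(channel_id)]


@dataclass(frozen=True)
class BandDefinitions:
    """Frequency bands (Hz): SWRs use a narrow band for event detection and a
    broader one for PSD/channel-selection analyses."""

    delta: tuple[float, float] = (1.0, 4.0)
    theta: tuple[float, float] = (6.0, 10.0)
    beta: tuple[float, float] = (15.0, 20.0)
    gamma: tuple[float, float] = (30.0, 80.0)
    swr_event: tuple[float, float] = (150.0, 250.0)
    swr_psd: tuple[float, float] = (120.0, 250.0)


def intervals_to_mask(t: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask of samples falling inside any [start, end) interval."""
    mask = np.zeros(len(t), dtype=bool)
    for start, end in np.atleast_2d(np.asarray(intervals, dtype=float).reshape(-1, 2)):
        mask |= (t >= start) & (t < end)
    return mask


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of possibly overlapping [start, end] intervals, sorted."""
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out)
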