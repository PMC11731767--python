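"""Shared synthetic-session fixtures.

Sessions are generated once per test run (session scope) and shared across
modules; all seeds are fixed so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from lmaze import (
    TaskConfig,
    TuningBinGrid,
    build_tuning_curves,
    classify_pyramidal,
    classify_state,
    generate_session,
    segment_theta_cycles,
)


def overlap_hits(truth, detected) -> int:
    """Number of truth intervals intersected by at least one detection."""
    if not len(truth) or not len(detected):
        return 0
    ds = detected["t_start"].to_numpy()
    de = detected["t_end"].to_numpy()
    return int(sum(
        bool(np.any((ds <= e) & (de >= s)))
        for s, e in truth[["t_start", "t_end"]].to_numpy()
    ))


@pytest.fixture(scope="session")
def attack_session():
    """A complete attack session with LFP (the default workload)."""
    return generate_session(TaskConfig(session_type="attack", seed=9), n_laps=38)


@pytest.fixture(scope="session")
def control_session():
    """A linear-track (no robot) session with LFP, used for detector
    validation where injected nest events are the only population bursts."""
    return generate_session(TaskConfig(session_type="linear_track", seed=5),
                            n_laps=40)


@pytest.fixture(scope="session")
def long_session():
    """A ~30-minute control session with 50 cells and no remapping, used for
    parameter-recovery checks."""
    return generate_session(
        TaskConfig(session_type="linear_track", seed=42),
        n_laps=150, remap_fraction=0.0,
    )


@pytest.fixture(scope="session")
def long_analysis(long_session):
    """State labels, theta cycles and whole-session tuning curves derived
    from the long session through the full LFP pathway."""
    sess = long_session
    state = classify_state(sess.lfp, channel=2)
    cycles = segment_theta_cycles(sess.lfp, state=state, channel=2)
    pyramidal = classify_pyramidal(sess.spikes.metrics)
    pyr_ids = [int(c) for c in sess.spikes.metrics.loc[pyramidal, "cell_id"]]
    grid = TuningBinGrid()
    curves = build_tuning_curves(
        sess.spikes, sess.trajectory, cycles, state, grid, cell_ids=pyr_ids
    )
    return {"state": state, "cycles": cycles, "pyr_ids": pyr_ids,
            "grid": grid, "curves": curves}
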