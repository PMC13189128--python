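"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from popdyn.session import (
    ArrayGeometry,
    ArrayItem,
    FixationEvent,
    Session,
    TrialRecord,
    UnitRecord,
)
from popdyn.simulate import SimConfig, make_array_geometry, null_sim_config, simulate_session


def tiny_trial(trial_id: int = 0, cue_category: str = "face") -> TrialRecord:
    """A minimal hand-built valid trial (two fixations, second on a target)."""
    items = [ArrayItem(1, cue_category, 1, True), ArrayItem(2, cue_category, 2, True)]
    other = ["house", "flower", "hand"] if cue_category == "face" else ["face", "flower", "hand"]
    for k in range(9):
        items.append(ArrayItem(3 + k, other[k % 3], 10 + k, False))
    fixations = [
        FixationEvent(1700.0, 1900.0, 3, items[2].category, items[2].exemplar,
                      False, 1, False, False, trial_id),
        FixationEvent(1950.0, 2750.0, 1, cue_category, 1, True, 2, False, False, trial_id),
    ]
    return TrialRecord(
        trial_id=trial_id, cue_category=cue_category, cue_exemplar=5,
        fixation_spot_on=0.0, cue_on=400.0, cue_off=1000.0, array_on=1500.0,
        trial_end=2750.0, array_items=items, fixations=fixations, correct=True,
    )


def tiny_session(n_trials: int = 2, rng: np.random.Generator | None = None) -> Session:
    """A minimal hand-built session with one unit and simple spike trains."""
    rng = rng or np.random.default_rng(0)
    trials = [tiny_trial(i, "face" if i % 2 == 0 else "house") for i in range(n_trials)]
    spikes = {
        t.trial_id: np.sort(rng.uniform(0, t.trial_end, size=rng.integers(5, 30)))
        for t in trials
    }
    unit = UnitRecord(unit_id="u0", area="V4", spikes=spikes)
    return Session(session_id="tiny", units=[unit], trials=trials,
                   array_geometry=make_array_geometry())


@pytest.fixture(scope="session")
def geometry() -> ArrayGeometry:
    return make_array_geometry()


@pytest.fixture(scope="session")
def tuned_session() -> Session:
    """Small session with strong planted tuning, shared across modules."""
    cfg = SimConfig(
        n_units={"V4": 24, "IT": 12, "OFC": 6, "LPFC": 6},
        n_trials=220,
        seed=7,
        p_category_tuned_foveal=0.5,
        p_attention_tuned=0.5,
    )
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def null_session() -> Session:
    """Session with no planted modulation (false-positive calibration)."""
    cfg = null_sim_config(
        n_units={"V4": 20, "IT": 10, "OFC": 5, "LPFC": 5},
        n_trials=160,
        seed=11,
    )
    return simulate_session(cfg)
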