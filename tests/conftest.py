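import numpy as np
import pandas as pd
import pytest

from rewardtask import SimConfig, cohort_to_frame, simulate_cohort
from rewardtask.value_model import ValueModelParams


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A small but realistic cohort: 2 subjects x 2 treatments x 3 sessions,
    ~200 trials per session, default (vehicle vs disconnection-like) params."""
    cfg = SimConfig(n_sessions_per_treatment=3, mean_trial_duration=30.0,
                    rng_seed=7)
    return cohort_to_frame(simulate_cohort(cfg))


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Cohort where both treatments share identical parameters (no true
    treatment effect)."""
    params = {"vehicle": ValueModelParams(0.2, 0.05, 1.0),
              "agonist": ValueModelParams(0.2, 0.05, 1.0)}
    cfg = SimConfig(params_by_treatment=params, n_sessions_per_treatment=4,
                    mean_trial_duration=40.0, rng_seed=11)
    return cohort_to_frame(simulate_cohort(cfg))


def make_trials(rows: list[dict]) -> pd.DataFrame:
    """Hand-build a trial table from terse row dicts (defaults filled in)."""
    defaults = {"subject_id": "m1", "session_id": "s1", "treatment": "vehicle",
                "cue_size": 4, "outcome": "correct", "reaction_time_ms": 400.0}
    out = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        r.setdefault("trial_index", i)
        r.setdefault("reward_delivered",
                     r["cue_size"] if r["outcome"] == "correct" else 0)
        r.setdefault("elapsed_time_s", 20.0 * (i + 1))
        out.append(r)
    return pd.DataFrame(out)
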