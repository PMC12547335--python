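"""Shared fixtures: small seeded cohorts and fitted models.

Everything is generated programmatically at test time from the synthetic
cohort module; no data files are required.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from carepath.cohort import (
    CohortConfig,
    EnvironmentParams,
    generate_cohort,
    simulate_cohort,
)
from carepath.features import STATE_FEATURES, feature_index
from carepath.policies import BehaviorPolicy


def make_state(**values) -> np.ndarray:
    """A 47-feature state vector with named overrides, zeros elsewhere."""
    s = np.zeros(len(STATE_FEATURES))
    for name, v in values.items():
        s[feature_index(name)] = v
    return s


@pytest.fixture(scope="session")
def env() -> EnvironmentParams:
    return EnvironmentParams()


@pytest.fixture(scope="session")
def behavior(env) -> BehaviorPolicy:
    return BehaviorPolicy.from_env(env)


@pytest.fixture(scope="session")
def small_cohort(env) -> pd.DataFrame:
    """500 patients, enough for structural and directional checks."""
    return generate_cohort(CohortConfig(n_patients=500, seed=101), env)


@pytest.fixture(scope="session")
def small_trajectories(small_cohort, behavior, env):
    """Behavior-policy rollouts of the small cohort over 6 months."""
    return simulate_cohort(small_cohort, behavior, env, horizon=6, seed=202)
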