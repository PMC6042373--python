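"""Shared fixtures.  Expensive synthetic cohorts are session-scoped."""

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from pafa.synthdata import (
    SimulationConfig,
    cohort_feature_matrix,
    simulate_training_cohort,
)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted-signal cohort: n=2000, 10 informative + 200 noise tracks."""
    return simulate_training_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def planted_matrix(planted_cohort):
    return cohort_feature_matrix(planted_cohort)


@pytest.fixture(scope="session")
def null_cohort():
    """Zero-effect cohort: classes exchangeable."""
    return simulate_training_cohort(SimulationConfig(seed=12, effect_size=0.0))


@pytest.fixture(scope="session")
def null_matrix(null_cohort):
    return cohort_feature_matrix(null_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
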