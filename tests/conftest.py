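import numpy as np
import pytest

from vodscore import SeverityScenario, simulate_cohort


@pytest.fixture(scope="session")
def small_scenario() -> SeverityScenario:
    """A reduced two-cohort scenario used across test modules."""
    return SeverityScenario(cohort_sizes=(3, 4), m=5, length_range=(60, 90), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_scenario):
    return simulate_cohort(small_scenario)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
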