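import numpy as np
import pytest

from tonebias import cohort


@pytest.fixture(scope="session")
def small_study1():
    """A reduced two-group cohort shared across integration tests."""
    config = cohort.CohortConfig(n_asymptomatic=8, n_symptomatic=6)
    records, truth = cohort.generate_study1_cohort(config, seed=11)
    return records, truth


@pytest.fixture(scope="session")
def small_study2():
    config = cohort.CohortConfig(n_subjects=6)
    records, truth = cohort.generate_study2_cohort(config, seed=12)
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
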