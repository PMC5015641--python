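import numpy as np
import pytest

from spiroref import (
    CohortConfig,
    generate_cohort,
    generate_fixture_equation_set,
)


@pytest.fixture(scope="session")
def lms_set():
    return generate_fixture_equation_set(seed=1, family="lms")


@pytest.fixture(scope="session")
def linear_set():
    return generate_fixture_equation_set(seed=1, family="linear_sd")


@pytest.fixture(scope="session")
def small_cohort(lms_set):
    """A 400-subject healthy index-consistent cohort under the LMS fixture."""
    config = CohortConfig(seed=11, strata=[{"centre": "sim", "n": 400}])
    cohort, _ = generate_cohort(config, lms_set)
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
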