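import numpy as np
import pytest

from frailmark import SyntheticConfig, generate_cohort, make_null_cohort, make_separable_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """49-subject synthetic cohort with the study's default structure."""
    return generate_cohort(SyntheticConfig(), seed=1)


@pytest.fixture(scope="session")
def null_cohort():
    return make_null_cohort(24, 24, 10, seed=7)


@pytest.fixture(scope="session")
def separable_cohort():
    """5 informative markers shifted 3 log-SD between groups of 22/27."""
    return make_separable_cohort(22, 27, {0, 1, 2, 3, 4}, 3.0, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
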