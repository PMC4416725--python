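import numpy as np
import pytest

from psorprs import paper_like_config, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Study-structured configuration at a reduced sample size."""
    return paper_like_config(n_cases=800, n_controls=800, seed=20240301)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, panel = simulate_cohort(small_config)
    return cohort, panel


@pytest.fixture(scope="session")
def full_cohort():
    """One study-scale cohort shared by the heavier checks."""
    cohort, panel = simulate_cohort(paper_like_config(seed=11))
    return cohort, panel


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
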