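import numpy as np
import pytest

import exgauss_rt as xg


@pytest.fixture(scope="session")
def condition_table():
    return xg.default_condition_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Four participants per country: fast, every cell populated."""
    design = xg.CohortDesign(participants_per_country=4, trials_per_cell=14, seed=123)
    return xg.generate_cohort(design)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-sized cohort: 2 x 50 participants x 224 trials."""
    return xg.generate_cohort(xg.CohortDesign(seed=2024))


@pytest.fixture
def rng():
    return np.random.default_rng(97531)
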