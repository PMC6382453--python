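import numpy as np
import pytest
from hypothesis import settings

from ogttbench import default_sim_config, generate_cohort

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_cohort():
    """A 543-participant cohort under the default study conditions."""
    return generate_cohort(default_sim_config(seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Moderate cohort with no missingness, for score-level checks."""
    cfg = default_sim_config(seed=7, n=800, n_progressors=215)
    cfg.missing_rate = {}
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
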