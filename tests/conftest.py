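import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pedmut.synthetic_cohort import CohortSpec, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort exercised by several integration tests."""
    spec = CohortSpec(n_f1=8, seed=11, n_sim_fnr=500, n_sim_transmission=500)
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
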