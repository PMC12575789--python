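import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from repeatscape import SimulationConfig, make_cohort, make_mini_reference

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def reference(sim_config):
    return make_mini_reference(sim_config)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return make_cohort(sim_config)


@pytest.fixture(scope="session")
def tumor(cohort):
    return next(m for m in cohort if m.group == "tumor")


@pytest.fixture(scope="session")
def normal(cohort):
    return next(m for m in cohort if m.group == "normal")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
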