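import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wingmosaic import SimulationConfig, simulate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Small disc at a high loss rate: quick, clone-rich wings."""
    return SimulationConfig(
        n0=200,
        rounds=3,
        p_loss=0.02,
        blade_fraction=1.0,
        screened_cells=3200,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, 6, group="small", seed=5)
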