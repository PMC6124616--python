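import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def recovery_dataset():
    """Large complete-data draw with known moderate effects, shared by tests."""
    from dyadsem.simulate import ScenarioConfig, simulate_dataset

    config = ScenarioConfig(
        n_families=200_000, v_fetal=0.0004, v_maternal=0.0001, seed=20_240_101
    )
    return config, simulate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
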