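import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nmda_dcm import ModelConfig, default_observation

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def obs():
    return default_observation()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
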