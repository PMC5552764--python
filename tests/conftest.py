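import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_config():
    from lgnsim import NetworkConfig

    return NetworkConfig.base()


@pytest.fixture(scope="session")
def tcr_params():
    from lgnsim import tonic_presets

    return tonic_presets()["TCR"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
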