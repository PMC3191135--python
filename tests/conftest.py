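import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import primevoice as pv

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    """Shipped default calibration."""
    return pv.default_params("exp1")


@pytest.fixture(scope="session")
def quiet_params(params):
    """Zero-noise variant of the defaults (deterministic dynamics)."""
    return params.replace(noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
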