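import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from photokin.light_response import IntensityResponse, MemoryParams

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def resp():
    """Default hyperbolic response: 2 -> 8 um/s with half-rise at level 50."""
    return IntensityResponse()


@pytest.fixture
def mem():
    """Two-timescale memory with the fitted step-response parameters."""
    return MemoryParams(beta=0.44, tau_m=35.0)
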