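import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from remapot import RateMap, TransportConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cfg():
    """Default high-accuracy sliced configuration."""
    return TransportConfig(seed=0, n_projections=10_000)


@pytest.fixture
def cfg_fast():
    """Low-projection configuration for score maps and sweeps."""
    return TransportConfig(seed=0, n_projections=100)


@pytest.fixture
def delta_map():
    def _make(shape, at, value=1.0):
        arr = np.zeros(shape)
        arr[at] = value
        return RateMap(arr)

    return _make
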