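import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_cell_polygon():
    """A 20x20 um square cell centred in a 30x30 um field."""
    return ((5.0, 5.0), (25.0, 5.0), (25.0, 25.0), (5.0, 25.0))
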