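import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from vnspi import patterns


@pytest.fixture(scope="session")
def h32():
    """Natural-order Hadamard matrix for 32x32 imaging (order 1024)."""
    return patterns.build_hadamard(10)


@pytest.fixture(scope="session")
def h32_walsh(h32):
    return patterns.walsh_order(h32)


@pytest.fixture(scope="session")
def seq32(h32_walsh):
    return patterns.to_mask_sequence(h32_walsh, 32, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
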