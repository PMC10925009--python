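import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_bits(rng):
    def make(n_bits: int) -> str:
        return "".join("1" if b else "0" for b in rng.integers(0, 2, n_bits))

    return make


@pytest.fixture
def random_bytes(rng):
    def make(n: int) -> bytes:
        return rng.integers(0, 256, n, dtype=np.uint8).tobytes()

    return make
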