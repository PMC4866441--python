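import numpy as np
import pytest

from gmrid import Volume, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    """Small random volume for kernel/filter algebra tests."""
    def make(shape=(4, 4, 4), lo=0.0, hi=1.0, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return Volume(r.uniform(lo, hi, size=shape))
    return make


@pytest.fixture(scope="session")
def phantom12():
    """Session-wide 12^3 default phantom (clean)."""
    return generate_phantom((12, 12, 12), seed=0)
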