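import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_instance(rng):
    """Random 8x8 weight matrix and binary input with >=1 active element."""
    w = rng.uniform(0.0, 1.0, size=(8, 8))
    x = np.zeros(8, dtype=np.uint8)
    x[rng.permutation(8)[:4]] = 1
    return w, x
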