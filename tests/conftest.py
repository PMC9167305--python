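import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_pair(rng):
    """A small random uint8 RGB stereo pair (no geometric relation)."""
    left = rng.integers(0, 256, size=(12, 14, 3), dtype=np.uint8)
    right = rng.integers(0, 256, size=(12, 14, 3), dtype=np.uint8)
    return left, right
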