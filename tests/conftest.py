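import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230711)


@pytest.fixture
def random_gray(rng):
    """A 64x64 seeded random grayscale raster."""
    return rng.integers(0, 256, size=(64, 64)).astype(np.uint8)


@pytest.fixture
def banded_gray():
    """Three horizontal bands at gray 30 / 200 / 60 (rows 0-19 / 20-39 / 40-59)."""
    img = np.empty((60, 60), dtype=np.uint8)
    img[:20] = 30
    img[20:40] = 200
    img[40:] = 60
    return img
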