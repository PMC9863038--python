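import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def smooth_image(rng):
    """Smooth random 32x32 RGB image; enough texture for exemplar search."""

    def make(size=32, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        img = r.integers(0, 256, (size, size, 3)).astype(float)
        img = ndimage.gaussian_filter(img, sigma=(2, 2, 0))
        return np.clip(img, 0, 255).astype(np.uint8)

    return make

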