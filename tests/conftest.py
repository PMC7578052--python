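import numpy as np
import pytest

from hepatex import MaskedImage
from hepatex.texture import DiscretizedROI


@pytest.fixture
def block_image() -> MaskedImage:
    """4x4 image of four 2x2 constant blocks (4 distinct intensities)."""
    px = np.array(
        [[0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 3, 3], [2, 2, 3, 3]], dtype=float
    )
    return MaskedImage(pixels=px, mask=np.ones((4, 4), dtype=bool))


@pytest.fixture
def block_roi() -> DiscretizedROI:
    """The block image as a 4-level discretized ROI (levels 0..3)."""
    lv = np.array(
        [[0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 3, 3], [2, 2, 3, 3]]
    )
    return DiscretizedROI(levels=lv, mask=np.ones((4, 4), dtype=bool), n_levels=9)


def random_roi(rng, size=8, n_levels=9, p_mask=0.8):
    """A random discretized ROI with a random (non-trivial) mask."""
    while True:
        mask = rng.random((size, size)) < p_mask
        if mask.sum() >= 2:
            break
    levels = rng.integers(0, n_levels, size=(size, size))
    return DiscretizedROI(levels=levels, mask=mask, n_levels=n_levels)
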