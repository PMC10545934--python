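import numpy as np
import pytest


def disc_mask(shape, centers_radii):
    """Labeled mask with one disc per (cy, cx, r) triple, ids 1..n."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=np.int32)
    for i, (cy, cx, r) in enumerate(centers_radii, start=1):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        mask[disc & (mask == 0)] = i
    return mask


@pytest.fixture
def single_disc():
    """One filled disc of radius 10 centered in a 64x64 grid."""
    return disc_mask((64, 64), [(32, 32, 10)])


@pytest.fixture
def touching_discs():
    """Two radius-10 discs sharing a boundary (centers 20 px apart)."""
    return disc_mask((64, 64), [(32, 21, 10), (32, 41, 10)])


@pytest.fixture
def separated_discs():
    """Eight well-separated radius-9 discs (gaps > 4 px) in 128x128."""
    centers = [(20, 20), (20, 60), (20, 100), (64, 40), (64, 84), (108, 20), (108, 64), (108, 108)]
    return disc_mask((128, 128), [(cy, cx, 9) for cy, cx in centers])
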