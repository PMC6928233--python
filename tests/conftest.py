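import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bar_mask():
    """A 7-px-wide, 105-px-long horizontal bar; its skeleton is ~100 px."""
    m = np.zeros((21, 125), bool)
    m[7:14, 10:115] = True
    return m


def make_disk_mask(shape=(60, 60), center=(30, 30), radius=20.5):
    from skimage.draw import disk

    m = np.zeros(shape, bool)
    rr, cc = disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


def random_blob_mask(rng, shape=(48, 48), n_blobs=3, radius_range=(2, 6)):
    from skimage.draw import disk

    m = np.zeros(shape, bool)
    for _ in range(n_blobs):
        r = rng.uniform(0, shape[0])
        c = rng.uniform(0, shape[1])
        rad = rng.uniform(*radius_range)
        rr, cc = disk((r, c), rad, shape=shape)
        m[rr, cc] = True
    return m
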