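import numpy as np
import pytest

from latmirror import Blob, RoiMask, StatVolume, TmapSpec, exclude_midline, generate_tmap


def symmetric_affine(shape, voxel=2.0):
    a = np.diag([voxel, voxel, voxel, 1.0])
    a[:3, 3] = -voxel * (np.asarray(shape) - 1) / 2.0
    return a


@pytest.fixture
def affine16():
    return symmetric_affine((16, 16, 16))


@pytest.fixture
def random_volume(affine16):
    rng = np.random.default_rng(42)
    return StatVolume(rng.normal(size=(16, 16, 16)), affine16)


@pytest.fixture
def full_mask(affine16):
    """All-true mask on the 16^3 grid, midline already excluded."""
    return exclude_midline(RoiMask(np.ones((16, 16, 16), bool), affine16))


@pytest.fixture
def x_volume(affine16):
    """Volume whose value at each voxel is its world x coordinate."""
    xs = symmetric_affine((16, 16, 16))[0, 0] * np.arange(16) + affine16[0, 3]
    data = np.broadcast_to(xs[:, None, None], (16, 16, 16)).copy()
    return StatVolume(data, affine16)


@pytest.fixture
def lateralised_map():
    """Strongly left-lateralised noise-free blob map with its ROI."""
    spec = TmapSpec(blobs=(Blob((14, 6, 4), 10.0, 4.0, 1.0),))
    vol, masks, truth = generate_tmap(spec)
    return vol, exclude_midline(masks[0]), truth
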