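import numpy as np
import pytest

from hybridreg.image_model import BinaryMask, DisplacementField, Image3D
from hybridreg.synthetic import PhantomSpec, make_phantom


def ramp_image(shape=(8, 8, 8), axis=0, spacing=(1.0, 1.0, 1.0), slope=1.0):
    """Image linear in one axis's physical coordinate: v = slope * x_axis."""
    idx = np.arange(shape[axis], dtype=float) * spacing[axis]
    shape_full = [1, 1, 1]
    shape_full[axis] = shape[axis]
    vox = np.broadcast_to(slope * idx.reshape(shape_full), shape).copy()
    return Image3D(vox, spacing)


def constant_field(img, vec):
    v = np.broadcast_to(np.asarray(vec, dtype=float), img.shape + (3,)).copy()
    return DisplacementField(v, img.spacing, img.origin)


def cube_mask(shape=(10, 10, 10), lo=(3, 3, 3), size=2, spacing=(1.0, 1.0, 1.0)):
    vox = np.zeros(shape, dtype=np.uint8)
    sl = tuple(slice(l, l + size) for l in lo)
    vox[sl] = 1
    return BinaryMask(vox, spacing)


@pytest.fixture(scope="session")
def phantom():
    """One 64³ phantom shared by read-only tests."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
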