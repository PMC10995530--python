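import numpy as np
import pytest

from pethotspot.volume_io import LesionMask, ScalarVolume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(values, spacing=1.0, origin=0.0):
    return ScalarVolume3D(np.asarray(values, dtype=float), spacing, origin)


def make_mask(values, spacing=1.0, origin=0.0):
    return LesionMask(np.asarray(values, dtype=bool), spacing, origin)


def digital_ball(radius_mm, spacing=1.0, margin_vox=3):
    """Boolean ball of a physical radius, centered on a voxel center."""
    spacing3 = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing3.size == 1:
        spacing3 = np.repeat(spacing3, 3)
    half = np.ceil(radius_mm / spacing3).astype(int) + margin_vox
    shape = 2 * half + 1
    center = half * spacing3
    axes = [np.arange(n) * s for n, s in zip(shape, spacing3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    ball = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2 <= radius_mm**2
    return ball, spacing3, center


@pytest.fixture
def ball20():
    """Digital 20 mm ball at 1 mm voxels with its center coordinates."""
    ball, spacing, center = digital_ball(20.0, 1.0)
    return make_mask(ball, spacing), center
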