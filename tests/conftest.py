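"""Shared fixtures: a midline AC-PC frame and voxelized box masks.

Box masks are built so that the *cube surface* of the voxel model lies
exactly on the requested world extents (voxel centers at half-integer
offsets inside), which makes boundary positions analytically known.
"""

import numpy as np
import pytest

from gpilead.coords import build_frame
from gpilead.gpi import SegmentationMask


@pytest.fixture
def frame():
    """Identity-axes frame: world x=lateral(+right), y=anterior, z=vertical."""
    return build_frame([0.0, 12.5, 0.0], [0.0, -12.5, 0.0], [1.0, 0.0, 0.0])


def make_box_mask(lat_range, ap_range, vert_range, voxel=1.0, label="GPi"):
    """Solid box whose voxel-cube surface lies on the given extents."""
    ranges = [lat_range, ap_range, vert_range]
    ns = [int(round((hi - lo) / voxel)) for lo, hi in ranges]
    data = np.ones(ns, dtype=bool)
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    affine[:3, 3] = [lo + voxel / 2.0 for lo, _ in ranges]
    return SegmentationMask(data, affine, label=label)


@pytest.fixture
def box_mask():
    """The reference box: LAT 10-20, AP -5-5, VERT -4-0 mm."""
    return make_box_mask((10, 20), (-5, 5), (-4, 0))


def random_rigid_motion(rng):
    """A random proper rotation + translation, as (R, t)."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(scale=30.0, size=3)
    return Q, t
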