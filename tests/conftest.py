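"""Shared fixtures: small analytic volumes and phantom geometries."""

import numpy as np
import pytest

from wallfibril3d.phantom import (GroundTruth, PhantomSpec, TrueCrossLink,
                                  TrueFibril, _rasterize)
from wallfibril3d.volume import DensityVolume

VS = 0.87  # nm/voxel used throughout the fixtures


@pytest.fixture(scope="session")
def cylinder_volume():
    """Soft-edged straight cylinder along y, radius 2.5 nm."""
    z, y, x = np.mgrid[0:24, 0:40, 0:24] * VS
    d = np.sqrt((z - 10 * VS) ** 2 + (x - 12 * VS) ** 2)
    data = np.clip((2.5 + 0.5 * VS - d) / VS, 0, 1).astype(np.float32)
    return DensityVolume(data, VS)


def straight_fibril(fid, z, x, r, layer, y_extent):
    v = np.array([[z, 0.0, x], [z, y_extent, x]])
    return TrueFibril(fid, v, np.full(2, r), layer, np.array([0.0, 1.0, 0.0]))


@pytest.fixture(scope="session")
def two_cylinder_bridge():
    """Two parallel fibrils (r = 2.5 nm) 10 nm apart in z, joined by one
    vertical bridge spanning the 5 nm surface gap."""
    spec = PhantomSpec(shape_voxels=(40, 60, 40), voxel_size=VS,
                       crosslink_density=0.0)
    fa = straight_fibril(0, 10.0, 10.0, 2.5, 0, 60 * VS)
    fb = straight_fibril(1, 20.0, 10.0, 2.5, 1, 60 * VS)
    link = TrueCrossLink(0, 1, np.array([12.5, 26.0, 10.0]),
                         np.array([17.5, 26.0, 10.0]), 5.0)
    truth = GroundTruth(fibrils=[fa, fb], crosslinks=[link])
    data = _rasterize(spec, truth, soft=True)
    return DensityVolume(data, VS), truth, spec


@pytest.fixture(scope="session")
def small_cryo_phantom():
    """Noiseless cryo-preset phantom at reduced ROI size."""
    from wallfibril3d.phantom import generate_wall_phantom, make_preset

    spec = make_preset("cryo", shape_voxels=(120, 120, 40), seed=7)
    vol, truth = generate_wall_phantom(spec)
    return vol, truth, spec
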