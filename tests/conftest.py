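"""Shared fixtures: small voxel phantoms built programmatically."""

import warnings

import numpy as np
import pytest

from osteolysis import VoxelVolume
from osteolysis.errors import ResolutionWarning

VOXEL_UM = 4.3


@pytest.fixture(autouse=True)
def _quiet_resolution_warnings():
    """Thin-shell/fringe windows warn by design on tiny fixtures."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ResolutionWarning)
        yield


def slab_with_holes(diameters, thickness, margin=26, voxel_size_um=VOXEL_UM):
    """Flat slab with z-axis through-holes; returns (volume, hole list).

    Holes are rasterised strictly (voxel centers closer than d/2 to the
    axis) and centered on voxel centers, matching the phantom generator.
    """
    width = (max(diameters, default=0) + 2 * margin + 60)
    mask = np.zeros((thickness + 2 * margin, width, width), dtype=bool)
    mask[margin:margin + thickness] = True
    ys = [width // 2] * len(diameters)
    xs = [int(width * (i + 1) / (len(diameters) + 1)) for i in range(len(diameters))]
    yy, xx = np.ogrid[:width, :width]
    for d, y0, x0 in zip(diameters, ys, xs):
        mask &= ~(((yy - y0) ** 2 + (xx - x0) ** 2 < (d / 2.0) ** 2)[None])
    vol = VoxelVolume(mask=mask, voxel_size_um=voxel_size_um)
    return vol, list(zip(diameters, ys, xs)), margin


def digital_ball(radius, voxel_size_um=VOXEL_UM, margin=6):
    """Solid digitised ball (inclusive rasterisation)."""
    n = 2 * (radius + margin) + 1
    c = n // 2
    zz, yy, xx = np.ogrid[:n, :n, :n]
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
    return VoxelVolume(mask=mask, voxel_size_um=voxel_size_um)


@pytest.fixture(scope="session")
def small_shaft():
    """A small capped hollow shaft with two radial through-holes."""
    from osteolysis import HoleSpec, PhantomSpec, make_phantom

    spec = PhantomSpec(
        shape="capped_shaft",
        outer_size_vox=(140, 124, 124),
        wall_thickness_vox=30,
        holes=[HoleSpec(diameter_vox=16, z=70, angle_deg=0.0),
               HoleSpec(diameter_vox=10, z=70, angle_deg=180.0)],
        noise_sd=0.0,
        seed=11,
    )
    return make_phantom(spec)
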