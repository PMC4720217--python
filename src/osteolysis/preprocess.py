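"""Binarisation and component selection.

Micro-CT bone analysis starts from a user-supplied global threshold (the
attenuation cut separating mineralised bone from marrow/air), followed by
removal of disconnected fragments such as a floating patella that was caught
in the scan field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DataError, EmptyInputError, InputError, SeedError
from .volume_io import GrayVolume, VoxelVolume

__all__ = ["ThresholdSpec", "threshold_volume", "select_component"]

# complementary connectivity pair: 26 for bone, 6 for background
STRUCT_26 = ndimage.generate_binary_structure(3, 3)
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class ThresholdSpec:
    """Binary threshold: ``value`` in intensity units, bone assumed brighter
    unless ``bone_brighter`` is cleared (inverted reconstructions)."""

    value: float
    bone_brighter: bool = True


def threshold_volume(gray: GrayVolume, spec: ThresholdSpec) -> VoxelVolume:
    """Apply a binary threshold to a grayscale volume.

    For integer volumes the threshold must lie within the dtype's
    representable range; float volumes only require a finite threshold.
    NaN intensities raise :class:`DataError`.
    """
    data = gray.data
    if np.issubdtype(data.dtype, np.floating) and np.isnan(data).any():
        raise DataError("volume contains NaN intensities")
    if not np.isfinite(spec.value):
        raise InputError(f"threshold must be finite, got {spec.value}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if not info.min <= spec.value <= info.max:
            raise InputError(
                f"threshold {spec.value} outside representable range "
                f"[{info.min}, {info.max}] of {data.dtype}")
    if spec.bone_brighter:
        mask = data >= spec.value
    else:
        mask = data <= spec.value
    return VoxelVolume(mask=mask, voxel_size_um=gray.voxel_size_um)


def select_component(vol: VoxelVolume, seed: tuple[int, int, int] | None = None) -> VoxelVolume:
    """Keep a single 26-connected component of the bone mask.

    With a ``seed`` voxel ``(z, y, x)`` the component containing it is kept;
    without one, the largest component by voxel count.  Everything else
    (floating fragments) is discarded.
    """
    mask = vol.mask
    if not mask.any():
        raise EmptyInputError("empty foreground: nothing to select")
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    if seed is not None:
        z, y, x = (int(c) for c in seed)
        if not (0 <= z < mask.shape[0] and 0 <= y < mask.shape[1] and 0 <= x < mask.shape[2]):
            raise SeedError(f"seed {seed} outside grid {mask.shape}")
        lab = labels[z, y, x]
        if lab == 0:
            raise SeedError(f"seed {seed} lies on background")
    else:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        lab = int(counts.argmax())
    return VoxelVolume(mask=labels == lab, voxel_size_um=vol.voxel_size_um)
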