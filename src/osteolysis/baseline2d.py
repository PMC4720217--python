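"""The 2-D comparison method: clipped-silhouette lesion measurement.

Long bones are roughly triangular in cross-section, so the traditional 2-D
workflow images three sides of the bone — the concave face, the face behind
the fibula, and the flat face — each time with the bone clipped in half so
that through-lesions in the remaining wall show the background colour.  The
lesion burden is then the summed area of those interior background regions
as a percentage of the imaged bone area.

This module reproduces that measurement with orthographic projections of a
clipped half-volume.  Because each face sees a different part of the bone
and the clip plane is a free choice, the 2-D estimate varies from view to
view — the variability mechanism that the full 3-D analysis removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyInputError, InputError
from .volume_io import VoxelVolume

__all__ = ["FaceImage", "FACE_VIEWS", "render_face", "measure_2d"]

#: face label -> (projection axis, camera side). The camera looks along the
#: given axis from the low side (+1) or the high side (-1); the near half of
#: the bone is clipped away so lesions in the far wall show through.
FACE_VIEWS: dict[str, tuple[int, int]] = {
    "concave": (1, +1),
    "fibular": (1, -1),
    "flat": (2, +1),
}


@dataclass
class FaceImage:
    """Binary silhouette of a clipped half-bone seen from one face."""

    pixels: np.ndarray
    pixel_size_um: float
    face_label: str

    def __post_init__(self) -> None:
        if self.face_label not in FACE_VIEWS:
            raise InputError(
                f"face_label must be one of {tuple(FACE_VIEWS)}, got {self.face_label!r}")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise EmptyInputError("face image must be a non-empty 2-D grid")


def render_face(
    vol: VoxelVolume,
    face_label: str,
    clip: int | None = None,
) -> FaceImage:
    """Orthographic silhouette of the half-volume behind the clip plane.

    ``clip`` is the plane position along the view axis (default: the grid
    midpoint); the half between the camera and the plane is removed, and the
    remaining bone is projected along the view axis.  A clip plane leaving
    no bone raises :class:`EmptyInputError`.
    """
    if face_label not in FACE_VIEWS:
        raise InputError(
            f"face_label must be one of {tuple(FACE_VIEWS)}, got {face_label!r}")
    axis, side = FACE_VIEWS[face_label]
    n = vol.mask.shape[axis]
    if clip is None:
        clip = n // 2
    if not 0 <= clip <= n:
        raise InputError(f"clip plane {clip} outside axis of length {n}")

    sl = [slice(None)] * 3
    sl[axis] = slice(clip, None) if side == +1 else slice(0, clip)
    half = vol.mask[tuple(sl)]
    if half.size == 0 or not half.any():
        raise EmptyInputError("clip plane leaves no bone in the imaged half")
    silhouette = half.any(axis=axis)
    return FaceImage(pixels=silhouette.astype(np.uint8),
                     pixel_size_um=vol.voxel_size_um, face_label=face_label)


def measure_2d(face: FaceImage) -> float:
    """Percent of the bone silhouette occupied by lesions.

    Lesions are the interior background regions of the silhouette — holes
    letting the background show through — identified as background
    components (4-connected, complementary to the 8-connected silhouette)
    not touching the image border.  Returns
    ``100 * lesion_pixels / (bone_pixels + lesion_pixels)``.
    """
    bone = face.pixels > 0
    if not bone.any():
        raise EmptyInputError("no bone pixels in face image")
    bg = ~bone
    lab, _ = ndimage.label(bg, structure=ndimage.generate_binary_structure(2, 1))
    border = np.unique(np.concatenate([
        lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
    interior = bg & ~np.isin(lab, border[border > 0])
    lesion_px = int(np.count_nonzero(interior))
    bone_px = int(np.count_nonzero(bone))
    return 100.0 * lesion_px / (bone_px + lesion_px)
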