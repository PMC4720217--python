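"""Lesion extraction and measurement.

Subtracting the original bone from its lesion-free reconstruction leaves one
connected component of filled voxels per lesion.  Each component is measured
by its filled-voxel count and by the area of the reconstructed-surface patch
that caps its opening; the total lesion area is reported as a percentage of
the reconstructed (lesion-free) bone surface, so the denominator does not
shrink as disease progresses.

Cap areas use the *vector area* of the exposed patch: the magnitude of the
sum of outward unit face normals over the faces a lesion component exposes
to the exterior.  For any cap the vector area equals the flat area enclosed
by the cap's rim — it measures the lesion mouth and is insensitive to how
far the reconstructed cap bulges or sags into the hole, and to the patch's
orientation on the voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import BoundsError, ContractViolationError, EmptyInputError, IdError
from .reconstruct3d import ReconstructionParams
from .volume_io import VoxelVolume

__all__ = ["LesionRecord", "AnalysisReport", "detect_lesions",
           "surface_area", "deselect", "pick_lesion"]

STRUCT_26 = ndimage.generate_binary_structure(3, 3)
STRUCT_6 = ndimage.generate_binary_structure(3, 1)

#: Face counting overestimates a smooth surface's area by 3/2 in expectation
#: (average of |nx|+|ny|+|nz| over orientations), hence the 2/3 correction.
FACE_AREA_CORRECTION = 2.0 / 3.0


@dataclass
class LesionRecord:
    """One detected lesion: filled voxels, cap (mouth) area, centroid."""

    id: int
    fill_vox: int
    cap_area_um2: float
    centroid_um: tuple[float, float, float]
    included: bool = True


@dataclass
class AnalysisReport:
    """Size-sorted lesion list with bone-surface totals.

    ``labels`` is the lesion label grid (0 = background), kept for 3-D
    picking and on-disk export but excluded from serialised reports.
    ``params`` records every parameter used, for reproducibility.
    """

    lesions: list[LesionRecord]
    bone_surface_area_um2: float
    bone_surface_area_raw_um2: float
    voxel_size_um: float
    params: dict = field(default_factory=dict)
    labels: Optional[np.ndarray] = None

    @property
    def total_lesion_area_um2(self) -> float:
        return float(sum(r.cap_area_um2 for r in self.lesions if r.included))

    @property
    def lesion_percent(self) -> float:
        if self.bone_surface_area_um2 <= 0:
            return 0.0
        return 100.0 * self.total_lesion_area_um2 / self.bone_surface_area_um2

    def to_dict(self) -> dict:
        return {
            "lesions": [
                {"id": r.id, "fill_vox": r.fill_vox,
                 "cap_area_um2": r.cap_area_um2,
                 "centroid_um": list(r.centroid_um),
                 "included": r.included}
                for r in self.lesions],
            "bone_surface_area_um2": self.bone_surface_area_um2,
            "bone_surface_area_raw_um2": self.bone_surface_area_raw_um2,
            "total_lesion_area_um2": self.total_lesion_area_um2,
            "lesion_percent": self.lesion_percent,
            "voxel_size_um": self.voxel_size_um,
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AnalysisReport":
        lesions = [LesionRecord(id=d["id"], fill_vox=d["fill_vox"],
                                cap_area_um2=d["cap_area_um2"],
                                centroid_um=tuple(d["centroid_um"]),
                                included=d["included"])
                   for d in payload["lesions"]]
        return cls(lesions=lesions,
                   bone_surface_area_um2=payload["bone_surface_area_um2"],
                   bone_surface_area_raw_um2=payload["bone_surface_area_raw_um2"],
                   voxel_size_um=payload["voxel_size_um"],
                   params=payload.get("params", {}))


def exterior_background(mask: np.ndarray) -> np.ndarray:
    """Background voxels reachable from the grid border (6-connected).

    Enclosed cavities (e.g. a sealed medullary canal) are *not* exterior.
    """
    lab, _ = ndimage.label(~mask, structure=STRUCT_6)
    border = np.concatenate([
        lab[0].ravel(), lab[-1].ravel(),
        lab[:, 0].ravel(), lab[:, -1].ravel(),
        lab[:, :, 0].ravel(), lab[:, :, -1].ravel()])
    ids = np.unique(border)
    ids = ids[ids > 0]
    return np.isin(lab, ids)


def _exposed_face_masks(ext: np.ndarray) -> list[tuple[int, int, np.ndarray]]:
    """For each of the 6 directions, the voxels whose neighbour in that
    direction is exterior (grid border counts as exterior)."""
    out = []
    for axis in range(3):
        for sign in (+1, -1):
            shifted = np.roll(ext, -sign, axis=axis)
            edge = [slice(None)] * 3
            edge[axis] = -1 if sign == 1 else 0
            shifted[tuple(edge)] = True
            out.append((axis, sign, shifted))
    return out


def surface_area(vol: VoxelVolume, corrected: bool = True) -> float:
    """Exposed surface area of a bone mask in μm².

    Counts foreground voxel faces adjacent to border-reachable background
    and multiplies by voxel-face area; ``corrected`` applies the 2/3
    isotropy factor (face counting overestimates smooth surfaces by 3/2).
    """
    mask = vol.mask
    if not mask.any():
        raise EmptyInputError("empty mask has no surface")
    ext = exterior_background(mask)
    faces = sum(int(np.count_nonzero(mask & shifted))
                for _, _, shifted in _exposed_face_masks(ext))
    area = faces * vol.voxel_size_um ** 2
    return area * FACE_AREA_CORRECTION if corrected else area


def _cap_area_vox2(lesion: np.ndarray, face_masks) -> float:
    """Vector area (in voxel-face units) of the largest exposed patch of one
    lesion component.  Faces are grouped into patches by 26-connectivity of
    the voxels bearing them; a through-tunnel therefore contributes its
    largest mouth, not the sum of both openings (whose normals would cancel)."""
    exposed = np.zeros_like(lesion)
    per_dir = []
    for axis, sign, shifted in face_masks:
        f = lesion & shifted
        per_dir.append((axis, sign, f))
        exposed |= f
    if not exposed.any():
        return 0.0
    lab, n = ndimage.label(exposed, structure=STRUCT_26)
    best = 0.0
    for pid in range(1, n + 1):
        patch = lab == pid
        vec = np.zeros(3)
        for axis, sign, f in per_dir:
            vec[axis] += sign * np.count_nonzero(f & patch)
        best = max(best, float(np.linalg.norm(vec)))
    return best


def detect_lesions(
    original: VoxelVolume,
    reconstructed: VoxelVolume,
    params: ReconstructionParams,
) -> AnalysisReport:
    """Label and measure lesions as reconstruction-minus-original components.

    Components smaller than ``params.min_lesion_vox`` voxels are dropped as
    threshold noise, as are fully enclosed components with no opening on the
    reconstructed surface (filled internal voids are not osteolytic
    lesions).  Lesions are listed in order of cap area, largest first.
    """
    if original.shape != reconstructed.shape:
        raise ContractViolationError("grids differ between original and reconstruction")
    if (original.mask & ~reconstructed.mask).any():
        raise ContractViolationError("reconstruction does not contain the original volume")
    s = original.voxel_size_um

    diff = reconstructed.mask & ~original.mask
    structure = STRUCT_26 if params.connectivity == 26 else STRUCT_6
    lab, n = ndimage.label(diff, structure=structure)

    ext = exterior_background(reconstructed.mask)
    face_masks = _exposed_face_masks(ext)

    records: list[LesionRecord] = []
    keep_labels: dict[int, int] = {}
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab, dtype=np.int64), lab,
                                   index=range(1, n + 1)).astype(int)
        centroids = ndimage.center_of_mass(diff, lab, range(1, n + 1))
        for comp, (size, com) in enumerate(zip(sizes, centroids), start=1):
            if size < params.min_lesion_vox:
                continue
            comp_mask = lab == comp
            cap = _cap_area_vox2(comp_mask, face_masks) * s ** 2
            if cap <= 0:
                continue  # enclosed void, no surface opening
            records.append(LesionRecord(
                id=comp, fill_vox=int(size), cap_area_um2=cap,
                centroid_um=tuple(float(c) * s for c in com)))
            keep_labels[comp] = comp

    records.sort(key=lambda r: (-r.cap_area_um2, r.id))
    labels_out = np.where(np.isin(lab, list(keep_labels)), lab, 0)

    bone_sa = surface_area(reconstructed, corrected=True)
    bone_sa_raw = surface_area(reconstructed, corrected=False)
    return AnalysisReport(
        lesions=records,
        bone_surface_area_um2=bone_sa,
        bone_surface_area_raw_um2=bone_sa_raw,
        voxel_size_um=s,
        params={"d_max_um": params.d_max_um, "window_um": params.window_um,
                "depth_step_vox": params.depth_step_vox,
                "connectivity": params.connectivity,
                "min_lesion_vox": params.min_lesion_vox,
                "voxel_size_um": s},
        labels=labels_out,
    )


def deselect(report: AnalysisReport, ids: list[int], restore: bool = False) -> AnalysisReport:
    """Exclude (or, with ``restore``, re-include) lesions by id.

    Records are retained with their flag cleared so the exclusion is
    auditable; totals and the lesion percent are recomputed over included
    lesions only.  Intended for manually removing natural openings such as
    the nutrient blood-vessel canal.
    """
    known = {r.id for r in report.lesions}
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise IdError(f"unknown lesion id(s): {unknown}")
    new = [LesionRecord(id=r.id, fill_vox=r.fill_vox, cap_area_um2=r.cap_area_um2,
                        centroid_um=r.centroid_um,
                        included=(True if restore and r.id in ids else
                                  False if not restore and r.id in ids else
                                  r.included))
           for r in report.lesions]
    return AnalysisReport(lesions=new,
                          bone_surface_area_um2=report.bone_surface_area_um2,
                          bone_surface_area_raw_um2=report.bone_surface_area_raw_um2,
                          voxel_size_um=report.voxel_size_um,
                          params=dict(report.params),
                          labels=report.labels)


def pick_lesion(
    report: AnalysisReport,
    point: tuple[int, int, int],
    d_max_um: float | None = None,
) -> int | None:
    """Return the id of the lesion at (or nearest to) a voxel coordinate.

    The scripted analogue of clicking a lesion in a 3-D view: an exact hit
    returns that lesion; otherwise the nearest lesion within d_max/2 is
    returned (ties broken toward the lower id); beyond that, ``None``.
    """
    labels = report.labels
    if labels is None:
        raise IdError("report carries no label grid")
    z, y, x = (int(c) for c in point)
    if not (0 <= z < labels.shape[0] and 0 <= y < labels.shape[1]
            and 0 <= x < labels.shape[2]):
        raise BoundsError(f"point {point} outside grid {labels.shape}")
    hit = int(labels[z, y, x])
    if hit:
        return hit
    coords = np.argwhere(labels > 0)
    if coords.size == 0:
        return None
    d2 = ((coords - np.array([z, y, x])) ** 2).sum(axis=1)
    dmin = np.sqrt(d2.min())
    if d_max_um is None:
        d_max_um = report.params.get("d_max_um", 0.0)
    if dmin * report.voxel_size_um > d_max_um / 2.0:
        return None
    nearest = coords[d2 == d2.min()]
    return int(min(labels[tuple(c)] for c in nearest))
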