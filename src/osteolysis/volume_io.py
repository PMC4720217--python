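"""Reading and writing of micro-CT volumes, label grids and lesion reports.

Volumes are held as ``(slice, row, col)`` = ``(z, y, x)`` arrays with a single
isotropic voxel size in micrometres.  Slice stacks are the native export
format of desktop micro-CT reconstruction software (one image per axial
slice); multipage TIFF and NIfTI single-file volumes are also accepted.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyInputError, FormatError, InputError

__all__ = [
    "GrayVolume",
    "VoxelVolume",
    "read_stack",
    "write_labels",
    "read_labels",
    "write_report",
    "read_report",
]

_SLICE_EXTENSIONS = {".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass
class GrayVolume:
    """Scalar 3-D intensity grid, pre-threshold.

    Attributes
    ----------
    data : ndarray, shape (slice, row, col)
        Reconstructed attenuation values, unmodified from disk.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres (e.g. 4.3 for a
        high-resolution murine tibia scan).
    source : str
        Provenance string (path or generator description).
    """

    data: np.ndarray
    voxel_size_um: float
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(f"volume must be 3-D with all dims >= 1, got shape {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise InputError(f"voxel_size_um must be positive, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VoxelVolume:
    """Binary 3-D occupancy grid — the sampled bone volume."""

    mask: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3 or min(self.mask.shape) < 1:
            raise FormatError(f"mask must be 3-D with all dims >= 1, got shape {self.mask.shape}")
        if not self.voxel_size_um > 0:
            raise InputError(f"voxel_size_um must be positive, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def count(self) -> int:
        """Number of foreground voxels."""
        return int(np.count_nonzero(self.mask))


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically, so ``file2 < file10``."""
    return tuple(int(tok) if tok.isdigit() else tok.lower()
                 for tok in re.split(r"(\d+)", name))


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:  # collapse colour channels to luminance
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D image, got shape {img.shape}")
    return img


def read_stack(path: str | Path, voxel_size_um: float) -> GrayVolume:
    """Read a slice-stack directory or a single-file volume.

    A directory is interpreted as one image per axial slice, ordered by
    natural filename sort.  Single files may be multipage TIFF or NIfTI
    (``.nii``/``.nii.gz``).

    Raises
    ------
    InputError
        if the path does not exist.
    EmptyInputError
        if the directory contains no readable slices.
    FormatError
        if slice dimensions are inconsistent.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")
    if not voxel_size_um > 0:
        raise InputError(f"voxel_size_um must be positive, got {voxel_size_um}")

    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTENSIONS),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise EmptyInputError(f"no slice images found in {path}")
        slices = [_read_image(p) for p in files]
        first = slices[0].shape
        for p, s in zip(files, slices):
            if s.shape != first:
                raise FormatError(
                    f"inconsistent slice dimensions: {files[0].name} is {first}, "
                    f"{p.name} is {s.shape}")
        data = np.stack(slices, axis=0)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise FormatError(f"{path}: expected 2-D/3-D TIFF, got shape {data.shape}")
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise FormatError(f"{path}: expected a 3-D NIfTI volume, got shape {arr.shape}")
        data = np.ascontiguousarray(arr.T)  # (x, y, z) -> (z, y, x)
    else:
        raise FormatError(f"unsupported volume format: {path.name}")

    if data.shape[0] < 1:
        raise EmptyInputError(f"{path}: zero slices")
    if np.issubdtype(data.dtype, np.floating) and not np.isfinite(data).all():
        raise FormatError(f"{path}: non-finite intensities")
    return GrayVolume(data=data, voxel_size_um=float(voxel_size_um), source=str(path))


def write_labels(labels: np.ndarray, path: str | Path, bits: int | None = None) -> None:
    """Write an integer label grid (0 = background) as a multipage TIFF.

    ``bits`` may force 8/16/32-bit output; a label exceeding the requested
    width raises :class:`FormatError`.
    """
    import tifffile

    labels = np.asarray(labels)
    if labels.ndim != 3 or not np.issubdtype(labels.dtype, np.integer):
        raise FormatError("labels must be a 3-D integer grid")
    top = int(labels.max(initial=0))
    if bits is not None:
        if top >= 2 ** bits:
            raise FormatError(f"label {top} not representable in {bits}-bit output")
        dtype = {8: np.uint8, 16: np.uint16, 32: np.uint32}[bits]
    else:
        dtype = np.uint8 if top < 2 ** 8 else np.uint16 if top < 2 ** 16 else np.uint32
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.astype(dtype), photometric="minisblack")


def read_labels(path: str | Path) -> np.ndarray:
    """Read a label grid written by :func:`write_labels`."""
    import tifffile

    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


# ---------------------------------------------------------------------------
# lesion reports


def write_report(report, path: str | Path) -> None:
    """Emit a lesion report as CSV + JSON.

    ``path`` may carry a ``.csv``/``.json`` suffix or none; both files are
    always written next to each other.  CSV rows are sorted by cap area,
    descending; summary totals follow as ``#``-prefixed footer lines so a
    plain CSV reader can skip them.
    """
    base = Path(path)
    if base.suffix.lower() in {".csv", ".json"}:
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)

    payload = report.to_dict()
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2)

    cols = ["id", "cap_area_um2", "fill_vox",
            "centroid_z_um", "centroid_y_um", "centroid_x_um", "included"]
    with open(base.with_suffix(".csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in report.lesions:
            writer.writerow([rec.id, repr(float(rec.cap_area_um2)), rec.fill_vox,
                             repr(float(rec.centroid_um[0])),
                             repr(float(rec.centroid_um[1])),
                             repr(float(rec.centroid_um[2])),
                             int(rec.included)])
        fh.write(f"# total_lesion_area_um2,{report.total_lesion_area_um2!r}\n")
        fh.write(f"# lesion_percent,{report.lesion_percent!r}\n")
        fh.write(f"# bone_surface_area_um2,{report.bone_surface_area_um2!r}\n")
        fh.write(f"# bone_surface_area_raw_um2,{report.bone_surface_area_raw_um2!r}\n")
        fh.write(f"# params,{json.dumps(report.params)}\n")


def read_report(path: str | Path):
    """Read back a report written by :func:`write_report` (from the JSON)."""
    from .lesions import AnalysisReport

    base = Path(path)
    if base.suffix.lower() in {".csv", ".json"}:
        base = base.with_suffix("")
    json_path = base.with_suffix(".json")
    if not json_path.exists():
        raise InputError(f"no such report: {json_path}")
    with open(json_path) as fh:
        payload = json.load(fh)
    return AnalysisReport.from_dict(payload)
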