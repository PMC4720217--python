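"""Lesion-free bone-surface reconstruction by two-stage volumetric diffusion.

The surface of the binarised bone is first diffused outwards by half the
user-specified maximum lesion diameter, which bridges every surface opening
up to that diameter.  The expanded volume is then contracted from its outer
surface by a locally optimised depth: within overlapping cubic windows tiled
over the expanded surface, the contraction depth is chosen to maximise the
volume-overlap ratio

    rho(d) = |C_d ∩ original| / |C_d|   within the window,

where ``C_d`` is the expanded volume contracted by depth ``d``.  Per-window
depths are blended by trilinear interpolation into a smooth depth field, and
the union of the contracted volume with the original bone forms the final
reconstruction.  Both diffusion stages are realised as level sets of exact
Euclidean distance transforms, so the procedure is deterministic and, on a
well-resolved shell, its non-adaptive limit is a morphological closing with
a ball of radius d_max/2 (provided by :func:`closing_oracle` as reference).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .errors import (ContractViolationError, ParameterError, ResolutionError,
                     ResolutionWarning)
from .volume_io import VoxelVolume

__all__ = ["ReconstructionParams", "DepthField", "expand_volume",
           "contract_adaptive", "reconstruct", "closing_oracle"]


@dataclass
class ReconstructionParams:
    """Tunable parameters of the reconstruction.

    d_max_um
        Maximum lesion diameter in μm; the only physically mandatory input.
        Sets the expansion radius r = d_max/2 and (by default) the local
        optimisation window.
    window_um
        Side of the cubic local-overlap windows; defaults to ``d_max_um``.
    depth_step_vox
        Step of the exhaustive contraction-depth search (1 = every voxel
        depth; r is small, so exhaustive search is cheap).
    connectivity
        Foreground connectivity for lesion labeling, 6 or 26.
    min_lesion_vox
        Noise floor: difference components smaller than this many voxels are
        discarded.
    """

    d_max_um: float
    window_um: float | None = None
    depth_step_vox: int = 1
    connectivity: int = 26
    min_lesion_vox: int = 8

    def __post_init__(self) -> None:
        if not self.d_max_um > 0:
            raise ParameterError(f"d_max_um must be positive, got {self.d_max_um}")
        if self.window_um is None:
            self.window_um = float(self.d_max_um)
        if not self.window_um > 0:
            raise ParameterError(f"window_um must be positive, got {self.window_um}")
        if self.depth_step_vox < 1:
            raise ParameterError("depth_step_vox must be a positive integer")
        if self.connectivity not in (6, 26):
            raise ParameterError(f"connectivity must be 6 or 26, got {self.connectivity}")
        if self.min_lesion_vox < 0:
            raise ParameterError("min_lesion_vox must be non-negative")

    def radius_vox(self, voxel_size_um: float) -> int:
        """Expansion/contraction radius in voxels: floor(d_max / (2 s)).

        Flooring is conservative — the method never fills an opening larger
        than the diameter the user specified.
        """
        ratio = self.d_max_um / voxel_size_um
        if ratio < 2:
            warnings.warn(
                f"d_max {self.d_max_um} μm is below twice the voxel size "
                f"({voxel_size_um} μm); lesions this small are not resolved",
                ResolutionWarning, stacklevel=2)
        r = math.floor(self.d_max_um / (2.0 * voxel_size_um))
        if r < 1:
            raise ResolutionError(
                f"d_max {self.d_max_um} μm is under one voxel radius at "
                f"{voxel_size_um} μm/voxel")
        return r

    def window_vox(self, voxel_size_um: float) -> int:
        w = int(round(self.window_um / voxel_size_um))
        if w < 1:
            raise ParameterError(
                f"window {self.window_um} μm is smaller than one voxel")
        return max(w, 2)


@dataclass
class DepthField:
    """Per-window contraction depths chosen on the expanded surface.

    ``centers`` are the window-center coordinates along each axis;
    ``depth_vox``/``overlap`` are the chosen depth and achieved overlap ratio
    on that center grid; ``valid`` marks windows that contained expanded
    surface (invalid entries are filled from their nearest valid window
    before blending).
    """

    centers: tuple[np.ndarray, np.ndarray, np.ndarray]
    depth_vox: np.ndarray
    overlap: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]


def _edt(mask: np.ndarray) -> np.ndarray:
    return ndimage.distance_transform_edt(mask)


def expand_volume(vol: VoxelVolume, params: ReconstructionParams) -> VoxelVolume:
    """Dilate the bone by the Euclidean radius r = d_max/2.

    Implemented as the sublevel set ``distance-to-bone <= r`` of the exact
    Euclidean distance transform; bridges every surface opening of diameter
    up to d_max.  The expansion is clipped at the grid border — leave a
    margin of at least r voxels around the bone (``reconstruct`` pads
    internally).
    """
    r = params.radius_vox(vol.voxel_size_um)
    expanded = _edt(~vol.mask) <= r
    return VoxelVolume(mask=expanded, voxel_size_um=vol.voxel_size_um)


def _window_centers(lo: int, hi: int, spacing: int) -> np.ndarray:
    """Centers spaced ``spacing`` apart covering [lo, hi] inclusive."""
    n = max(1, math.ceil((hi - lo) / spacing) + 1)
    return lo + spacing * np.arange(n)


def contract_adaptive(
    expanded: VoxelVolume,
    original: VoxelVolume,
    params: ReconstructionParams,
) -> tuple[VoxelVolume, DepthField]:
    """Contract the expanded volume inwards by a locally optimised depth.

    The contraction family is ``C_d = {v : distance-to-exterior(v) > d}``
    for integer depths d = 0, step, ..., r.  In each window the depth with
    the highest overlap ratio rho(d) is chosen (ties broken toward smaller
    depth, i.e. less contraction); windows without expanded-surface voxels
    inherit the depth of their nearest valid window.  Window-center depths
    are blended trilinearly into a per-voxel depth field and the contracted
    volume keeps the voxels deeper than their local depth.
    """
    if expanded.voxel_size_um != original.voxel_size_um:
        raise ContractViolationError("voxel sizes differ between volumes")
    if expanded.shape != original.shape:
        raise ContractViolationError("grids differ between expanded and original")
    if (original.mask & ~expanded.mask).any():
        raise ContractViolationError("expanded volume does not contain the original")

    s = expanded.voxel_size_um
    r = params.radius_vox(s)
    w = params.window_vox(s)
    step = params.depth_step_vox
    depths = np.arange(0, r + 1, step)
    if depths[-1] != r:  # always consider the full radius
        depths = np.append(depths, r)

    exp = expanded.mask
    dist_in = _edt(exp)
    # quantised depth level: voxel belongs to C_d exactly for d < q
    q = np.ceil(dist_in).astype(np.int32)
    q_max = int(q.max(initial=0))
    nbins = q_max + 2

    fg = np.argwhere(exp)
    if fg.size == 0:
        raise ContractViolationError("expanded volume is empty")
    lo = fg.min(axis=0)
    hi = fg.max(axis=0)

    spacing = max(1, w // 2)  # 50 % window overlap
    centers = tuple(_window_centers(lo[a], hi[a], spacing) for a in range(3))
    grid_shape = tuple(len(c) for c in centers)
    depth_grid = np.zeros(grid_shape, dtype=np.int32)
    overlap_grid = np.zeros(grid_shape, dtype=np.float64)
    valid = np.zeros(grid_shape, dtype=bool)

    surface = exp & (q <= 1)
    orig = original.mask
    half = w // 2
    thin_windows = 0

    for iz, cz in enumerate(centers[0]):
        zsl = slice(max(0, cz - half), cz + half + 1)
        for iy, cy in enumerate(centers[1]):
            ysl = slice(max(0, cy - half), cy + half + 1)
            for ix, cx in enumerate(centers[2]):
                xsl = slice(max(0, cx - half), cx + half + 1)
                wexp = exp[zsl, ysl, xsl]
                if not surface[zsl, ysl, xsl].any():
                    continue
                qw = q[zsl, ysl, xsl][wexp]
                qo = q[zsl, ysl, xsl][wexp & orig[zsl, ysl, xsl]]
                # |C_d ∩ W| = #{q > d}: suffix sums of the level histogram
                hw = np.bincount(qw, minlength=nbins)
                denom = hw.sum() - np.cumsum(hw)
                ho = np.bincount(qo, minlength=nbins)
                num = ho.sum() - np.cumsum(ho)
                dn = denom[depths]
                nm = num[depths]
                valid[iz, iy, ix] = True
                ok = dn > 0
                if not ok.any() or nm.max(initial=0) == 0:
                    # no overlap with the original at any depth: either a
                    # fringe window beyond the bone (routine) or a shell
                    # locally thinner than a voxel — contract fully
                    depth_grid[iz, iy, ix] = r
                    overlap_grid[iz, iy, ix] = 0.0
                    thin_windows += 1
                    continue
                rho = np.where(ok, nm / np.maximum(dn, 1), -1.0)
                best = int(np.argmax(rho))  # argmax takes the first (smallest d) on ties
                depth_grid[iz, iy, ix] = depths[best]
                overlap_grid[iz, iy, ix] = rho[best]

    n_valid = int(valid.sum())
    if n_valid and thin_windows > n_valid // 2:
        # fringe windows beyond the bone are expected; a majority with no
        # bone suggests the shell thresholded away (thinner than a voxel)
        warnings.warn(
            f"{thin_windows}/{n_valid} surface windows saw no bone at any "
            "depth (shell thinner than one voxel?); contracted fully there",
            ResolutionWarning, stacklevel=2)

    if not valid.any():
        raise ContractViolationError("no window contained expanded surface")

    if not valid.all():
        # inherit nearest valid window's depth
        _, idx = ndimage.distance_transform_edt(~valid, return_indices=True)
        depth_grid = depth_grid[tuple(idx)]
        overlap_grid = overlap_grid[tuple(idx)]

    field_ = DepthField(centers=centers, depth_vox=depth_grid,
                        overlap=overlap_grid, valid=valid)

    # trilinear blend of window-center depths, queried at expanded voxels
    interp = RegularGridInterpolator(
        tuple(c.astype(float) for c in centers), depth_grid.astype(float),
        method="linear", bounds_error=False, fill_value=None)
    pts = fg.astype(float)
    for a in range(3):
        np.clip(pts[:, a], centers[a][0], centers[a][-1], out=pts[:, a])
    local_depth = interp(pts)

    contracted = np.zeros_like(exp)
    # small tolerance: trilinear blending of integer depths must not drop
    # below the integer value through float roundoff
    keep = dist_in[tuple(fg.T)] > local_depth + 1e-6
    contracted[tuple(fg[keep].T)] = True
    return VoxelVolume(mask=contracted, voxel_size_um=s), field_


def reconstruct(
    original: VoxelVolume, params: ReconstructionParams
) -> tuple[VoxelVolume, DepthField]:
    """Full two-stage reconstruction: expand, contract, union with original.

    The grid is padded internally by r + 1 voxels so the diffusion is never
    clipped at the border; the returned volume is on the input grid.
    Deterministic: identical inputs give voxel-identical outputs.
    """
    r = params.radius_vox(original.voxel_size_um)
    pad = r + 1
    padded = VoxelVolume(
        mask=np.pad(original.mask, pad),
        voxel_size_um=original.voxel_size_um)
    expanded = expand_volume(padded, params)
    contracted, field_ = contract_adaptive(expanded, padded, params)
    merged = contracted.mask | padded.mask
    core = merged[pad:-pad, pad:-pad, pad:-pad]
    return VoxelVolume(mask=core, voxel_size_um=original.voxel_size_um), field_


def closing_oracle(vol: VoxelVolume, d_max_um: float) -> VoxelVolume:
    """Global morphological closing with a Euclidean ball of radius d_max/2.

    The non-adaptive limit of the reconstruction: dilation (distance-to-bone
    <= r) followed by erosion (distance-to-exterior > r), computed on a
    padded grid.  Extensive, idempotent and increasing.
    """
    params = ReconstructionParams(d_max_um=d_max_um)
    r = params.radius_vox(vol.voxel_size_um)
    pad = r + 1
    mask = np.pad(vol.mask, pad)
    dilated = _edt(~mask) <= r
    closed = _edt(dilated) > r
    return VoxelVolume(mask=closed[pad:-pad, pad:-pad, pad:-pad],
                       voxel_size_um=vol.voxel_size_um)
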