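"""Synthetic cortical-bone phantoms with known lesion ground truth.

The generator emulates the object the 3-D lesion pipeline is built for: a
hollow cortical shell (a long-bone diaphysis) with through-holes of known
diameter standing in for osteolytic lesions, an optional narrow "vessel"
canal standing in for the natural nutrient foramen, and additive Gaussian
grayscale noise.  Hole mouths are right cylinders, so every phantom carries
analytic expectations (cap area pi*(d/2)^2, closed-form shell surface area)
against which the pipeline can be validated end to end.

Default conditions are fixed once and mirror a murine tibia imaged at
4.3 μm/voxel: cortical wall 30 voxels (~130 μm), medullary canal wider than
the maximum lesion diameter so it is never mistaken for a lesion, bone/
background attenuation 200/10 with noise up to 10 % of that contrast.

All randomness derives from the spec's integer seed; the generator is pure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .volume_io import GrayVolume

__all__ = ["HoleSpec", "PhantomSpec", "HoleTruth", "PhantomTruth",
           "make_phantom", "make_acute_angle_phantom", "battery_specs"]

SHAPES = ("hollow_cylinder", "capped_shaft", "slab", "triangular_prism")


@dataclass
class HoleSpec:
    """One punched through-hole.

    Placement semantics depend on the phantom shape:
    slab — ``yx`` center, punched along z;
    hollow_cylinder / capped_shaft — ``z`` and ``angle_deg``, punched
    radially outward;
    triangular_prism — ``z`` and ``x``, punched along −y through the front
    face.
    """

    diameter_vox: float
    z: Optional[int] = None
    angle_deg: Optional[float] = None
    yx: Optional[tuple[int, int]] = None
    x: Optional[int] = None


@dataclass
class PhantomSpec:
    shape: str
    outer_size_vox: tuple[int, int, int] = (160, 124, 124)
    wall_thickness_vox: int = 30
    holes: list[HoleSpec] = field(default_factory=list)
    vessel: Optional[HoleSpec] = None
    noise_sd: float = 0.0
    intensities: tuple[float, float] = (200.0, 10.0)
    seed: int = 0
    voxel_size_um: float = 4.3
    pad_vox: int = 16

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise PhantomSpecError(f"unknown shape {self.shape!r}; one of {SHAPES}")
        if self.wall_thickness_vox < 2:
            raise PhantomSpecError("wall thickness must be >= 2 voxels")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be non-negative")
        small = min(self.outer_size_vox)
        for h in list(self.holes) + ([self.vessel] if self.vessel else []):
            if not 0 < h.diameter_vox < small:
                raise PhantomSpecError(
                    f"hole diameter {h.diameter_vox} outside (0, {small})")


@dataclass
class HoleTruth:
    center_vox: tuple[float, float, float]
    diameter_vox: float
    expected_cap_area_um2: float


@dataclass
class PhantomTruth:
    """Ground truth for a generated phantom: the noise-free shell mask, the
    punched holes with their analytic cap areas, and the closed-form
    lesion-free surface area."""

    holes: list[HoleTruth]
    true_surface_area_um2: float
    mask: np.ndarray
    vessel_center_vox: Optional[tuple[float, float, float]] = None
    crease_region: Optional[tuple[int, int, int, int, int, int]] = None


def _cylinder_geometry(spec: PhantomSpec):
    nz, ny, nx = spec.outer_size_vox
    pad = spec.pad_vox
    cy, cx = ny // 2, nx // 2
    r_out = (min(ny, nx) - 2 * pad) / 2.0
    r_in = r_out - spec.wall_thickness_vox
    if r_in < 1:
        raise PhantomSpecError("wall thicker than the shaft radius")
    return nz, ny, nx, pad, cy, cx, r_out, r_in


def _punch_radial(mask: np.ndarray, cy: int, cx: int, hole: HoleSpec) -> None:
    """Carve a radial cylinder of ``diameter_vox`` from the shaft axis
    outward at ``angle_deg`` (measured from +y toward +x), at height ``z``."""
    if hole.z is None or hole.angle_deg is None:
        raise PhantomSpecError("cylindrical shapes need holes with z and angle_deg")
    th = math.radians(hole.angle_deg)
    uy, ux = math.cos(th), math.sin(th)
    zz, yy, xx = np.ogrid[:mask.shape[0], :mask.shape[1], :mask.shape[2]]
    dy, dx, dz = yy - cy, xx - cx, zz - hole.z
    t = dy * uy + dx * ux
    d2 = dz ** 2 + dy ** 2 + dx ** 2 - t ** 2
    mask &= ~((t >= 0) & (d2 < (hole.diameter_vox / 2.0) ** 2))


def _build_shell(spec: PhantomSpec) -> tuple[np.ndarray, float, list[tuple]]:
    """Return (mask, analytic surface area in vox^2, hole mouth centers)."""
    nz, ny, nx = spec.outer_size_vox
    pad = spec.pad_vox
    t = spec.wall_thickness_vox
    mask = np.zeros(spec.outer_size_vox, dtype=bool)
    centers: list[tuple] = []

    if spec.shape == "slab":
        y0, y1 = pad, ny - pad
        x0, x1 = pad, nx - pad
        mask[pad:pad + t, y0:y1, x0:x1] = True
        a, b = y1 - y0, x1 - x0
        sa = 2.0 * (a * b + a * t + b * t)
        for h in spec.holes:
            if h.yx is None:
                raise PhantomSpecError("slab holes need a yx center")
            hy, hx = h.yx
            rad = h.diameter_vox / 2.0
            if not (y0 + rad <= hy <= y1 - rad and x0 + rad <= hx <= x1 - rad):
                raise PhantomSpecError(f"hole at {h.yx} falls outside the slab wall")
            yy, xx = np.ogrid[:ny, :nx]
            mask &= ~(((yy - hy) ** 2 + (xx - hx) ** 2 < rad ** 2)[None])
            centers.append((pad + t / 2.0, float(hy), float(hx)))

    elif spec.shape in ("hollow_cylinder", "capped_shaft"):
        nz, ny, nx, pad, cy, cx, r_out, r_in = _cylinder_geometry(spec)
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        rr2 = (yy - cy) ** 2 + (xx - cx) ** 2
        shaft = (zz >= pad) & (zz < nz - pad)
        annulus = (rr2 < r_out ** 2) & (rr2 >= r_in ** 2)
        mask |= shaft & annulus
        h_len = nz - 2 * pad
        if spec.shape == "capped_shaft":
            caps = (((zz >= pad) & (zz < pad + t)) |
                    ((zz >= nz - pad - t) & (zz < nz - pad)))
            mask |= caps & (rr2 < r_out ** 2)
            sa = (2 * math.pi * r_out * h_len + 2 * math.pi * r_out ** 2 +
                  2 * math.pi * r_in * (h_len - 2 * t) + 2 * math.pi * r_in ** 2)
        else:
            sa = (2 * math.pi * (r_out + r_in) * h_len +
                  2 * (math.pi * r_out ** 2 - math.pi * r_in ** 2))
        r_mid = (r_out + r_in) / 2.0
        for h in spec.holes:
            lo = pad + (t if spec.shape == "capped_shaft" else 0)
            hi = nz - lo
            rad = h.diameter_vox / 2.0
            if h.z is None or not (lo + rad <= h.z <= hi - rad):
                raise PhantomSpecError(f"hole z={h.z} falls outside the shaft wall")
            _punch_radial(mask, cy, cx, h)
            th = math.radians(h.angle_deg)
            centers.append((float(h.z), cy + r_mid * math.cos(th),
                            cx + r_mid * math.sin(th)))

    else:  # triangular_prism
        from shapely.geometry import Polygon
        from skimage.draw import polygon as draw_polygon

        cy, cx = ny // 2, nx // 2
        r_circ = (min(ny, nx) - 2 * pad) / 2.0
        angles = [math.radians(a) for a in (180.0, 60.0, -60.0)]
        verts = [(cy + r_circ * math.cos(a), cx + r_circ * math.sin(a))
                 for a in angles]  # flat face faces -y
        ry, rx = draw_polygon([v[0] for v in verts], [v[1] for v in verts],
                              shape=(ny, nx))
        outer2d = np.zeros((ny, nx), dtype=bool)
        outer2d[ry, rx] = True
        inner2d = ndimage.distance_transform_edt(outer2d) > t
        shell2d = outer2d & ~inner2d
        mask[pad:nz - pad] = shell2d[None]
        h_len = nz - 2 * pad
        poly = Polygon(verts)
        inner = poly.buffer(-t)  # round joins, matching the EDT erosion
        sa = ((poly.length + inner.length) * h_len +
              2 * (poly.area - inner.area))
        for h in spec.holes:
            if h.z is None or h.x is None:
                raise PhantomSpecError("prism holes need z and x")
            zz, yy, xx = np.ogrid[:nz, :ny, :nx]
            rad = h.diameter_vox / 2.0
            front_y = min(v[0] for v in verts)
            col = ((zz - h.z) ** 2 + (xx - h.x) ** 2 < rad ** 2) & (yy < cy)
            if not (mask & col).any():
                raise PhantomSpecError(f"prism hole at z={h.z}, x={h.x} misses the wall")
            mask &= ~col
            centers.append((float(h.z), front_y + t / 2.0, float(h.x)))

    return mask, sa, centers


def make_phantom(spec: PhantomSpec) -> tuple[GrayVolume, PhantomTruth]:
    """Generate a grayscale phantom volume and its ground truth.

    The shell is drawn at the bone intensity on the background intensity,
    holes (and the optional vessel canal) are punched as right cylinders
    rasterised strictly (voxel centers closer than d/2 to the axis), and
    Gaussian noise with sd ``noise_sd`` is added from the spec's seed.
    """
    mask, sa_vox2, centers = _build_shell(spec)
    vessel_center = None
    if spec.vessel is not None:
        if spec.shape == "slab":
            yy, xx = np.ogrid[:mask.shape[1], :mask.shape[2]]
            hy, hx = spec.vessel.yx
            mask &= ~(((yy - hy) ** 2 + (xx - hx) ** 2 <
                       (spec.vessel.diameter_vox / 2.0) ** 2)[None])
            vessel_center = (spec.pad_vox + spec.wall_thickness_vox / 2.0,
                             float(hy), float(hx))
        else:
            nz, ny, nx, pad, cy, cx, r_out, r_in = _cylinder_geometry(spec)
            _punch_radial(mask, cy, cx, spec.vessel)
            th = math.radians(spec.vessel.angle_deg)
            r_mid = (r_out + r_in) / 2.0
            vessel_center = (float(spec.vessel.z), cy + r_mid * math.cos(th),
                             cx + r_mid * math.sin(th))

    bone, bg = spec.intensities
    s = spec.voxel_size_um
    data = np.where(mask, float(bone), float(bg))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    gray = GrayVolume(data=data, voxel_size_um=s,
                      source=f"phantom:{spec.shape}:seed={spec.seed}")

    holes = [HoleTruth(center_vox=c, diameter_vox=h.diameter_vox,
                       expected_cap_area_um2=math.pi * (h.diameter_vox / 2.0) ** 2 * s ** 2)
             for h, c in zip(spec.holes, centers)]
    truth = PhantomTruth(holes=holes, true_surface_area_um2=sa_vox2 * s ** 2,
                         mask=mask, vessel_center_vox=vessel_center)
    return gray, truth


def make_acute_angle_phantom(
    spec: PhantomSpec,
    groove_angle_deg: float = 20.0,
    groove_depth_vox: int = 40,
    floor_halfwidth_vox: int = 3,
    fillet_vox: int = 5,
    convex: bool = False,
) -> tuple[GrayVolume, PhantomTruth]:
    """Known-failure fixture: a block with an acute re-entrant groove.

    The groove runs along y with ``groove_angle_deg`` between its walls and
    a flat, filleted floor; it contains **zero** true lesions, yet a
    reconstruction whose maximum lesion diameter spans the groove mouth will
    (by design of the method, which treats any concavity up to d_max as a
    lesion) report spurious lesions along the crease.  With d_max well below
    the mouth width the rolling ball reaches the filleted floor and nothing
    is reported.  With ``convex`` the groove is omitted and the block edge
    is chamfered instead — a convex solid on which no lesion can appear.
    """
    nz, ny, nx = spec.outer_size_vox
    pad = spec.pad_vox
    top = nz - pad
    mask = np.zeros(spec.outer_size_vox, dtype=bool)
    mask[pad:top, pad:ny - pad, pad:nx - pad] = True
    crease = None

    if convex:
        # 45-degree chamfer along one top edge: still convex everywhere
        zz, _, xx = np.ogrid[:nz, :ny, :nx]
        mask &= ~((zz - (top - 20)) > (xx - pad))
    else:
        cx = nx // 2
        fz = top - groove_depth_vox
        tan_half = math.tan(math.radians(groove_angle_deg / 2.0))
        zz2, xx2 = np.ogrid[:nz, :nx]
        air2 = (zz2 >= fz) & (np.abs(xx2 - cx) <
                              floor_halfwidth_vox + (zz2 - fz) * tan_half)
        if fillet_vox > 0:  # round the floor corners: open the air region
            er = ndimage.distance_transform_edt(air2) > fillet_vox
            air2 = ndimage.distance_transform_edt(~er) <= fillet_vox
        air2 |= zz2 >= top
        mask &= ~np.broadcast_to(air2[:, None, :], mask.shape)
        mouth_half = floor_halfwidth_vox + groove_depth_vox * tan_half
        crease = (fz - 2, top, pad, ny - pad,
                  int(cx - mouth_half - 2), int(cx + mouth_half + 3))

    bone, bg = spec.intensities
    data = np.where(mask, float(bone), float(bg))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    gray = GrayVolume(data=data, voxel_size_um=spec.voxel_size_um,
                      source=f"phantom:acute_wedge:seed={spec.seed}")
    truth = PhantomTruth(holes=[], true_surface_area_um2=float("nan"),
                         mask=mask, crease_region=crease)
    return gray, truth


def battery_specs(
    n_phantoms: int = 20,
    seed: int = 0,
    diameter_range: tuple[int, int] = (8, 24),
    max_noise_fraction: float = 0.10,
) -> list[PhantomSpec]:
    """The seeded validation battery: capped hollow shafts with 1–2 radial
    through-holes of 8–24 voxel diameter and noise up to 10 % of the
    bone/background contrast.  Deterministic given ``seed``.

    The medullary canal (radius 26) clears the probing ball (radius 12 at
    the battery's d_max of 24 voxels) with a wide margin and holes sit on
    well-separated z levels, so every punched lesion labels as its own
    component.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_phantoms):
        n_holes = int(rng.integers(1, 3))
        angles = rng.permutation([0.0, 90.0, 180.0, 270.0])[:n_holes]
        zs = [88, 152][:n_holes]
        dias = rng.integers(diameter_range[0], diameter_range[1] + 1, size=n_holes)
        holes = [HoleSpec(diameter_vox=int(d), z=int(z), angle_deg=float(a))
                 for d, z, a in zip(dias, zs, angles)]
        contrast = 190.0
        nz = 240 if n_holes == 2 else 176
        specs.append(PhantomSpec(
            shape="capped_shaft",
            outer_size_vox=(nz, 144, 144),
            wall_thickness_vox=30,
            holes=holes,
            noise_sd=float(rng.uniform(0.0, max_noise_fraction)) * contrast,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        ))
    return specs
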