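# Methods

## Problem and model

Cancer-induced bone disease (multiple myeloma, metastatic breast cancer)
erodes focal *osteolytic lesions* through the cortical shell of long bones.
In murine models these are imaged ex vivo by micro-CT at a few μm per voxel,
and the disease burden is summarised as the total lesion area as a
proportion of the bone surface. This package quantifies that burden in 3-D:
it reconstructs what the cortical surface would look like without lesions,
subtracts the actual bone, and measures each filled hole.

The reconstruction is a two-stage volumetric diffusion on the binarised
bone volume `O`:

1. **Expansion.** `O` is dilated by the Euclidean radius `r = D_max / 2`,
   where `D_max` is the user-specified maximum lesion diameter. Implemented
   as the sublevel set `dist(·, O) ≤ r` of an exact Euclidean distance
   transform, this bridges every surface opening of diameter up to `D_max`.
2. **Adaptive contraction.** The expanded volume `E` is contracted from its
   outer surface by a locally chosen depth. The contraction family is
   `C_d = {v ∈ E : dist(v, ∂E_out) > d}` for integer depths `d = 0 … r`.
   Cubic windows of side `window_um` (default `D_max`) are tiled over the
   expanded surface with 50 % overlap; in each window the depth `d*`
   maximising the volume-overlap ratio `ρ(d) = |C_d ∩ O|_W / |C_d|_W` is
   selected (ties toward smaller depth). Window-center depths are blended
   trilinearly into a per-voxel depth field, and the contracted volume
   keeps the voxels deeper than their local depth.

The final reconstruction is `contracted ∪ O`. The lesion field is the
difference `R \ O`, labeled with 26-connectivity (background uses the
complementary 6-connectivity throughout, avoiding topological paradoxes).

### A provable degeneracy worth knowing about

With the volume-overlap (precision-type) ratio above, every original-bone
voxel lies deeper than `r` in the expanded volume, so the numerator of
`ρ(d)` is constant in `d` while the denominator is non-increasing. In any
window that sees both bone and exterior the optimum is therefore exactly
`d* = r`, and the whole adaptive contraction coincides, voxel for voxel,
with a **global morphological closing** by a ball of radius `r`. The window
machinery still matters at degenerate windows (shell locally thinner than a
voxel, or windows seeing no bone at all), where it contracts fully rather
than leaving halo artefacts, and it is the hook for alternative overlap
definitions (e.g. surface overlap) that would genuinely localise the depth.
The tests exploit the degeneracy: on flat and convex phantoms the pipeline
must equal `closing_oracle`, which itself is validated against an
independent dilate/erode implementation with an explicit ball structuring
element.

A practical consequence of ball-closing geometry: a through-hole of
diameter `D` in a wall of thickness `t` is bridged only if the ball cannot
sag through it from both faces, i.e. roughly `2(r − √(r² − (D/2)²)) < t`.
At `D = D_max` the continuum ball passes tangentially, so exact selectivity
at the boundary relies on strict hole rasterisation (voxel centers closer
than `D/2` to the axis), which keeps the digital hole a shade under its
nominal diameter. The phantom battery's wall of 30 voxels (~130 μm at the
4.3 μm default — a realistic murine cortical thickness) satisfies the
inequality across the battery's whole diameter range.

## Measurements

- **Cap (lesion) area.** Each lesion's reported area is the area of its
  mouth on the reconstructed surface, computed as the *vector area* of the
  exposed patch: faces of lesion voxels adjacent to border-reachable
  exterior are grouped into 26-connected patches, and the magnitude of the
  sum of outward unit face normals is taken for the largest patch. The
  vector area of any cap equals the flat area enclosed by its rim, so the
  estimate is exact for flat caps, insensitive to how far the cap drapes
  into the hole, and orientation-independent — unlike raw face counting,
  which is biased by up to ±41 % depending on surface orientation. A
  through-tunnel contributes its largest mouth (patches are separated by
  the wall thickness); summing both mouths would cancel the normals.
- **Bone surface area** (the denominator of the lesion percent) uses
  classical face counting over the reconstructed volume with the 2/3
  isotropy correction (face counting overestimates smooth surfaces by 3/2
  in expectation); the uncorrected count is also reported since both
  conventions are in use in bone μCT. The *reconstructed* surface is used
  so the denominator does not shrink as disease grows.
- **Enclosed components** of the difference with no opening on the
  reconstructed surface (e.g. fill rings where a sealed medullary canal
  meets the end of the shaft) are not osteolytic lesions and are dropped;
  components smaller than `min_lesion_vox` (default 8) are dropped as
  threshold noise.
- **De-selection** of natural openings (nutrient vessel canal) is manual
  by lesion id or 3-D pick; records are retained with a cleared flag so
  exclusions stay auditable. No automatic vessel classification is
  attempted: widened natural holes are indistinguishable from disease
  without expertise.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `d_max_um` | — (user) | maximum lesion diameter; 900 μm is a typical choice for murine tibiae |
| `voxel_size_um` | — (user) | isotropic voxel size; 4.3 μm in the reference scan geometry |
| `window_um` | `d_max_um` | side of the local-overlap windows |
| `depth_step_vox` | 1 | contraction-depth search step (exhaustive; `r` is at most ~105 voxels at reference settings) |
| `connectivity` | 26 | lesion labeling connectivity |
| `min_lesion_vox` | 8 | noise floor for difference components |

The voxel radius is `r = floor(d_max_um / (2 · voxel_size_um))` — flooring
is conservative: the method never fills an opening larger than the
specified maximum (900 μm at 4.3 μm/voxel gives r = 104). A diameter under
twice the voxel size raises a resolution warning, consistent with the
rule of thumb that a feature needs ~4 voxels across to be detected
reliably.

## Synthetic phantoms

`make_phantom` builds hollow cortical shells (slab, open hollow cylinder,
end-capped shaft, hollow triangular prism) with through-holes punched as
right cylinders normal to the wall, an optional narrow vessel canal, and
additive Gaussian noise, all derived from one integer seed. Ground truth
carries the noise-free mask, each hole's analytic mouth area
`π(d/2)²·s²`, and the closed-form continuum surface area of the
lesion-free shell. The battery used for validation
(`battery_specs`) fixes: capped shafts, wall 30 voxels, medullary canal
radius 26 voxels (clearing the d_max = 24 voxel probing ball with margin —
a marginal canal is only restored marginally by the closing and digitises
into spurious sleeves), holes of 8–24 voxels on z-levels 64 voxels apart,
noise up to 10 % of the bone/background contrast, 20 phantoms.

What the phantoms do **not** emulate: irregular lesion shapes, trabecular
architecture, partial-volume and beam-hardening artefacts, ring artefacts,
intensity inhomogeneity. Passing the battery therefore demonstrates the
geometric correctness of the reconstruction and measurement chain, not
robustness to scanner physics.

`make_acute_angle_phantom` is the documented failure fixture: a block with
a re-entrant groove whose walls meet at 20°, a flat floor and a filleted
(radius 5) root, and zero true lesions. A mathematically sharp crease would
be filled at *every* probing radius (the fill scales as r² but never
vanishes), so the fixture fillets the root: with `d_max` spanning the
groove mouth the pipeline reports a spurious crease lesion, and with
`d_max` well below the mouth the ball reaches the floor and reports
nothing. Structures rich in acute angles (vertebrae, trabecular bone) are
outside the method's domain for exactly this reason.

## The 2-D baseline

`baseline2d` reproduces the classical workflow: the bone is clipped in
half, the remaining half is orthographically projected along one of three
face directions (concave / fibular / flat), and the lesion percent is the
interior background area of the silhouette over the silhouette area
(holes included in the denominator, keeping the measure ≤ 100 %). Its
estimate depends on the chosen face and clip plane — the variability
mechanism the 3-D method eliminates — which the tests assert on a shared
phantom. Camera geometry is an axis-aligned stand-in; reproducing any
specific rendering setup is out of scope.

## Numerical choices and edge cases

- Distance transforms are exact Euclidean (`scipy.ndimage`); all
  morphology is defined through them, so two runs are bit-identical.
- `reconstruct` pads the grid by `r + 1` internally so diffusion is never
  clipped at the border; `expand_volume` called directly documents the
  margin requirement instead.
- The blended depth field is compared against voxel depths with a 1e-6
  tolerance: trilinear interpolation of an integer-constant field may land
  a hair below the integer and must not flip voxels at exactly depth `r`.
- Ties in the per-window depth search go to the smaller depth (less
  contraction); windows with no bone at any depth contract fully and warn.
- Thresholds are validated against the dtype's representable range for
  integer volumes; float volumes only require finiteness. NaNs are
  rejected.
- Slice stacks are ordered by natural filename sort (`slice2` before
  `slice10`), matching scanner export conventions. Anisotropic voxels are
  rejected rather than resampled.

## Problem sizes

Validation runs use phantoms of ~2–5 M voxels with `d_max = 24` voxels —
the geometry scaled so that hole diameter : voxel ratios (8–24) bracket
the reference in-vivo setting (a 900 μm lesion cap at 4.3 μm is ~209
voxels across) while keeping the battery quick to regenerate. All sizes
are fixed in `battery_specs` and the test fixtures.

## Known limitations

- With the volume-overlap ratio the contraction is globally the ball
  closing (see above); heavily concave anatomy (flared metaphyses) is
  smoothed accordingly, and acute creases read as lesions.
- Lesion mouths closer together than roughly the probing diameter can
  merge into one reported lesion; counts are reliable for well-separated
  lesions.
- Cap areas assume a reasonably planar mouth; strongly saddle-shaped
  openings are underestimated by the vector area.
- The 2-D baseline is a qualitative comparator, not a calibrated
  reimplementation of any specific historical pipeline.
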