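"""Two-stage surface reconstruction: expansion, adaptive contraction, closing."""

import numpy as np
import pytest
from scipy import ndimage

from osteolysis import (ReconstructionParams, VoxelVolume, closing_oracle,
                        contract_adaptive, expand_volume, reconstruct)
from osteolysis.errors import (ContractViolationError, ParameterError,
                               ResolutionError)

from conftest import VOXEL_UM, digital_ball, slab_with_holes

S6 = ndimage.generate_binary_structure(3, 1)
S26 = ndimage.generate_binary_structure(3, 3)


def _params(d_max_vox, **kw):
    return ReconstructionParams(d_max_um=d_max_vox * VOXEL_UM, **kw)


def _ball_structuring_element(r):
    zz, yy, xx = np.ogrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return zz ** 2 + yy ** 2 + xx ** 2 <= r ** 2


def _through(mask, y0, x0):
    """Is the former hole axis still a background passage top-to-bottom?"""
    lab, _ = ndimage.label(~mask, structure=S6)
    return lab[0, y0, x0] == lab[-1, y0, x0]


class TestExpand:
    def test_single_voxel_expands_to_digital_ball(self):
        mask = np.zeros((15, 15, 15), bool)
        mask[7, 7, 7] = True
        vol = VoxelVolume(mask=mask, voxel_size_um=VOXEL_UM)
        out = expand_volume(vol, _params(6))
        # brute-force oracle: Euclidean distance to the seed over the grid
        zz, yy, xx = np.indices(mask.shape)
        oracle = np.sqrt((zz - 7) ** 2 + (yy - 7) ** 2 + (xx - 7) ** 2) <= 3
        np.testing.assert_array_equal(out.mask, oracle)

    def test_expansion_is_a_superset(self, small_shaft):
        gray, truth = small_shaft
        vol = VoxelVolume(mask=truth.mask, voxel_size_um=VOXEL_UM)
        out = expand_volume(vol, _params(10))
        assert not (vol.mask & ~out.mask).any()

    def test_hole_absent_from_expanded_border_reachable_background(self):
        vol, holes, _ = slab_with_holes([10], thickness=20)
        out = expand_volume(vol, _params(20))
        _, y0, x0 = holes[0]
        assert not _through(out.mask, y0, x0)

    def test_subvoxel_radius_raises(self):
        vol = digital_ball(3)
        with pytest.raises(ResolutionError):
            expand_volume(vol, ReconstructionParams(d_max_um=0.5 * VOXEL_UM))


class TestContract:
    def test_degenerate_expanded_equals_original(self):
        vol = digital_ball(6)
        contracted, field = contract_adaptive(vol, vol, _params(2))
        np.testing.assert_array_equal(contracted.mask, vol.mask)
        assert field.depth_vox[field.valid].max(initial=0) == 0

    def test_contract_requires_containment(self):
        big = digital_ball(6)
        small = VoxelVolume(mask=ndimage.binary_erosion(big.mask),
                            voxel_size_um=VOXEL_UM)
        with pytest.raises(ContractViolationError):
            contract_adaptive(small, big, _params(4))

    def test_window_below_voxel_size_raises(self):
        with pytest.raises(ParameterError):
            ReconstructionParams(d_max_um=40.0, window_um=0.0)

    def test_cap_over_hole_stays_near_surface_plane(self):
        # away from the hole the surface is restored exactly; over the hole
        # the cap may sag by the ball-drape depth (~1 voxel here, <=2 digital)
        vol, holes, margin = slab_with_holes([10], thickness=20)
        recon, _ = reconstruct(vol, _params(20))
        d, y0, x0 = holes[0]
        yy, xx = np.ogrid[:vol.shape[1], :vol.shape[2]]
        col = (yy - y0) ** 2 + (xx - x0) ** 2 < (d / 2.0) ** 2
        sub = recon.mask[:, col]
        tops = [np.nonzero(sub[:, c])[0].min() for c in range(sub.shape[1])]
        assert max(tops) - margin <= 2
        # away from the hole the flat surface is restored exactly
        np.testing.assert_array_equal(recon.mask[:, ~col], vol.mask[:, ~col])

    def test_depth_field_invariants(self):
        vol, _, _ = slab_with_holes([8], thickness=20)
        params = _params(16)
        padded = VoxelVolume(mask=np.pad(vol.mask, 9), voxel_size_um=VOXEL_UM)
        expanded = expand_volume(padded, params)
        _, field = contract_adaptive(expanded, padded, params)
        r = params.radius_vox(VOXEL_UM)
        assert field.depth_vox.min() >= 0 and field.depth_vox.max() <= r
        assert field.overlap.min() >= 0.0 and field.overlap.max() <= 1.0


class TestClosingOracle:
    def test_closing_of_ball_is_idempotent_identity(self):
        ball = digital_ball(8)
        closed = closing_oracle(ball, 10 * VOXEL_UM)
        np.testing.assert_array_equal(closed.mask, ball.mask)

    def test_closing_is_extensive_on_random_masks(self):
        rng = np.random.default_rng(5)
        mask = ndimage.binary_dilation(rng.random((20, 20, 20)) > 0.97,
                                       iterations=2)
        vol = VoxelVolume(mask=mask, voxel_size_um=1.0)
        closed = closing_oracle(vol, 6.0)
        assert not (mask & ~closed.mask).any()
        again = closing_oracle(closed, 6.0)
        np.testing.assert_array_equal(again.mask, closed.mask)

    def test_matches_independent_dilate_erode_implementation(self):
        # second, independent oracle: scipy binary morphology with an
        # explicit ball structuring element
        vol, holes, _ = slab_with_holes([10], thickness=14, margin=14)
        r = 5
        closed = closing_oracle(vol, 2 * r * VOXEL_UM)
        se = _ball_structuring_element(r)
        pad = r + 1
        ref = ndimage.binary_erosion(
            ndimage.binary_dilation(np.pad(vol.mask, pad), structure=se),
            structure=se)[pad:-pad, pad:-pad, pad:-pad]
        np.testing.assert_array_equal(closed.mask, ref)


class TestReconstruct:
    def test_lesion_free_convex_phantom_reconstructs_to_itself(self):
        ball = digital_ball(10)
        recon, _ = reconstruct(ball, _params(12))
        np.testing.assert_array_equal(recon.mask, ball.mask)

    def test_holes_within_dmax_filled_to_cylinder_volume(self):
        vol, holes, _ = slab_with_holes([8, 16], thickness=40)
        recon, _ = reconstruct(vol, _params(20))
        diff = recon.mask & ~vol.mask
        lab, n = ndimage.label(diff, structure=S26)
        assert n == 2
        for comp in range(1, n + 1):
            com = ndimage.center_of_mass(lab == comp)
            d = min(holes, key=lambda h: abs(h[2] - com[2]))[0]
            analytic = np.pi * (d / 2.0) ** 2 * 40
            assert (lab == comp).sum() == pytest.approx(analytic, rel=0.20)

    def test_hole_wider_than_dmax_not_filled(self):
        vol, holes, _ = slab_with_holes([40], thickness=40)
        recon, _ = reconstruct(vol, _params(20))
        _, y0, x0 = holes[0]
        assert _through(recon.mask, y0, x0)
        d = holes[0][0]
        yy, xx = np.ogrid[:vol.shape[1], :vol.shape[2]]
        col = (yy - y0) ** 2 + (xx - x0) ** 2 < (d / 2.0) ** 2
        in_hole_fill = (recon.mask & ~vol.mask)[:, col].sum()
        assert in_hole_fill < 0.05 * np.pi * (d / 2.0) ** 2 * 40

    def test_extensivity_and_determinism(self, small_shaft):
        _, truth = small_shaft
        vol = VoxelVolume(mask=truth.mask, voxel_size_um=VOXEL_UM)
        a, _ = reconstruct(vol, _params(24))
        b, _ = reconstruct(vol, _params(24))
        assert not (vol.mask & ~a.mask).any()
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_filled_volume_monotone_in_dmax(self, small_shaft):
        _, truth = small_shaft
        vol = VoxelVolume(mask=truth.mask, voxel_size_um=VOXEL_UM)
        fills = []
        for d_vox in (8, 16, 24):
            recon, _ = reconstruct(vol, _params(d_vox))
            fills.append(int((recon.mask & ~vol.mask).sum()))
        assert fills == sorted(fills)

    def test_adaptive_equals_closing_on_flat_and_convex_phantoms(self):
        for vol in (slab_with_holes([10], thickness=20)[0], digital_ball(9)):
            recon, _ = reconstruct(vol, _params(12))
            oracle = closing_oracle(vol, 12 * VOXEL_UM)
            np.testing.assert_array_equal(recon.mask, oracle.mask | vol.mask)

    def test_paper_scale_radius_conversion(self):
        # 900 um maximum lesion diameter at 4.3 um voxels -> 104-voxel radius
        assert ReconstructionParams(d_max_um=900.0).radius_vox(4.3) == 104
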