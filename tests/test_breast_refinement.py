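"""Tests of the breast-mask refinement chain on constructed fixtures and phantoms."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from breastdens import BinaryMask, PhantomSpec, generate_phantom, make_leakage_fixture
from breastdens.breast_refinement import (
    FOREGROUND,
    BreastComponent,
    RefinementParams,
    build_breast_mask,
    close_concavities,
    cut_at_sternum,
    evaluate_components,
    extract_largest_component,
    fill_holes_and_exclude_lower,
    find_reference_slice,
    propagate_boundaries,
    update_slice,
)
from conftest import dice

SP = (1.0, 1.0, 1.0)


def _mask(arr):
    return BinaryMask(data=np.asarray(arr, dtype=np.uint8), spacing=SP)


def _comp(fg, spacing=SP):
    return BreastComponent.from_foreground(np.asarray(fg, dtype=bool), spacing)


def _disk(n, cy, cx, r):
    yy, xx = np.mgrid[:n, :n]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestLargestComponent:
    def test_single_blob_kept_with_center_of_mass(self):
        fg = np.zeros((4, 10, 10), dtype=np.uint8)
        fg[1:3, 2:5, 2:5] = 1
        comp = extract_largest_component(_mask(fg))
        np.testing.assert_array_equal(comp.foreground, fg.astype(bool))
        assert comp.centroid == pytest.approx((1.5, 3.0, 3.0))
        assert comp.bbox == ((1, 2, 2), (2, 4, 4))

    def test_larger_of_two_blobs_kept(self):
        fg = np.zeros((3, 12, 12), dtype=np.uint8)
        fg[1, 1:6, 1:5] = 1  # 20 voxels
        fg[1, 8:10, 8:10] = 1  # 4 voxels
        comp = extract_largest_component(_mask(fg))
        assert comp.foreground.sum() == 20
        assert not comp.foreground[1, 8, 8]

    def test_tie_broken_deterministically(self):
        fg = np.zeros((3, 12, 12), dtype=np.uint8)
        fg[1, 1:3, 1:3] = 1
        fg[1, 8:10, 8:10] = 1
        a = extract_largest_component(_mask(fg))
        b = extract_largest_component(_mask(fg))
        np.testing.assert_array_equal(a.foreground, b.foreground)
        assert a.foreground.sum() == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extract_largest_component(_mask(np.zeros((2, 4, 4))))

    def test_signed_labels(self):
        fg = np.zeros((2, 4, 4), dtype=np.uint8)
        fg[0, 1, 1] = 1
        comp = extract_largest_component(_mask(fg))
        assert set(np.unique(comp.labels)) == {-1, 1}


class TestReferenceSlice:
    def test_identical_slices_select_centroid(self):
        fg = np.zeros((9, 20, 20), dtype=bool)
        fg[:, 5:15, 5:15] = True
        comp = _comp(fg)
        assert find_reference_slice(comp) == 4

    def test_slice_with_leakage_lobe_not_selected(self):
        # lobe on the slice after the centroid is a large difference component
        n = 32
        fg = np.zeros((9, n, n), dtype=bool)
        base = _disk(n, 10, 16, 8)
        fg[:] = base
        lobe_slice = 5  # z_c + 1
        fg[lobe_slice] |= _disk(n, 24, 16, 5)  # ~28% of base area, > T = 5%
        comp = _comp(fg)
        z_ref = find_reference_slice(comp)
        assert z_ref != lobe_slice
        assert z_ref not in (4, 6)  # neighbours see the lobe as a big difference

    def test_two_slice_stack_rejected(self):
        fg = np.zeros((2, 8, 8), dtype=bool)
        fg[:, 2:6, 2:6] = True
        with pytest.raises(ValueError):
            find_reference_slice(_comp(fg))


class TestEvaluateAndUpdate:
    def test_identical_slices_keep_everything(self):
        n = 32
        sl = _disk(n, 16, 10, 6) | _disk(n, 16, 24, 6)
        kept, ws, ids = evaluate_components(sl, sl)
        rebuilt = update_slice(kept, sl.shape, ws, ids, original_mask=sl) == FOREGROUND
        np.testing.assert_array_equal(rebuilt, sl)

    def test_lobe_joined_by_neck_discarded(self):
        n = 40
        breast = _disk(n, 12, 20, 9)
        lobe = _disk(n, 30, 20, 6)
        neck = np.zeros_like(breast)
        neck[12:30, 19:21] = True
        j = breast | lobe | neck
        kept, ws, ids = evaluate_components(breast, j)
        rebuilt = update_slice(kept, j.shape, ws, ids, original_mask=j) == FOREGROUND
        assert not rebuilt[30, 20]  # lobe centre removed
        assert rebuilt[12, 20]  # breast centre kept
        assert (rebuilt & lobe).sum() / lobe.sum() < 0.05

    def test_empty_j_slice_gives_empty_result(self):
        i = _disk(16, 8, 8, 4)
        kept, ws, ids = evaluate_components(i, np.zeros_like(i))
        assert kept == []
        out = update_slice(kept, i.shape)
        assert (out == FOREGROUND).sum() == 0

    def test_empty_reference_slice_rejected(self):
        j = _disk(16, 8, 8, 4)
        with pytest.raises(ValueError):
            evaluate_components(np.zeros_like(j), j)

    def test_single_component_update(self):
        m = _disk(16, 8, 8, 4)
        out = update_slice([m], m.shape)
        np.testing.assert_array_equal(out == FOREGROUND, m)


class TestPropagation:
    def test_smooth_neck_free_stack_unchanged(self):
        # a stack of smoothly varying solid cross-sections has no necks and
        # no nucleating pockets: propagation is the identity on it
        n = 40
        fg = np.zeros((12, n, n), dtype=bool)
        for z in range(12):
            r = 8 + 4 * np.sin(np.pi * z / 11)
            fg[z] = _disk(n, 14, 20, r)
        comp = _comp(fg)
        out = propagate_boundaries(comp, find_reference_slice(comp))
        np.testing.assert_array_equal(out.foreground, comp.foreground)

    def test_leakage_free_phantom_nearly_unchanged(self, truth1):
        # texture-enclosed fat pockets that nucleate mid-stack are discarded
        # at birth (one-directional sweep); the loss stays marginal
        comp = extract_largest_component(truth1.fat_mask)
        out = propagate_boundaries(comp, find_reference_slice(comp))
        deleted = comp.foreground & ~out.foreground
        assert deleted.sum() / comp.foreground.sum() < 0.01
        assert not (out.foreground & ~comp.foreground).any()

    def test_lobe_removed_with_small_collateral_damage(self, truth1):
        leak = make_leakage_fixture(truth1, lobe_radius=8, neck_width=2, z_slices=[10, 11])
        comp = extract_largest_component(leak.fat_mask)
        out = propagate_boundaries(comp, find_reference_slice(comp))
        before, after = comp.foreground, out.foreground
        lobe = leak.lobe_mask.data.astype(bool)
        breast_fat = truth1.breast_mask.data.astype(bool) & truth1.fat_mask.data.astype(bool)
        assert (lobe & after).sum() / lobe.sum() < 0.01
        assert (breast_fat & before & ~after).sum() / breast_fat.sum() < 0.02

    def test_end_to_end_refinement_repairs_leakage_damage(self, truth1):
        leak = make_leakage_fixture(truth1, lobe_radius=8, neck_width=2, z_slices=[10, 11])
        ref = truth1.breast_mask.data
        raw = extract_largest_component(leak.fat_mask)
        refined = build_breast_mask(leak.fat_mask)
        assert dice(refined.data, ref) >= dice(raw.foreground, ref)

    def test_lobe_on_reference_slice_survives(self, truth1):
        # documented limitation: the reference slice itself is assumed clean
        comp0 = extract_largest_component(truth1.fat_mask)
        z_ref = find_reference_slice(comp0)
        leak = make_leakage_fixture(truth1, lobe_radius=8, neck_width=2, z_slices=[z_ref])
        comp = extract_largest_component(leak.fat_mask)
        out = propagate_boundaries(comp, z_ref)
        lobe = leak.lobe_mask.data.astype(bool)
        assert (lobe & out.foreground).sum() / lobe.sum() > 0.9

    def test_no_voxels_added_beyond_ridges(self, truth1):
        leak = make_leakage_fixture(truth1, lobe_radius=8, neck_width=2, z_slices=[10, 11])
        comp = extract_largest_component(leak.fat_mask)
        out = propagate_boundaries(comp, find_reference_slice(comp))
        added = out.foreground & ~comp.foreground
        assert added.sum() == 0  # ridge voxels are inside the original mask


class TestFillAndExclude:
    def test_interior_cavity_filled(self):
        fg = np.zeros((3, 20, 20), dtype=bool)
        fg[1, 2:12, 2:12] = True
        fg[1, 6:8, 6:8] = False  # in-plane cavity
        out = fill_holes_and_exclude_lower(_comp(fg), RefinementParams(lower_exclusion_frac=0.99))
        assert out.foreground[1, 6, 6]

    def test_posterior_band_removed_with_exact_count(self):
        fg = np.zeros((3, 21, 10), dtype=bool)
        fg[:, 0:20, 2:8] = True  # y-extent 0..19
        p = RefinementParams(lower_exclusion_frac=0.85)
        out = fill_holes_and_exclude_lower(_comp(fg), p)
        # cut at y > 0 + 0.85*19 = 16.15 -> rows 17,18,19 removed on every slice
        removed = fg.sum() - out.foreground.sum()
        assert removed == 3 * 3 * 6
        assert not out.foreground[:, 17:, :].any()


class TestCloseConcavities:
    def test_convex_mask_unchanged(self):
        fg = np.zeros((8, 30, 30), dtype=bool)
        fg[1:7, 4:26, 4:26] = True
        out = close_concavities(_comp(fg), RefinementParams())
        np.testing.assert_array_equal(out.foreground, fg)

    def test_small_anterior_notch_filled_large_notch_kept(self):
        def notched(r_notch):
            fg = np.zeros((9, 40, 40), dtype=bool)
            fg[1:8, 5:35, 5:35] = True
            yy, xx = np.mgrid[:40, :40]
            notch = (yy - 5) ** 2 + (xx - 20) ** 2 <= r_notch**2  # on the anterior face
            fg[1:8, notch] = False
            return fg

        p = RefinementParams(nipple_ball_mm=8.0)
        small = notched(3)
        out_small = close_concavities(_comp(small), p)
        assert out_small.foreground[4, 6, 20]  # notch interior refilled
        large = notched(20)
        out_large = close_concavities(_comp(large), p)
        assert not out_large.foreground[4, 10, 20]  # too wide for the ball

    def test_output_superset_of_input(self, truth1):
        comp = extract_largest_component(truth1.fat_mask)
        out = close_concavities(comp, RefinementParams())
        assert not (comp.foreground & ~out.foreground).any()

    def test_subvoxel_radius_clamped_with_warning(self):
        fg = np.zeros((4, 10, 10), dtype=bool)
        fg[1:3, 2:8, 2:8] = True
        comp = BreastComponent.from_foreground(fg, (2.0, 1.0, 1.0))
        with pytest.warns(UserWarning, match="clamped"):
            close_concavities(comp, RefinementParams(side_ball_mm=0.5, nipple_ball_mm=0.5, pectoral_ball_mm=0.5))


class TestSternumCut:
    def test_cut_at_cleft_posterior_extreme(self, truth1):
        comp = extract_largest_component(truth1.breast_mask)
        out = cut_at_sternum(comp, RefinementParams())
        ys = np.nonzero(out.foreground.any(axis=(0, 2)))[0]
        assert ys.max() == truth1.chest_wall_y

    def test_all_anterior_foreground_unchanged(self):
        fg = np.zeros((3, 20, 20), dtype=bool)
        fg[:, 2:8, 5:15] = True  # midline window holds the deepest tissue row
        comp = _comp(fg)
        out = cut_at_sternum(comp, RefinementParams())
        np.testing.assert_array_equal(out.foreground, fg)

    def test_empty_midline_window_warns_and_returns_identity(self):
        fg = np.zeros((3, 20, 40), dtype=bool)
        fg[:, 2:8, 2:6] = True
        fg[:, 2:12, 34:38] = True  # centroid x ~ 20; window around it is empty
        comp = _comp(fg)
        with pytest.warns(UserWarning, match="midline"):
            out = cut_at_sternum(comp, RefinementParams())
        np.testing.assert_array_equal(out.foreground, fg)


class TestBuildBreastMask:
    def test_clean_phantom_recovers_truth(self, truth1, seg1):
        mask = build_breast_mask(seg1.seg3d)
        assert dice(mask.data, truth1.breast_mask.data) >= 0.95

    def test_empty_segmentation_rejected(self):
        with pytest.raises(ValueError):
            build_breast_mask(_mask(np.zeros((3, 8, 8))))

    def test_cut_and_exclusion_are_subsets_closing_superset(self, truth1):
        comp = extract_largest_component(truth1.fat_mask)
        filled = fill_holes_and_exclude_lower(comp, RefinementParams())
        cut = cut_at_sternum(filled, RefinementParams())
        assert not (cut.foreground & ~filled.foreground).any()
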