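import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctmotion import CTVolume, SegmentationParams, VoxelMask
from ctmotion.masks import (bone_length, compare_reports, morph, proximal_cut,
                            region_grow, segmentation_report, subtract_implant,
                            threshold_mask, tray_plane_from_implant)


def volume_from(values, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(values, dtype=float), spacing)


def mask_from(grid, spacing=(1.0, 1.0, 1.0), role="bone"):
    return VoxelMask(np.asarray(grid, dtype=bool), spacing, role=role)


# -- thresholding -----------------------------------------------------------

def test_threshold_window_selects_expected_levels():
    vol = volume_from(np.array([100.0, 600.0, 2500.0]).reshape(3, 1, 1))
    bone = threshold_mask(vol, 430.0, 1900.0)
    assert bone.grid.ravel().tolist() == [False, True, False]
    implant = threshold_mask(vol, 2200.0, role="implant")
    assert implant.grid.ravel().tolist() == [False, False, True]
    empty = threshold_mask(vol, 5000.0)
    assert empty.voxel_count == 0


def test_threshold_rejects_inverted_bounds():
    vol = volume_from(np.zeros((2, 2, 2)))
    with pytest.raises(ValueError):
        threshold_mask(vol, 500.0, 400.0)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.floats(-100, 1000), st.floats(0, 500))
def test_threshold_monotone_in_lower_bound(seed, lo, delta):
    gen = np.random.default_rng(seed)
    vol = volume_from(gen.uniform(-200, 2000, (6, 6, 6)))
    wide = threshold_mask(vol, lo)
    narrow = threshold_mask(vol, lo + delta)
    assert not np.any(narrow.grid & ~wide.grid)


# -- region growing ---------------------------------------------------------

def two_blob_mask():
    grid = np.zeros((12, 6, 6), dtype=bool)
    grid[1:4, 1:4, 1:4] = True      # blob A
    grid[8:11, 1:4, 1:4] = True     # blob B, disconnected
    return mask_from(grid)


def test_region_grow_keeps_only_seeded_component():
    mask = two_blob_mask()
    out = region_grow(mask, [[2.0, 2.0, 2.0]])
    assert out.voxel_count == 27
    assert out.grid[2, 2, 2] and not out.grid[9, 2, 2]


def test_region_grow_all_components_seeded_is_identity():
    mask = two_blob_mask()
    out = region_grow(mask, [[2.0, 2.0, 2.0], [9.0, 2.0, 2.0]])
    assert np.array_equal(out.grid, mask.grid)


def test_region_grow_background_seed_warns_and_yields_empty():
    mask = two_blob_mask()
    with pytest.warns(UserWarning):
        out = region_grow(mask, [[5.0, 5.0, 5.0]])
    assert out.voxel_count == 0


def test_region_grow_seed_outside_grid_raises():
    with pytest.raises(ValueError):
        region_grow(two_blob_mask(), [[50.0, 0.0, 0.0]])


def test_region_grow_uses_26_connectivity():
    grid = np.zeros((4, 4, 4), dtype=bool)
    grid[0, 0, 0] = True
    grid[1, 1, 1] = True            # diagonal neighbour
    out = region_grow(mask_from(grid), [[0.0, 0.0, 0.0]])
    assert out.voxel_count == 2


# -- morphology -------------------------------------------------------------

def test_morph_radius_zero_is_identity():
    mask = two_blob_mask()
    assert np.array_equal(morph(mask, "erode", 0).grid, mask.grid)


def test_erode_cube_leaves_core():
    grid = np.zeros((9, 9, 9), dtype=bool)
    grid[2:7, 2:7, 2:7] = True
    out = morph(mask_from(grid), "erode", 1)
    expect = np.zeros_like(grid)
    expect[3:6, 3:6, 3:6] = True
    assert np.array_equal(out.grid, expect)


def test_closing_covers_convex_mask(rng):
    grid = np.zeros((14, 14, 14), dtype=bool)
    grid[4:10, 4:10, 4:10] = True
    mask = mask_from(grid)
    closed = morph(morph(mask, "dilate", 2), "erode", 2)
    assert np.all(closed.grid[mask.grid])


def test_morph_unknown_op_rejected():
    with pytest.raises(ValueError):
        morph(two_blob_mask(), "open", 1)


# -- proximal cut and subtraction -------------------------------------------

def bone_cylinder(length_vox=100, spacing=(1.0, 1.0, 1.0)):
    grid = np.zeros((9, length_vox + 4, 9), dtype=bool)
    grid[2:7, 2:length_vox + 2, 2:7] = True
    return mask_from(grid, spacing)


def test_cut_zero_removes_only_at_or_above_plane():
    bone = bone_cylinder(20)
    plane = ([0.0, 12.0, 0.0], [0.0, 1.0, 0.0])
    out = proximal_cut(bone, plane, 0.0)
    kept_y = np.where(out.grid.any(axis=(0, 2)))[0]
    assert kept_y.max() == 11


def test_cut_depth_removes_expected_layers():
    bone = bone_cylinder(100)           # voxels y = 2..101, extent 100 mm
    plane = ([0.0, 102.0, 0.0], [0.0, 1.0, 0.0])
    out = proximal_cut(bone, plane, 5.0)
    assert bone_length(out) == pytest.approx(95.0)


def test_cut_below_all_bone_raises():
    bone = bone_cylinder(20)
    with pytest.raises(ValueError):
        proximal_cut(bone, ([0.0, 0.0, 0.0], [0.0, 1.0, 0.0]), 5.0)


def test_subtract_disjoint_masks_is_identity():
    bone = bone_cylinder(10)
    implant = mask_from(np.zeros(bone.shape, dtype=bool), role="implant")
    out = subtract_implant(bone, implant)
    assert np.array_equal(out.grid, bone.grid)


def test_subtract_superset_empties_bone():
    bone = bone_cylinder(10)
    implant = VoxelMask(np.ones(bone.shape, dtype=bool), bone.spacing, role="implant")
    assert subtract_implant(bone, implant).voxel_count == 0


def test_subtract_removes_exact_overlap_count():
    bone = bone_cylinder(10)
    overlap = np.zeros(bone.shape, dtype=bool)
    overlap[3:5, 3:8, 3:5] = True
    implant = VoxelMask(overlap, bone.spacing, role="implant")
    out = subtract_implant(bone, implant)
    k = int((bone.grid & overlap).sum())
    assert out.voxel_count == bone.voxel_count - k
    assert not np.any(out.grid & implant.grid)


def test_subtract_geometry_mismatch_raises():
    bone = bone_cylinder(10)
    other = VoxelMask(np.zeros(bone.shape, dtype=bool), (2.0, 1.0, 1.0), role="implant")
    with pytest.raises(ValueError):
        subtract_implant(bone, other)


# -- bone length ------------------------------------------------------------

def test_bone_length_seventy_mm_no_warning(recwarn):
    bone = bone_cylinder(70)
    assert bone_length(bone) == pytest.approx(70.0)
    assert not any(isinstance(w.message, UserWarning) for w in recwarn.list)


def test_bone_length_short_bone_warns():
    bone = bone_cylinder(50)
    with pytest.warns(UserWarning, match="7 cm"):
        assert bone_length(bone) == pytest.approx(50.0)


def test_bone_length_single_voxel_is_voxel_extent():
    grid = np.zeros((3, 3, 3), dtype=bool)
    grid[1, 1, 1] = True
    with pytest.warns(UserWarning):
        assert bone_length(mask_from(grid, (0.5, 0.4, 0.5))) == pytest.approx(0.4)


def test_bone_length_empty_mask_raises():
    with pytest.raises(ValueError):
        bone_length(mask_from(np.zeros((3, 3, 3), dtype=bool)))


# -- tray plane -------------------------------------------------------------

def test_tray_plane_sits_at_distal_tray_face():
    grid = np.zeros((21, 40, 21), dtype=bool)
    grid[8:13, 5:25, 8:13] = True       # stem
    grid[2:19, 25:29, 2:19] = True      # tray slab
    mask = mask_from(grid, (0.5, 0.5, 0.5), role="implant")
    point, normal = tray_plane_from_implant(mask)
    assert np.allclose(normal, [0, 1, 0])
    assert point[1] == pytest.approx(25 * 0.5, abs=0.5)


# -- report -----------------------------------------------------------------

def test_report_volumes_match_voxel_count():
    bone = bone_cylinder(10, spacing=(0.5, 0.4, 0.5))
    implant = mask_from(np.zeros(bone.shape, dtype=bool), (0.5, 0.4, 0.5), "implant")
    params = SegmentationParams()
    rep = segmentation_report(params, bone, implant)
    vol = rep.loc[rep.quantity == "Volume_Bone (cm3)", "value"].iloc[0]
    assert vol == pytest.approx(bone.voxel_count * 0.5 * 0.4 * 0.5 / 1000.0, abs=1e-12)


def test_identical_observers_have_zero_absolute_difference():
    bone = bone_cylinder(10)
    implant = mask_from(np.zeros(bone.shape, dtype=bool), role="implant")
    params = SegmentationParams()
    a = segmentation_report(params, bone, implant, observer="OBS1")
    b = segmentation_report(params, bone, implant, observer="OBS2")
    merged = compare_reports(a, b)
    assert np.allclose(merged["abs_dif"].fillna(0.0), 0.0)
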