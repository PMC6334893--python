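"""Volume I/O, threshold/binarize, resampling, grid matching, masking, QC."""

import warnings

import nibabel as nib
import numpy as np
import pytest

from gradmap import (
    VolumeGrid,
    apply_mask,
    load_volume,
    make_cluster,
    make_reference_space,
    match_grid,
    preprocess,
    resample_to_reference,
    threshold_binarize,
)


def save_nifti(path, data, affine, dtype=np.float32):
    nib.save(nib.Nifti1Image(np.asarray(data).astype(dtype), affine), str(path))


def centered_affine(shape, step=2.0):
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = step
    aff[:3, 3] = -step * (np.array(shape) - 1) / 2.0
    return aff


class TestLoadVolume:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(8, 9, 10)).astype(np.float64)
        aff = centered_affine((8, 9, 10))
        p = tmp_path / "vol.nii.gz"
        save_nifti(p, data, aff, dtype=np.float64)
        vol = load_volume(p)
        np.testing.assert_allclose(vol.values, data)
        np.testing.assert_allclose(vol.affine, aff)

    def test_trailing_singleton_dim_squeezed(self, tmp_path):
        p = tmp_path / "vol4d1.nii.gz"
        save_nifti(p, np.ones((5, 5, 5, 1)), centered_affine((5, 5, 5)))
        assert load_volume(p).shape == (5, 5, 5)

    def test_timeseries_rejected_naming_dimensionality(self, tmp_path):
        p = tmp_path / "ts.nii.gz"
        save_nifti(p, np.ones((4, 4, 4, 5)), centered_affine((4, 4, 4)))
        with pytest.raises(ValueError, match="4-D with 5"):
            load_volume(p)

    def test_full_size_one_mm_grid_loads(self, tmp_path):
        # full 1 mm MNI-like grid with a small cluster
        data = np.zeros((182, 218, 182), dtype=np.uint8)
        data[90:95, 50:55, 40:45] = 1
        aff = np.diag([-1.0, 1.0, 1.0, 1.0])
        aff[:3, 3] = [90.0, -126.0, -72.0]
        p = tmp_path / "big.nii.gz"
        save_nifti(p, data, aff, dtype=np.uint8)
        vol = load_volume(p)
        assert vol.shape == (182, 218, 182)
        assert int(vol.values.sum()) == 125

    def test_implausible_affine_warns(self, tmp_path):
        aff = centered_affine((5, 5, 5))
        aff[:3, 3] += 500.0  # far from the anterior commissure
        p = tmp_path / "far.nii.gz"
        save_nifti(p, np.ones((5, 5, 5)), aff)
        with pytest.warns(UserWarning, match="MNI152"):
            load_volume(p)

    def test_plausible_affine_does_not_warn(self, tmp_path):
        p = tmp_path / "ok.nii.gz"
        save_nifti(p, np.ones((5, 5, 5)), centered_affine((5, 5, 5)))
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            load_volume(p)


class TestThresholdBinarize:
    def test_strictly_greater_than_threshold(self):
        vol = VolumeGrid(
            np.array([5.0, 6.0, 7.0]).reshape(3, 1, 1), np.eye(4)
        )
        out = threshold_binarize(vol, threshold=6.0, binarize=True)
        np.testing.assert_array_equal(out.values.ravel(), [0.0, 0.0, 1.0])

    def test_no_threshold_keeps_binary_mask_unchanged(self):
        rng = np.random.default_rng(1)
        data = (rng.uniform(size=(6, 6, 6)) > 0.5).astype(float)
        vol = VolumeGrid(data, np.eye(4))
        out = threshold_binarize(vol, threshold=None, binarize=True)
        np.testing.assert_array_equal(out.values, data)

    def test_surviving_count_matches_brute_force(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(size=(10, 10, 10))
        thr = float(np.median(data))
        vol = VolumeGrid(data, np.eye(4))
        out = threshold_binarize(vol, threshold=thr, binarize=True)
        assert int(out.values.sum()) == int((data > thr).sum())

    def test_no_binarize_keeps_values(self):
        data = np.array([2.0, 5.0, 9.0]).reshape(1, 1, 3)
        out = threshold_binarize(VolumeGrid(data, np.eye(4)), 4.0, binarize=False)
        np.testing.assert_array_equal(out.values.ravel(), [0.0, 5.0, 9.0])


@pytest.fixture(scope="module")
def small_ref():
    return make_reference_space(shape=(10, 12, 10))


class TestResample:
    def test_identity_resample_bit_identical(self, small_ref):
        rng = np.random.default_rng(3)
        data = (rng.uniform(size=small_ref.shape) > 0.7).astype(float)
        vol = VolumeGrid(data, small_ref.affine.copy())
        out = resample_to_reference(vol, small_ref, is_binary=True)
        assert np.array_equal(out.values, data)

    def _fine_grid(self, small_ref):
        """1 mm grid exactly tiling the 2 mm reference voxels."""
        f = 2
        shape = tuple(f * s for s in small_ref.shape)
        aff = small_ref.affine.copy()
        aff[:3, :3] /= f
        aff[:3, 3] -= 0.5
        return shape, aff

    def test_partial_volume_eighth_does_not_survive(self, small_ref):
        shape, aff = self._fine_grid(small_ref)
        data = np.zeros(shape)
        data[8, 8, 8] = 1.0  # one 1 mm voxel = 1/8 of its 2 mm parent
        out = resample_to_reference(VolumeGrid(data, aff), small_ref, is_binary=True)
        assert out.values.sum() == 0

    def test_full_occupancy_survives(self, small_ref):
        shape, aff = self._fine_grid(small_ref)
        data = np.zeros(shape)
        data[8:10, 8:10, 8:10] = 1.0  # a full 2 mm voxel worth of 1 mm voxels
        out = resample_to_reference(VolumeGrid(data, aff), small_ref, is_binary=True)
        assert out.values.sum() == 1
        assert out.values[4, 4, 4] == 1.0

    def test_continuous_identity_at_centers(self, small_ref):
        shape, aff = self._fine_grid(small_ref)
        rng = np.random.default_rng(4)
        coarse = rng.uniform(1.0, 2.0, size=small_ref.shape)
        fine = np.repeat(np.repeat(np.repeat(coarse, 2, 0), 2, 1), 2, 2)
        out = resample_to_reference(VolumeGrid(fine, aff), small_ref, is_binary=False)
        np.testing.assert_allclose(out.values, coarse, atol=1e-12)

    def test_no_overlap_warns_and_empties(self, small_ref):
        aff = small_ref.affine.copy()
        aff[:3, 3] += 1000.0
        vol = VolumeGrid(np.ones((4, 4, 4)), aff)
        with pytest.warns(UserWarning, match="no overlap"):
            out = resample_to_reference(vol, small_ref, is_binary=True)
        assert not out.values.any()


class TestMatchGrid:
    def test_matching_shape_is_identity(self, small_ref):
        rng = np.random.default_rng(5)
        data = rng.uniform(size=small_ref.shape)
        out = match_grid(VolumeGrid(data, small_ref.affine.copy()), small_ref)
        np.testing.assert_array_equal(out.values, data)

    def test_extra_leading_zero_slice_cropped(self, small_ref):
        rng = np.random.default_rng(6)
        data = rng.uniform(size=small_ref.shape)
        padded = np.concatenate([np.zeros((1,) + small_ref.shape[1:]), data], axis=0)
        aff = small_ref.affine.copy()
        aff[:3, 3] -= aff[:3, :3] @ np.array([1.0, 0.0, 0.0])
        out = match_grid(VolumeGrid(padded, aff), small_ref)
        np.testing.assert_array_equal(out.values, data)

    def test_offset_grid_preserves_world_coordinates(self, small_ref):
        rng = np.random.default_rng(7)
        data = np.zeros(small_ref.shape)
        interior = rng.integers(3, 7, size=(20, 3))
        data[tuple(interior.T)] = 1.0
        aff = small_ref.affine.copy()
        aff[:3, 3] += aff[:3, :3] @ np.array([2.0, 0.0, 0.0])  # +2 slices
        vol = VolumeGrid(data, aff)
        before = {tuple(np.round(w, 6)) for w in vol.world_coords(vol.nonzero_voxels())}
        out = match_grid(vol, small_ref)
        after = {tuple(np.round(w, 6)) for w in out.world_coords(out.nonzero_voxels())}
        assert before == after

    def test_orientation_mismatch_rejected(self, small_ref):
        aff = small_ref.affine.copy()
        aff[0, 0] *= -1
        with pytest.raises(ValueError, match="orientation"):
            match_grid(VolumeGrid(np.zeros(small_ref.shape), aff), small_ref)


class TestApplyMask:
    def test_outside_cluster_zeroed_with_warning(self, ref):
        data = np.zeros(ref.shape)
        data[0, 0, 0] = 1.0  # grid corner is outside the ellipsoid mask
        assert ref.mask.values[0, 0, 0] == 0
        with pytest.warns(UserWarning, match="gray-matter"):
            out = apply_mask(VolumeGrid(data, ref.affine.copy()), ref)
        assert not out.values.any()

    def test_inside_cluster_unchanged(self, ref, cluster17):
        out = apply_mask(cluster17.volume, ref)
        np.testing.assert_array_equal(out.values, cluster17.volume.values)

    def test_straddling_cluster_matches_set_intersection(self, ref):
        cl = make_cluster(ref, n_voxels=20, spill_outside=True, seed=9)
        out = apply_mask(cl.volume, ref)
        got = set(map(tuple, out.nonzero_voxels()))
        mask_set = set(map(tuple, np.argwhere(ref.mask.values > 0)))
        cluster_set = set(map(tuple, cl.volume.nonzero_voxels()))
        assert got == (mask_set & cluster_set)


class TestPreprocess:
    def test_masked_binary_reference_volume_is_fixed_point(self, ref, cluster17):
        out, report = preprocess(cluster17.volume, ref)
        np.testing.assert_array_equal(out.values, cluster17.volume.values)
        assert report.moved_voxels == []
        assert report.in_mask_preserved

    def test_boundary_straddling_cluster_keeps_in_mask_set(self, ref):
        cl = make_cluster(
            ref, n_voxels=25, resolution_mm=1.0, spill_outside=True, seed=10
        )
        out, report = preprocess(cl.volume, ref)
        assert report.moved_voxels == []
        got = set(map(tuple, out.nonzero_voxels()))
        assert got == set(map(tuple, cl.in_mask_voxels))
        assert report.n_voxels_after == report.n_voxels_before_in_mask

    def test_preprocess_twice_is_noop(self, ref):
        cl = make_cluster(
            ref, n_voxels=30, resolution_mm=1.0, spill_outside=True, seed=12
        )
        out1, _ = preprocess(cl.volume, ref)
        out2, report2 = preprocess(out1, ref, threshold=None)
        np.testing.assert_array_equal(out2.values, out1.values)
        assert report2.moved_voxels == []

    def test_gray_matter_invariance_against_independent_pipeline(self, ref):
        """QC contract: in-mask output set == in-mask set of the thresholded,
        reference-resampled input, computed here by composing stages by hand."""
        cl = make_cluster(
            ref, n_voxels=20, resolution_mm=1.0, spill_outside=True,
            values="graded", seed=13,
        )
        thr = 4.0
        out, report = preprocess(cl.volume, ref, threshold=thr, binarize=True)
        manual = resample_to_reference(
            threshold_binarize(cl.volume, thr, binarize=True), ref, is_binary=True
        )
        mask_set = set(map(tuple, np.argwhere(ref.mask.values > 0)))
        manual_in_mask = set(map(tuple, manual.nonzero_voxels())) & mask_set
        assert set(map(tuple, out.nonzero_voxels())) == manual_in_mask
        assert report.moved_voxels == []

    def test_every_output_voxel_inside_mask(self, ref):
        for seed in range(5):
            cl = make_cluster(ref, n_voxels=15, spill_outside=True, seed=seed)
            out, _ = preprocess(cl.volume, ref)
            outside = (out.values != 0) & (ref.mask.values == 0)
            assert not outside.any()

    def test_from_file(self, ref, tmp_path, cluster17):
        p = tmp_path / "cl.nii.gz"
        cluster17.volume.save(p)
        out, report = preprocess(p, ref)
        assert report.n_voxels_after == 17
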