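"""Volume I/O, mask extraction, downsampling, pyramid and feature matrices."""

import numpy as np
import pytest

from hsrc import (
    BinaryVolume,
    Grid,
    LabelVolume,
    assemble_feature_matrix,
    build_pyramid,
    downsample_binary,
    extract_cortical_mask,
    load_label_volume,
    voxel_to_mni,
    write_volume,
)
from hsrc.volumes import FLATTEN_ORDER


def make_grid(shape, affine=None):
    return Grid(shape=shape, affine=np.eye(4) if affine is None else affine)


class TestNiftiIO:
    def test_zero_volume_loads_as_zero_labels(self, tmp_path):
        grid = make_grid((2, 2, 2))
        vol = LabelVolume(grid=grid, labels=np.zeros((2, 2, 2), dtype=np.int64))
        path = tmp_path / "zeros.nii.gz"
        write_volume(vol, path)
        loaded = load_label_volume(path)
        assert (loaded.labels == 0).all()
        assert loaded.grid == grid

    def test_roundtrip_preserves_labels_and_affine(self, tmp_path, rng):
        affine = np.eye(4)
        affine[:3, :3] = np.diag([0.7, 0.7, 0.7])
        affine[:3, 3] = [-10.0, 3.0, 5.0]
        labels = rng.choice([0, 251, 1000, 2035], size=(5, 4, 3)).astype(np.int64)
        vol = LabelVolume(grid=make_grid((5, 4, 3), affine), labels=labels)
        path = tmp_path / "parc.nii.gz"
        write_volume(vol, path)
        loaded = load_label_volume(path)
        np.testing.assert_array_equal(loaded.labels, labels)
        np.testing.assert_allclose(loaded.grid.affine, affine, atol=1e-6)

    def test_wmparc_like_values_preserved_exactly(self, tmp_path):
        labels = np.zeros((3, 3, 3), dtype=np.int64)
        labels[0, 0, 0], labels[1, 1, 1] = 251, 2035
        vol = LabelVolume(grid=make_grid((3, 3, 3)), labels=labels)
        path = tmp_path / "v.nii.gz"
        write_volume(vol, path)
        np.testing.assert_array_equal(load_label_volume(path).labels, labels)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises((OSError, FileNotFoundError)):
            load_label_volume(tmp_path / "nope.nii.gz")

    def test_non_integral_values_rejected(self, tmp_path):
        import nibabel as nib

        data = np.full((2, 2, 2), 0.5, dtype=np.float32)
        nib.save(nib.Nifti1Image(data, np.eye(4)), tmp_path / "bad.nii.gz")
        with pytest.raises(ValueError, match="not integral"):
            load_label_volume(tmp_path / "bad.nii.gz")


class TestCorticalMask:
    def test_label_range_inclusive_both_ends(self):
        labels = np.array([0, 251, 1000, 2035, 2036]).reshape(5, 1, 1)
        parc = LabelVolume(grid=make_grid((5, 1, 1)), labels=labels)
        mask = extract_cortical_mask(parc, 251, 2035)
        np.testing.assert_array_equal(mask.mask.ravel(), [0, 1, 1, 1, 0])

    def test_all_zero_labels_give_empty_mask(self):
        parc = LabelVolume(grid=make_grid((3, 3, 3)), labels=np.zeros((3, 3, 3), dtype=int))
        assert extract_cortical_mask(parc, 251, 2035).mask.sum() == 0

    def test_matches_naive_triple_loop(self, rng):
        labels = rng.integers(0, 12, size=(4, 5, 3))
        parc = LabelVolume(grid=make_grid((4, 5, 3)), labels=labels)
        mask = extract_cortical_mask(parc, 3, 7)
        for i in range(4):
            for j in range(5):
                for k in range(3):
                    assert mask.mask[i, j, k] == (1 if 3 <= labels[i, j, k] <= 7 else 0)

    def test_inverted_bounds_rejected(self):
        parc = LabelVolume(grid=make_grid((2, 2, 2)), labels=np.zeros((2, 2, 2), dtype=int))
        with pytest.raises(ValueError):
            extract_cortical_mask(parc, 10, 5)


class TestDownsample:
    def test_constant_volume_stays_constant(self):
        vol = BinaryVolume(grid=make_grid((4, 4, 4)), mask=np.ones((4, 4, 4), dtype=np.uint8))
        out = downsample_binary(vol, 2)
        assert out.grid.shape == (2, 2, 2)
        assert (out.mask == 1).all()

    def test_exact_half_block_ties_to_one(self):
        mask = np.zeros((2, 2, 2), dtype=np.uint8)
        mask[0, 0, 0] = mask[0, 0, 1] = mask[0, 1, 0] = mask[0, 1, 1] = 1
        vol = BinaryVolume(grid=make_grid((2, 2, 2)), mask=mask)
        assert downsample_binary(vol, 2).mask[0, 0, 0] == 1

    def test_matches_explicit_block_majority(self, rng):
        mask = (rng.random((8, 8, 8)) < 0.5).astype(np.uint8)
        vol = BinaryVolume(grid=make_grid((8, 8, 8)), mask=mask)
        out = downsample_binary(vol, 2)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    block = mask[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2]
                    assert out.mask[i, j, k] == (1 if 2 * block.sum() >= 8 else 0)

    def test_odd_shape_uses_actual_block_size(self):
        # edge block truncated to 1x2x2 = 4 voxels; 2 ones of 4 is a tie -> 1
        mask = np.zeros((3, 2, 2), dtype=np.uint8)
        mask[2, 0, 0] = mask[2, 1, 0] = 1
        vol = BinaryVolume(grid=make_grid((3, 2, 2)), mask=mask)
        out = downsample_binary(vol, 2)
        assert out.grid.shape == (2, 1, 1)
        assert out.mask[1, 0, 0] == 1
        # a single 1 of 4 falls below the majority
        mask2 = np.zeros((3, 2, 2), dtype=np.uint8)
        mask2[2, 0, 0] = 1
        out2 = downsample_binary(BinaryVolume(grid=make_grid((3, 2, 2)), mask=mask2), 2)
        assert out2.mask[1, 0, 0] == 0

    def test_block_centers_preserved_in_world_coordinates(self):
        affine = np.diag([0.7, 0.7, 0.7, 1.0])
        vol = BinaryVolume(
            grid=make_grid((4, 4, 4), affine), mask=np.ones((4, 4, 4), dtype=np.uint8)
        )
        out = downsample_binary(vol, 2)
        # coarse voxel (0,0,0) covers fine voxels 0..1 -> center at fine index 0.5
        np.testing.assert_allclose(voxel_to_mni(out.grid, 0), np.full(3, 0.35))
        np.testing.assert_allclose(out.grid.voxel_size, [1.4, 1.4, 1.4])

    def test_any_and_all_rules(self):
        mask = np.zeros((2, 2, 2), dtype=np.uint8)
        mask[0, 0, 0] = 1
        vol = BinaryVolume(grid=make_grid((2, 2, 2)), mask=mask)
        assert downsample_binary(vol, 2, rule="any").mask[0, 0, 0] == 1
        assert downsample_binary(vol, 2, rule="all").mask[0, 0, 0] == 0

    def test_blockwise_constant_volume_equals_subsampling(self, rng):
        coarse = (rng.random((3, 3, 3)) < 0.5).astype(np.uint8)
        fine = np.repeat(np.repeat(np.repeat(coarse, 2, 0), 2, 1), 2, 2)
        vol = BinaryVolume(grid=make_grid((6, 6, 6)), mask=fine)
        np.testing.assert_array_equal(downsample_binary(vol, 2).mask, coarse)


class TestPyramid:
    def test_power_of_two_shapes(self):
        pyr = build_pyramid(make_grid((4, 4, 4)), 3)
        assert [g.shape for g in pyr.levels] == [(4, 4, 4), (2, 2, 2), (1, 1, 1)]

    def test_parent_child_inverse_exhaustive(self, identity_grid):
        pyr = build_pyramid(identity_grid, 2)
        coarse = pyr.levels[1]
        for p in range(coarse.n_voxels):
            children = pyr.children_of(0, p)
            assert 1 <= children.size <= 8
            parents = {int(pyr.parent_of(0, int(c))) for c in children}
            assert parents == {p}

    def test_children_partition_fine_grid(self, identity_grid):
        pyr = build_pyramid(identity_grid, 2)
        all_children = np.concatenate(
            [pyr.children_of(0, p) for p in range(pyr.levels[1].n_voxels)]
        )
        assert np.array_equal(np.sort(all_children), np.arange(identity_grid.n_voxels))

    def test_interior_voxel_has_eight_children(self):
        pyr = build_pyramid(make_grid((8, 8, 8)), 2)
        interior = np.ravel_multi_index((1, 1, 1), (4, 4, 4), order=FLATTEN_ORDER)
        assert pyr.children_of(0, int(interior)).size == 8

    def test_pyramid_grids_match_downsampled_grids(self):
        affine = np.diag([0.7, 0.7, 0.7, 1.0])
        vol = BinaryVolume(
            grid=make_grid((10, 9, 8), affine), mask=np.zeros((10, 9, 8), dtype=np.uint8)
        )
        pyr = build_pyramid(vol.grid, 3)
        down = downsample_binary(vol, 2)
        assert pyr.levels[1] == down.grid
        assert pyr.levels[2] == downsample_binary(down, 2).grid


class TestFeatureMatrix:
    def grid_vols(self, masks):
        grid = make_grid(masks[0].shape)
        return [BinaryVolume(grid=grid, mask=m.astype(np.uint8)) for m in masks]

    def test_identical_masks_give_zero_features(self, rng):
        m = (rng.random((3, 3, 3)) < 0.5).astype(np.uint8)
        F = assemble_feature_matrix(self.grid_vols([m, m]), ["a", "b"])
        assert F.n_features == 0

    def test_hand_checkable_constant_removal(self):
        m1 = np.array([1, 1, 0]).reshape(3, 1, 1)
        m2 = np.array([1, 0, 0]).reshape(3, 1, 1)
        F = assemble_feature_matrix(self.grid_vols([m1, m2]), ["a", "b"])
        assert F.n_features == 1
        assert F.voxel_index.tolist() == [1]
        np.testing.assert_array_equal(F.X, [[1], [0]])

    def test_surviving_columns_match_naive_scan(self, rng):
        masks = (rng.random((20, 5, 5, 5)) < 0.5).astype(np.uint8)
        F = assemble_feature_matrix(
            self.grid_vols(list(masks)), [f"s{i}" for i in range(20)]
        )
        # naive per-column scan in the package's documented flattening order
        flat = np.stack([m.ravel(order=FLATTEN_ORDER) for m in masks])
        keep = [
            j
            for j in range(flat.shape[1])
            if 0 < flat[:, j].sum() < flat.shape[0]
        ]
        assert F.voxel_index.tolist() == keep
        np.testing.assert_array_equal(F.X, flat[:, keep])

    def test_never_contains_constant_column(self, small_features):
        sums = small_features.X.sum(axis=0)
        assert (sums > 0).all() and (sums < small_features.n_subjects).all()

    def test_grid_mismatch_rejected(self):
        v1 = BinaryVolume(grid=make_grid((2, 2, 2)), mask=np.zeros((2, 2, 2), dtype=np.uint8))
        v2 = BinaryVolume(grid=make_grid((3, 3, 3)), mask=np.zeros((3, 3, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            assemble_feature_matrix([v1, v2], ["a", "b"])

    def test_restrict_returns_sorted_intersection(self, small_features):
        want = small_features.voxel_index[[5, 1, 3]]
        sub = small_features.restrict(np.append(want, small_features.grid.n_voxels - 1))
        assert sub.voxel_index.tolist() == sorted(
            set(want) & set(small_features.voxel_index)
        )


class TestVoxelToMni:
    def test_identity_affine_origin(self):
        assert voxel_to_mni(make_grid((3, 3, 3)), 0).tolist() == [0, 0, 0]

    def test_scaled_offset_affine(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-10, -10, -10]
        grid = make_grid((6, 1, 1), affine)
        idx = np.ravel_multi_index((5, 0, 0), grid.shape, order=FLATTEN_ORDER)
        np.testing.assert_allclose(voxel_to_mni(grid, int(idx)), [0, -10, -10])

    def test_matches_matrix_vector_product(self, rng):
        affine = np.eye(4)
        affine[:3, :] = rng.normal(size=(3, 4))
        affine[:3, :3] += np.eye(3) * 2
        grid = make_grid((4, 5, 6), affine)
        idx = int(rng.integers(grid.n_voxels))
        ijk = np.unravel_index(idx, grid.shape, order=FLATTEN_ORDER)
        expected = affine @ np.array([*ijk, 1.0])
        np.testing.assert_allclose(voxel_to_mni(grid, idx), expected[:3])

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            voxel_to_mni(make_grid((2, 2, 2)), 8)
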