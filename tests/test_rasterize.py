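"""Patch grid arithmetic, pseudobulk conservation, crops, log transform, filtering."""

import math

import numpy as np
import pytest

from stablate.rasterize import (
    PatchExpression,
    build_patch_grid,
    extract_patches,
    filter_zero_patches,
    log1p_transform,
    pseudobulk,
    spots_to_patches,
)
from stablate.synthetic import SequencingReadout

GENES = ["g0", "g1", "g2"]


class TestBuildPatchGrid:
    @pytest.mark.parametrize(
        "w,h,p,rows,cols",
        [(1000, 1000, 250, 4, 4), (999, 999, 250, 3, 3), (200, 200, 250, 0, 0)],
    )
    def test_full_patch_counts(self, w, h, p, rows, cols):
        grid = build_patch_grid(w, h, p)
        assert (grid.n_rows, grid.n_cols) == (rows, cols)
        assert grid.n_patches == rows * cols

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            build_patch_grid(100, 100, 0)
        with pytest.raises(ValueError):
            build_patch_grid(0, 100, 10)


class TestPseudobulk:
    def test_single_point_lands_in_its_patch(self):
        grid = build_patch_grid(64, 64, 16)
        expr = pseudobulk(np.array([[7, 0, 0]]), np.array([[24.0, 40.0]]), grid, GENES)
        assert expr.counts[2 * 4 + 1, 0] == 7  # row 2 (y=40), col 1 (x=24)
        assert expr.counts.sum() == 7

    def test_total_counts_conserved_exactly(self):
        rng = np.random.default_rng(0)
        grid = build_patch_grid(100, 80, 20)
        pts = rng.uniform(0, [100, 80], size=(500, 2))
        counts = rng.poisson(3, size=(500, 3))
        expr = pseudobulk(counts, pts, grid, GENES)
        np.testing.assert_array_equal(expr.counts.sum(axis=0), counts.sum(axis=0))

    def test_out_of_region_points_dropped(self):
        grid = build_patch_grid(32, 32, 16)
        expr = pseudobulk(np.array([[5, 5, 5]]), np.array([[40.0, 1.0]]), grid, GENES)
        assert expr.counts.sum() == 0

    def test_boundary_point_assigned_to_right_hand_patch(self):
        grid = build_patch_grid(32, 32, 16)
        expr = pseudobulk(np.array([[1, 0, 0]]), np.array([[16.0, 0.0]]), grid, GENES)
        assert expr.counts[1, 0] == 1  # column index 1, not 0


class TestSpotsToPatches:
    def _readout(self, counts, centers, pitch=16.0):
        return SequencingReadout(
            spot_counts=np.asarray(counts),
            spot_centers=np.asarray(centers, float),
            spot_pitch=pitch,
            capture_efficiency=0.2,
            diffusion_mix=0.0,
            dropout_prob=0.0,
        )

    def test_matched_pitch_reproduces_spot_matrix(self):
        grid = build_patch_grid(32, 32, 16)
        counts = np.arange(12).reshape(4, 3)
        centers = [[8.0, 8.0], [24.0, 8.0], [8.0, 24.0], [24.0, 24.0]]
        expr = spots_to_patches(self._readout(counts, centers), grid, GENES)
        np.testing.assert_array_equal(expr.counts, counts)

    def test_outside_spot_dropped(self):
        grid = build_patch_grid(16, 16, 16)
        expr = spots_to_patches(
            self._readout([[1, 1, 1], [9, 9, 9]], [[8.0, 8.0], [40.0, 8.0]]), grid, GENES
        )
        np.testing.assert_array_equal(expr.counts, [[1, 1, 1]])

    def test_two_spots_in_one_patch_is_an_error(self):
        grid = build_patch_grid(16, 16, 16)
        with pytest.raises(ValueError):
            spots_to_patches(
                self._readout([[1, 0, 0], [2, 0, 0]], [[4.0, 4.0], [12.0, 12.0]]),
                grid,
                GENES,
            )

    def test_empty_readout_gives_zero_counts(self):
        grid = build_patch_grid(32, 32, 16)
        expr = spots_to_patches(self._readout(np.empty((0, 3), int), np.empty((0, 2))), grid, GENES)
        assert expr.counts.sum() == 0 and expr.n_patches == 4


class TestExtractPatches:
    def test_constant_image_gives_constant_patches(self):
        img = np.full((64, 64, 3), 17, np.uint8)
        tiles = extract_patches(img, build_patch_grid(64, 64, 16))
        assert tiles.shape == (16, 16, 16, 3)
        assert (tiles == 17).all()

    def test_tiles_partition_and_reassemble_the_region(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, size=(48, 32, 3), dtype=np.uint8)
        grid = build_patch_grid(32, 48, 16)
        tiles = extract_patches(img, grid)
        rebuilt = np.concatenate(
            [
                np.concatenate([tiles[r * grid.n_cols + c] for c in range(grid.n_cols)], axis=1)
                for r in range(grid.n_rows)
            ],
            axis=0,
        )
        np.testing.assert_array_equal(rebuilt, img)

    def test_grid_past_image_bounds_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((31, 32, 3), np.uint8), build_patch_grid(32, 32, 16))


class TestLog1p:
    def test_known_values_and_direct_formula(self):
        assert log1p_transform(np.array([0]))[0] == 0.0
        assert log1p_transform(np.array([math.e - 1]))[0] == pytest.approx(1.0, abs=1e-12)
        rng = np.random.default_rng(2)
        c = rng.integers(0, 100, size=100)
        expected = np.array([math.log(v + 1) for v in c])
        np.testing.assert_allclose(log1p_transform(c), expected, atol=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log1p_transform(np.array([-1]))


class TestFilterZeroPatches:
    def _expr(self, counts):
        return PatchExpression(np.asarray(counts), np.arange(len(counts)), GENES)

    def test_zero_patch_removed_and_reported(self):
        expr, removed = filter_zero_patches(self._expr([[1, 0, 0], [0, 0, 0], [0, 2, 0]]))
        assert list(removed) == [1]
        np.testing.assert_array_equal(expr.patch_ids, [0, 2])

    def test_no_zero_patches_is_identity(self):
        expr, removed = filter_zero_patches(self._expr([[1, 0, 0], [0, 1, 0]]))
        assert len(removed) == 0 and expr.n_patches == 2

    def test_all_zero_patches_empty_output(self):
        expr, removed = filter_zero_patches(self._expr(np.zeros((3, 3), int)))
        assert expr.n_patches == 0 and list(removed) == [0, 1, 2]

    def test_images_filtered_alongside(self):
        imgs = np.stack([np.full((4, 4, 3), i, np.uint8) for i in range(3)])
        expr, kept_imgs, removed = filter_zero_patches(
            self._expr([[1, 0, 0], [0, 0, 0], [0, 2, 0]]), imgs
        )
        assert kept_imgs.shape[0] == 2 and (kept_imgs[1] == 2).all()
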