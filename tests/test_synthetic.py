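"""Generator contracts: determinism, count laws, degradation limits, misalignment."""

import dataclasses

import numpy as np
import pytest

from stablate.registration import AffineTransform
from stablate.synthetic import (
    RenderStyle,
    SceneConfig,
    apply_known_misalignment,
    diffuse_spot_rates,
    expected_spot_rates,
    generate_scene,
    make_replicate,
    marker_rate_matrix,
    render_image,
    sample_imaging_counts,
    sample_sequencing_spots,
)


class TestGenerateScene:
    def test_same_config_and_seed_is_byte_identical(self, tiny_config):
        a, b = generate_scene(tiny_config), generate_scene(tiny_config)
        np.testing.assert_array_equal(a.cell_xy, b.cell_xy)
        np.testing.assert_array_equal(a.cell_type, b.cell_type)

    def test_zero_cells_per_type_gives_valid_empty_scene(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, cells_per_type=0)
        scene = generate_scene(cfg)
        assert scene.n_cells == 0
        assert scene.rate_matrix.shape == (cfg.n_cell_types, cfg.n_genes)

    def test_vanishing_niche_sd_collapses_cells_onto_centers(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, niche_sd=0.0)
        scene = generate_scene(cfg)
        for t, (cx, cy) in enumerate(cfg.niche_centers):
            pts = scene.cell_xy[scene.cell_type == t]
            np.testing.assert_allclose(pts, np.broadcast_to([cx, cy], pts.shape), atol=1e-9)

    def test_all_cells_inside_scene_bounds(self, tiny_scene):
        cfg = tiny_scene.config
        assert (tiny_scene.cell_xy[:, 0] >= 0).all()
        assert (tiny_scene.cell_xy[:, 0] < cfg.width_px).all()
        assert (tiny_scene.cell_xy[:, 1] >= 0).all()
        assert (tiny_scene.cell_xy[:, 1] < cfg.height_px).all()

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            SceneConfig(width_px=0)

    def test_marker_genes_have_elevated_rate_in_their_type(self):
        rm = marker_rate_matrix(4, 24, marker_fraction=0.8)
        # 16 marker genes, 4 per type, laid out first
        for t in range(4):
            for g in range(t * 4, (t + 1) * 4):
                others = np.delete(rm[:, g], t)
                assert (rm[t, g] / others > 1).all()


class TestRenderImage:
    def test_empty_scene_renders_uniform_background(self, tiny_config):
        scene = generate_scene(dataclasses.replace(tiny_config, cells_per_type=0))
        img = render_image(scene)
        assert img.shape == (tiny_config.height_px, tiny_config.width_px, 3)
        assert (img == img[0, 0]).all()

    def test_single_cell_alters_pixels_at_its_position(self):
        cfg = SceneConfig(
            width_px=64, height_px=64, n_cell_types=1, n_genes=2,
            cells_per_type=1, niche_centers=((32.0, 20.0),), niche_sd=0.0, seed=0,
        )
        img = render_image(generate_scene(cfg))
        style = RenderStyle()
        assert not (img[20, 32] == np.array(style.background, np.uint8)).all()

    def test_rendering_is_deterministic(self, tiny_scene):
        np.testing.assert_array_equal(render_image(tiny_scene), render_image(tiny_scene))


class TestImagingCounts:
    def test_zero_rate_gene_yields_zero_column(self, tiny_config):
        rm = tiny_config.rate_matrix.copy()
        rm[:, 3] = 0.0
        scene = generate_scene(dataclasses.replace(tiny_config, rate_matrix=rm))
        counts = sample_imaging_counts(scene, 0.9, seed=1).cell_counts
        assert (counts[:, 3] == 0).all()
        assert counts.min() >= 0 and np.issubdtype(counts.dtype, np.integer)

    def test_monte_carlo_mean_matches_efficiency_times_rate(self):
        # one type, many cells: Poisson mean within 3 MC standard errors
        n = 100_000
        cfg = SceneConfig(
            width_px=100, height_px=100, n_cell_types=1, n_genes=3,
            cells_per_type=n, niche_sd=30.0,
            rate_matrix=np.array([[0.5, 2.0, 8.0]]), marker_fraction=0.0, seed=2,
        )
        scene = generate_scene(cfg)
        for eff in (1.0, 0.5):
            counts = sample_imaging_counts(scene, eff, seed=5).cell_counts
            mu = eff * cfg.rate_matrix[0]
            se = np.sqrt(mu / n)
            assert (np.abs(counts.mean(axis=0) - mu) < 3 * se).all()

    def test_rejects_bad_efficiency(self, tiny_scene):
        for eff in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                sample_imaging_counts(tiny_scene, eff)


class TestSequencingSpots:
    def test_heavy_dropout_drives_sparsity_toward_one(self, tiny_scene):
        r = sample_sequencing_spots(tiny_scene, dropout_prob=0.99, seed=3)
        assert (r.spot_counts == 0).mean() > 0.98

    def test_isolated_cell_expectation_equals_efficiency_times_rate(self):
        cfg = SceneConfig(
            width_px=80, height_px=80, n_cell_types=1, n_genes=2,
            cells_per_type=1, niche_centers=((40.0, 40.0),), niche_sd=0.0,
            rate_matrix=np.array([[4.0, 1.0]]), marker_fraction=0.0, seed=0,
        )
        scene = generate_scene(cfg)
        mu, _, n_rows, n_cols = expected_spot_rates(scene, 16.0, capture_efficiency=0.5)
        np.testing.assert_allclose(mu[2, 2], [2.0, 0.5])
        assert mu.sum() == pytest.approx(2.5)

    def test_diffusion_conserves_interior_mass(self):
        # mass only in the interior: nothing can leave through the edges
        rng = np.random.default_rng(0)
        mu = np.zeros((6, 6, 3))
        mu[2:4, 2:4, :] = rng.uniform(0, 5, size=(2, 2, 3))
        out = diffuse_spot_rates(mu, 0.3)
        np.testing.assert_allclose(out.sum(), mu.sum(), atol=1e-9)

    def test_rejects_out_of_range_parameters(self, tiny_scene):
        with pytest.raises(ValueError):
            sample_sequencing_spots(tiny_scene, diffusion_mix=1.0)
        with pytest.raises(ValueError):
            sample_sequencing_spots(tiny_scene, dropout_prob=-0.1)

    def test_spot_centers_form_regular_grid(self, tiny_scene):
        r = sample_sequencing_spots(tiny_scene, spot_pitch=16.0, seed=0)
        xs = np.unique(r.spot_centers[:, 0])
        np.testing.assert_allclose(np.diff(xs), 16.0)

    def test_sequencing_has_higher_zero_fraction_than_imaging_at_equal_efficiency(self):
        # high per-cell rates so imaging zeros are rare; dropout dominates spots
        cfg = SceneConfig(
            width_px=160, height_px=160, n_cell_types=2, n_genes=6,
            cells_per_type=400, niche_sd=60.0,
            rate_matrix=np.full((2, 6), 6.0), marker_fraction=0.0, seed=9,
        )
        scene = generate_scene(cfg)
        img = sample_imaging_counts(scene, 0.5, seed=1)
        seq = sample_sequencing_spots(
            scene, capture_efficiency=0.5, diffusion_mix=0.0, dropout_prob=0.5, seed=1
        )
        assert (seq.spot_counts == 0).mean() > (img.cell_counts == 0).mean()


class TestReplicate:
    def test_replicate_shares_rates_but_not_coordinates(self, tiny_config):
        a = generate_scene(tiny_config)
        b = make_replicate(tiny_config, new_seed=99)
        np.testing.assert_array_equal(a.rate_matrix, b.rate_matrix)
        assert a.n_cells == b.n_cells
        assert not np.array_equal(a.cell_xy, b.cell_xy)

    def test_replicate_per_gene_mean_counts_agree_within_mc_error(self, tiny_config):
        a = sample_imaging_counts(generate_scene(tiny_config), 0.8, seed=1)
        b = sample_imaging_counts(make_replicate(tiny_config, 99), 0.8, seed=2)
        n = a.cell_counts.shape[0]
        ma, mb = a.cell_counts.mean(axis=0), b.cell_counts.mean(axis=0)
        se = np.sqrt((a.cell_counts.var(axis=0) + b.cell_counts.var(axis=0)) / n)
        assert (np.abs(ma - mb) < 3 * np.maximum(se, 1e-6)).all()


class TestMisalignment:
    def test_identity_leaves_points_unchanged(self, tiny_scene):
        out = apply_known_misalignment(tiny_scene.cell_xy, AffineTransform.identity())
        np.testing.assert_allclose(out, tiny_scene.cell_xy)

    def test_transform_then_inverse_restores_points(self, tiny_scene):
        A = AffineTransform(np.array([[1.1, 0.2, 5.0], [-0.1, 0.9, -3.0]]))
        out = apply_known_misalignment(
            apply_known_misalignment(tiny_scene.cell_xy, A), A.inverse()
        )
        np.testing.assert_allclose(out, tiny_scene.cell_xy, atol=1e-9)

    def test_pure_translation_shifts_points_exactly(self, tiny_scene):
        A = AffineTransform(np.array([[1.0, 0.0, 7.0], [0.0, 1.0, -2.0]]))
        out = apply_known_misalignment(tiny_scene.cell_xy, A)
        shift = out - tiny_scene.cell_xy
        np.testing.assert_allclose(shift, np.broadcast_to([7.0, -2.0], shift.shape))

    def test_singular_transform_rejected(self, tiny_scene):
        A = AffineTransform(np.array([[1.0, 0.0, 0.0], [2.0, 0.0, 0.0]]))
        with pytest.raises(np.linalg.LinAlgError):
            apply_known_misalignment(tiny_scene.cell_xy, A)

    def test_image_translation_moves_content(self, tiny_scene):
        img = render_image(tiny_scene)
        A = AffineTransform(np.array([[1.0, 0.0, 10.0], [0.0, 1.0, 0.0]]))
        moved = apply_known_misalignment(img, A)
        np.testing.assert_array_equal(moved[:, 10:, :], img[:, :-10, :])


def test_marker_fidelity_inside_vs_outside_niche(tiny_scene):
    """Mean marker counts are higher for cells of the marked type."""
    counts = sample_imaging_counts(tiny_scene, 0.8, seed=4).cell_counts
    n_types = tiny_scene.config.n_cell_types
    # tiny config: round(0.8*8)=6 -> 4 after even split -> 1 marker per type
    for t in range(n_types):
        inside = tiny_scene.cell_type == t
        assert counts[inside, t].mean() > counts[~inside, t].mean()
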