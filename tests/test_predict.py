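"""Splitting protocol, featurizer determinism, training and inference contracts."""

import dataclasses

import numpy as np
import pytest

from stablate.predict import (
    ModelConfig,
    SplitSpec,
    featurize,
    predict_expression,
    split_dataset,
    train_model,
)
from stablate.rasterize import PatchDataset, PatchExpression, log1p_transform


def _dataset_from_bundle(bundle, split_seed=0):
    expr = PatchExpression(
        bundle.imaging_counts.counts,
        bundle.imaging_counts.patch_ids,
        bundle.gene_names,
        log_expr=log1p_transform(bundle.imaging_counts.counts),
    )
    labels = split_dataset(expr.n_patches, SplitSpec(seed=split_seed))
    return PatchDataset(bundle.patch_images, expr, labels)


class TestSplitDataset:
    def test_hundred_patches_split_75_10_15(self):
        labels = split_dataset(100, SplitSpec(seed=1))
        assert (labels == "train").sum() == 75
        assert (labels == "val").sum() == 10
        assert (labels == "test").sum() == 15

    def test_same_seed_reproduces_labels(self):
        a = split_dataset(57, SplitSpec(seed=4))
        b = split_dataset(57, SplitSpec(seed=4))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, split_dataset(57, SplitSpec(seed=5)))

    def test_assignment_is_exhaustive_and_disjoint(self):
        labels = split_dataset(43, SplitSpec(seed=2))
        assert len(labels) == 43
        assert set(labels) <= {"train", "val", "test"}

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train=0.5, val=0.2, test=0.2)
        with pytest.raises(ValueError):
            split_dataset(5, SplitSpec())


class TestFeaturize:
    def test_fixed_projection_is_deterministic_and_sized(self):
        rng = np.random.default_rng(0)
        imgs = rng.integers(0, 255, (6, 16, 16, 3), np.uint8)
        cfg = ModelConfig(featurizer_kind="fixed-random-projection", embed_dim=20,
                          hidden_dims=(8, 8, 8, 8), epochs=1)
        e1, e2 = featurize(imgs, cfg), featurize(imgs, cfg)
        np.testing.assert_array_equal(e1, e2)
        assert e1.shape == (6, 20)

    def test_identical_patches_get_identical_embeddings(self):
        imgs = np.tile(np.full((16, 16, 3), 90, np.uint8), (4, 1, 1, 1))
        cfg = ModelConfig(embed_dim=16, hidden_dims=(8, 8, 8, 8), epochs=1)
        emb = featurize(imgs, cfg)
        np.testing.assert_allclose(emb, np.broadcast_to(emb[0], emb.shape))

    def test_pretrained_backbone_requires_external_weights(self):
        imgs = np.zeros((2, 16, 16, 3), np.uint8)
        cfg = ModelConfig(featurizer_kind="pretrained-residual-cnn")
        with pytest.raises(NotImplementedError):
            featurize(imgs, cfg)


class TestTrainModel:
    def test_loss_decreases_and_history_is_complete(self, tiny_bundle, fast_model_config):
        ds = _dataset_from_bundle(tiny_bundle)
        model = train_model(ds, fast_model_config)
        hist = model.history
        assert len(hist) == fast_model_config.epochs
        assert hist.train_mse.iloc[-1] < hist.train_mse.iloc[0]
        assert {"train_mse", "val_mse"} <= set(hist.columns)

    def test_small_dataset_memorization_capacity(self, tiny_bundle):
        ds = _dataset_from_bundle(tiny_bundle)
        keep = np.zeros(ds.n_patches, bool)
        keep[:20] = True
        small = ds.subset(keep)
        small.split_labels = np.array(["train"] * 16 + ["val"] * 2 + ["test"] * 2)
        cfg = ModelConfig(
            embed_dim=32, hidden_dims=(64, 48, 32, 32),
            epochs=400, batch_size=16, dropout=0.0, augment=False, seed=1,
        )
        model = train_model(small, cfg)
        assert model.history.train_mse.iloc[-1] < 0.01
        # generalization gap after overfitting: train error < test error
        train_pred = predict_expression(model, small.split("train").patch_images)
        test_pred = predict_expression(model, small.split("test").patch_images)
        train_mse = np.mean((train_pred - small.split("train").log_expr) ** 2)
        test_mse = np.mean((test_pred - small.split("test").log_expr) ** 2)
        assert train_mse < test_mse

    def test_training_is_deterministic_for_fixed_seed(self, tiny_bundle, fast_model_config):
        ds = _dataset_from_bundle(tiny_bundle)
        h1 = train_model(ds, fast_model_config).history
        h2 = train_model(ds, fast_model_config).history
        np.testing.assert_allclose(h1.train_mse, h2.train_mse, rtol=1e-6)

    def test_missing_split_labels_rejected(self, tiny_bundle, fast_model_config):
        ds = _dataset_from_bundle(tiny_bundle)
        ds.split_labels = None
        with pytest.raises(ValueError):
            train_model(ds, fast_model_config)


class TestPredictExpression:
    def test_repeated_inference_is_identical_and_shaped(self, tiny_bundle, fast_model_config):
        ds = _dataset_from_bundle(tiny_bundle)
        model = train_model(ds, fast_model_config)
        p1 = predict_expression(model, ds.patch_images[:7])
        p2 = predict_expression(model, ds.patch_images[:7])
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (7, len(tiny_bundle.gene_names))
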