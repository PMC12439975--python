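"""Patch-level expression prediction from histology patches.

The model mirrors the standard histology-to-expression regression design: an
image featurizer producing a fixed-size embedding, followed by a four-layer
MLP head — each layer a linear transform, batch normalization, ReLU and
dropout — and a final linear layer emitting one value per gene. Training uses
MSE loss on log1p expression with the Adam optimizer (lr 1e-3, weight decay
1e-5 by default), batch size 64, and random horizontal/vertical flips plus
90° rotations as augmentation. Patches are split uniformly at random into
train/validation/test at 75/10/15; the validation split is monitored only —
final-epoch weights are returned, with no early stopping.

Featurizer kinds:

* ``small-cnn`` (default) — a trainable 3-block convolutional network
  (conv–batchnorm–ReLU, 2× average pooling after the first two blocks) ending
  in global average pooling; its last conv block is the Grad-CAM target.
* ``fixed-random-projection`` — a frozen seeded Gaussian projection of the
  raw pixels; fast, deterministic, not convolutional (no saliency support).
* ``pretrained-residual-cnn`` — placeholder for an externally supplied
  pretrained backbone (2048-d embeddings); selecting it raises, since no
  pretrained weights or deep-learning runtime ship with this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from ._rng import child_rng
from .rasterize import PatchDataset

__all__ = [
    "SplitSpec",
    "ModelConfig",
    "TrainedModel",
    "split_dataset",
    "featurize",
    "train_model",
    "predict_expression",
]


@dataclass(frozen=True)
class SplitSpec:
    """Uniform random patch-level train/val/test assignment."""

    train: float = 0.75
    val: float = 0.10
    test: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("split fractions must be nonnegative")


def split_dataset(dataset_or_n, spec: SplitSpec = SplitSpec()) -> np.ndarray:
    """Assign each patch to train/val/test (largest-remainder rounding).

    Accepts a :class:`~stablate.rasterize.PatchDataset` or a patch count and
    returns an array of labels; reuse the same spec (and hence labels) across
    modalities for paired comparisons.
    """
    n_patches = dataset_or_n if isinstance(dataset_or_n, (int, np.integer)) else dataset_or_n.n_patches
    if n_patches < 10:
        raise ValueError("need at least 10 patches to split")
    fracs = np.array([spec.train, spec.val, spec.test])
    counts = np.floor(fracs * n_patches).astype(int)
    rema = fracs * n_patches - counts
    for i in np.argsort(-rema)[: n_patches - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.array(["train", "val", "test"]), counts)
    rng = child_rng(spec.seed, "split")
    return labels[np.argsort(rng.permutation(n_patches))]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters."""

    featurizer_kind: str = "small-cnn"
    embed_dim: int = 128
    hidden_dims: tuple[int, ...] = (256, 128, 64, 32)
    dropout: float = 0.2
    lr: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 64
    epochs: int = 150
    augment: bool = True  # random flips + 90° rotations during training
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden_dims) != 4:
            raise ValueError("the MLP head has exactly 4 hidden layers")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.lr, self.batch_size, self.epochs) <= 0:
            raise ValueError("lr, batch_size and epochs must be positive")
        if self.featurizer_kind not in (
            "small-cnn",
            "fixed-random-projection",
            "pretrained-residual-cnn",
        ):
            raise ValueError(f"unknown featurizer kind {self.featurizer_kind!r}")


def _build_conv_stack(embed_dim: int, rng: np.random.Generator) -> nn.Sequential:
    c1, c2 = max(embed_dim // 4, 4), max(embed_dim // 2, 8)
    return nn.Sequential(
        [
            nn.Conv2d(3, c1, rng=rng),
            nn.BatchNorm(c1),
            nn.ReLU(),
            nn.AvgPool2(),
            nn.Conv2d(c1, c2, rng=rng),
            nn.BatchNorm(c2),
            nn.ReLU(),
            nn.Conv2d(c2, embed_dim, rng=rng),
            nn.BatchNorm(embed_dim),
            nn.ReLU(),
        ]
    )


def _build_head(
    embed_dim: int, n_genes: int, config: ModelConfig, rng: np.random.Generator
) -> nn.Sequential:
    layers = []
    d_in = embed_dim
    for d in config.hidden_dims:
        layers += [
            nn.Linear(d_in, d, rng=rng),
            nn.BatchNorm(d),
            nn.ReLU(),
            nn.Dropout(config.dropout, rng=child_rng(config.seed, "dropout", d_in, d)),
        ]
        d_in = d
    layers.append(nn.Linear(d_in, n_genes, rng=rng))
    return nn.Sequential(layers)


@dataclass
class TrainedModel:
    """Weights, config, seed and the full per-epoch loss history."""

    config: ModelConfig
    gene_names: list[str]
    head: nn.Sequential
    conv_stack: nn.Sequential | None  # None for non-convolutional featurizers
    gap: nn.GlobalAvgPool | None
    projection: np.ndarray | None  # fixed-random-projection matrix
    norm_mean: np.ndarray  # per-channel, dataset-computed
    norm_sd: np.ndarray
    history: pd.DataFrame

    @property
    def is_convolutional(self) -> bool:
        return self.conv_stack is not None

    def normalize(self, patch_images: np.ndarray) -> np.ndarray:
        x = (patch_images.astype(np.float32) / 255.0 - self.norm_mean) / self.norm_sd
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def embed(self, x_nchw: np.ndarray, training: bool = False) -> np.ndarray:
        if self.conv_stack is not None:
            return self.gap.forward(self.conv_stack.forward(x_nchw, training), training)
        flat = x_nchw.reshape(x_nchw.shape[0], -1)
        return (flat @ self.projection.T).astype(np.float32)

    def predict(self, patch_images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference pass: no augmentation, dropout off, batchnorm running stats."""
        outs = []
        for lo in range(0, len(patch_images), batch_size):
            x = self.normalize(patch_images[lo : lo + batch_size])
            outs.append(self.head.forward(self.embed(x, training=False), training=False))
        return np.vstack(outs)


def featurize(patch_images: np.ndarray, config: ModelConfig) -> np.ndarray:
    """One embedding per patch from a freshly built (untrained) featurizer.

    Deterministic for a fixed (config.seed, inputs); useful for probing the
    embedding space and for the frozen-projection pipeline.
    """
    model = _init_model(config, patch_images, n_genes=1)
    return model.embed(model.normalize(patch_images), training=False)


def _init_model(config: ModelConfig, patch_images: np.ndarray, n_genes: int) -> TrainedModel:
    if patch_images.ndim != 4 or patch_images.shape[3] != 3:
        raise ValueError("patch_images must be (n, H, W, 3)")
    if config.featurizer_kind == "pretrained-residual-cnn":
        raise NotImplementedError(
            "the pretrained residual backbone requires externally downloaded "
            "weights and a deep-learning runtime; use 'small-cnn' or "
            "'fixed-random-projection'"
        )
    rng = child_rng(config.seed, "init")
    scaled = patch_images.astype(np.float32) / 255.0
    norm_mean = scaled.mean(axis=(0, 1, 2))
    norm_sd = np.maximum(scaled.std(axis=(0, 1, 2)), 1e-6)
    conv_stack = gap = projection = None
    if config.featurizer_kind == "small-cnn":
        h, w = patch_images.shape[1:3]
        if h % 4 or w % 4:
            raise ValueError("small-cnn needs patch dimensions divisible by 4")
        conv_stack = _build_conv_stack(config.embed_dim, rng)
        gap = nn.GlobalAvgPool()
    else:
        flat_dim = int(np.prod(patch_images.shape[1:]))
        projection = (
            rng.normal(0.0, 1.0 / np.sqrt(flat_dim), size=(config.embed_dim, flat_dim))
        ).astype(np.float32)
    head = _build_head(config.embed_dim, n_genes, config, rng)
    return TrainedModel(
        config=config,
        gene_names=[],
        head=head,
        conv_stack=conv_stack,
        gap=gap,
        projection=projection,
        norm_mean=norm_mean,
        norm_sd=norm_sd,
        history=pd.DataFrame(),
    )


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal/vertical flips and 90° rotations, per sample."""
    out = x.copy()
    flips_h = rng.random(len(x)) < 0.5
    flips_v = rng.random(len(x)) < 0.5
    rots = rng.integers(0, 4, len(x))
    for i in range(len(x)):
        xi = out[i]
        if flips_h[i]:
            xi = xi[:, :, ::-1]
        if flips_v[i]:
            xi = xi[:, ::-1, :]
        if rots[i]:
            xi = np.rot90(xi, k=int(rots[i]), axes=(1, 2))
        out[i] = xi
    return out


def train_model(dataset: PatchDataset, config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Train featurizer (if trainable) and head end-to-end with MSE + Adam.

    Targets are the dataset's log1p expression. Returns the final-epoch
    weights and the full per-epoch train/val loss history. Deterministic for
    a fixed (dataset, config).
    """
    if dataset.split_labels is None:
        raise ValueError("dataset must carry split labels; run split_dataset first")
    train = dataset.split("train")
    if train.n_patches == 0:
        raise ValueError("empty training split")
    val = dataset.split("val")

    model = _init_model(config, train.patch_images, n_genes=len(dataset.expression.gene_names))
    model.gene_names = list(dataset.expression.gene_names)
    params = model.head.parameters() + (
        model.conv_stack.parameters() if model.conv_stack is not None else []
    )
    opt = nn.Adam(params, lr=config.lr, weight_decay=config.weight_decay)

    x_train = model.normalize(train.patch_images)
    y_train = train.log_expr.astype(np.float32)
    x_val = model.normalize(val.patch_images) if val.n_patches else None
    y_val = val.log_expr.astype(np.float32) if val.n_patches else None
    shuffle_rng = child_rng(config.seed, "shuffle")
    aug_rng = child_rng(config.seed, "augment")

    history = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(x_train))
        epoch_losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            if config.augment and model.conv_stack is not None:
                xb = _augment_batch(x_train[idx], aug_rng)
            else:
                xb = x_train[idx]
            opt.zero_grad()
            emb = model.embed(xb, training=True)
            pred = model.head.forward(emb, training=True)
            loss, dloss = nn.mse_loss(pred, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}, batch {lo // config.batch_size}: "
                    f"lr={config.lr}, batch={len(idx)}"
                )
            demb = model.head.backward(dloss.astype(np.float32))
            if model.conv_stack is not None:
                model.conv_stack.backward(model.gap.backward(demb))
            opt.step()
            epoch_losses.append(loss)
        row = {"epoch": epoch, "train_mse": float(np.mean(epoch_losses))}
        if x_val is not None:
            pv = model.head.forward(model.embed(x_val, training=False), training=False)
            row["val_mse"] = float(np.mean((pv - y_val) ** 2))
        history.append(row)
    model.history = pd.DataFrame(history)
    return model


def predict_expression(model: TrainedModel, patch_images: np.ndarray) -> np.ndarray:
    """Deterministic inference: (n_patches, n_genes) predicted log-expression."""
    pred = model.predict(patch_images)
    if model.gene_names and pred.shape[1] != len(model.gene_names):
        raise ValueError("gene-dimension mismatch")
    return pred


def _collect_state(model: TrainedModel) -> dict:
    state = {}
    modules = {"head": model.head}
    if model.conv_stack is not None:
        modules["conv"] = model.conv_stack
    for name, mod in modules.items():
        for i, layer in enumerate(mod.layers):
            for j, p in enumerate(layer.parameters()):
                state[f"{name}.{i}.{j}"] = p.value
            if isinstance(layer, nn.BatchNorm):
                state[f"{name}.{i}.running_mean"] = layer.running_mean
                state[f"{name}.{i}.running_var"] = layer.running_var
    if model.projection is not None:
        state["projection"] = model.projection
    state["norm_mean"] = model.norm_mean
    state["norm_sd"] = model.norm_sd
    return state


def save_model(model: TrainedModel, path: str) -> None:
    """Single-archive checkpoint: weights + config + seed + loss history."""
    import dataclasses
    import json

    meta = {
        "config": dataclasses.asdict(model.config),
        "gene_names": model.gene_names,
        "history": model.history.to_dict(orient="list"),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **_collect_state(model))


def load_model(path: str) -> TrainedModel:
    """Inverse of :func:`save_model`."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = ModelConfig(**{**meta["config"], "hidden_dims": tuple(meta["config"]["hidden_dims"])})
        n_genes = len(meta["gene_names"]) or 1
        # rebuild with matching architecture, then overwrite every tensor
        dummy_hw = 16
        model = _init_model(cfg, np.zeros((1, dummy_hw, dummy_hw, 3), np.uint8), n_genes)
        model.gene_names = meta["gene_names"]
        state = _collect_state(model)
        for key, arr in state.items():
            arr[...] = data[key]
        model.norm_mean = data["norm_mean"]
        model.norm_sd = data["norm_sd"]
        model.history = pd.DataFrame(meta["history"])
    return model
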