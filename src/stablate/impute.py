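"""Expression imputation / smoothing for the rescue experiments.

Two smoothing families operate on patch×gene matrices:

* :func:`knn_smooth` — stepwise k-nearest-neighbour smoothing of raw counts.
  At step s the working matrix is median-depth-normalized,
  Freeman–Tukey-transformed (``√x + √(x+1)``), projected onto the top ``d``
  principal components, and each patch's profile is replaced by the sum of
  the RAW counts of its ``k_s = min(2^s, k)`` nearest neighbours (self
  included); steps repeat until ``k_s = k``. Defaults k=50, d=20.

* :func:`diffusion_smooth` — Markov-graph diffusion of log-expression: build
  a knn graph over patches, weight edges with an adaptive Gaussian kernel
  (per-row bandwidth = distance to the ⌈knn/3⌉-th neighbour), symmetrize,
  row-normalize to a stochastic operator M, and return ``M^t · X``.
  ``t_steps=0`` is the identity escape hatch; the default is a fixed
  ``t_steps=3`` rather than any automatic selection.

A third family — deep generative imputation against an external single-cell
reference — is represented only by the :class:`ExternalImputer` adapter seam:
it needs reference data and model training that live outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "KnnSmoothConfig",
    "DiffusionConfig",
    "knn_smooth",
    "diffusion_smooth",
    "diffusion_operator",
    "ExternalImputer",
]


@dataclass(frozen=True)
class KnnSmoothConfig:
    k: int = 50  # neighbours aggregated at the final step
    d: int = 20  # principal components for the neighbour search
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.d < 1:
            raise ValueError("d must be >= 1")


@dataclass(frozen=True)
class DiffusionConfig:
    knn: int = 50
    t_steps: int = 3  # diffusion operator power (fixed, not auto-selected)
    decay_quantile_k: int | None = None  # bandwidth neighbour; default ceil(knn/3)

    def __post_init__(self):
        if self.t_steps < 0:
            raise ValueError("t_steps must be >= 0")
        if self.knn < 1:
            raise ValueError("knn must be >= 1")


def _freeman_tukey(x: np.ndarray) -> np.ndarray:
    return np.sqrt(x) + np.sqrt(x + 1.0)


def _median_normalize(x: np.ndarray) -> np.ndarray:
    depths = x.sum(axis=1)
    med = np.median(depths[depths > 0]) if (depths > 0).any() else 1.0
    scale = np.where(depths > 0, med / np.maximum(depths, 1e-12), 1.0)
    return x * scale[:, None]


def knn_smooth(raw_counts: np.ndarray, config: KnnSmoothConfig = KnnSmoothConfig()) -> np.ndarray:
    """Stepwise KNN smoothing of a raw patch×gene count matrix.

    Patches with total count below ``d`` are excluded from the smoothing and
    reinserted unchanged (low-count rows destabilize the PCA projection).
    Output rows are sums of raw-count rows, hence integral and nonnegative;
    with k=1 the input is returned unchanged.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2D patch x gene matrix")
    n, g = raw.shape
    if config.k >= n:
        raise ValueError(f"k={config.k} must be < n_patches={n}")
    if raw.sum() == 0:
        raise ValueError("all-zero count matrix cannot be smoothed")
    if config.k == 1:
        return raw.copy()

    ok = raw.sum(axis=1) >= config.d  # low-count patches sit out
    work = raw[ok]
    if work.shape[0] <= config.k:
        raise ValueError("too few usable patches for the requested k")
    d = min(config.d, g, work.shape[0])

    smoothed = work.copy()
    s = 1
    while True:
        k_s = min(2**s, config.k)
        z = _freeman_tukey(_median_normalize(smoothed))
        z = z - z.mean(axis=0, keepdims=True)
        pcs = PCA(n_components=d, svd_solver="full", random_state=config.seed).fit_transform(z)
        nn = NearestNeighbors(n_neighbors=k_s).fit(pcs)
        idx = nn.kneighbors(return_distance=False)  # excludes self
        idx = np.column_stack([np.arange(work.shape[0]), idx[:, : k_s - 1]])
        smoothed = work[idx].sum(axis=1)
        if k_s == config.k:
            break
        s += 1

    out = raw.copy()
    out[ok] = smoothed
    return out


def diffusion_operator(
    x: np.ndarray, config: DiffusionConfig = DiffusionConfig()
) -> np.ndarray:
    """Row-stochastic Markov operator M over the rows of ``x``.

    Adaptive Gaussian affinities ``exp(−(d_ij/σ_i)²)`` with σ_i the distance
    from row i to its ⌈knn/3⌉-th neighbour; symmetrized, self-loops kept, and
    row-normalized so every row sums to 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    knn = min(config.knn, n - 1)
    bw_k = config.decay_quantile_k or int(np.ceil(knn / 3))
    bw_k = max(1, min(bw_k, knn))
    nn = NearestNeighbors(n_neighbors=knn).fit(x)
    dist, idx = nn.kneighbors()
    sigma = np.maximum(dist[:, bw_k - 1], 1e-12)
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), knn)
    W[rows, idx.ravel()] = np.exp(-((dist.ravel() / sigma[rows]) ** 2))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 1.0)  # self-loop: singleton rows stay put
    return W / W.sum(axis=1, keepdims=True)


def diffusion_smooth(
    log_expr: np.ndarray, config: DiffusionConfig = DiffusionConfig()
) -> np.ndarray:
    """Graph diffusion of log-expression: returns ``M^t_steps · X``."""
    x = np.asarray(log_expr, dtype=float)
    if config.t_steps == 0:
        return x.copy()
    M = diffusion_operator(x, config)
    out = x
    for _ in range(config.t_steps):
        out = M @ out
    return out


class ExternalImputer(Protocol):
    """Adapter seam for imputation backends that need external resources.

    A deep generative imputer trained on a matched single-cell reference fits
    here: implement ``__call__(log_expr) -> log_expr`` and pass it wherever an
    experiment config names an imputation step. No such backend ships with
    this package.
    """

    def __call__(self, log_expr: np.ndarray) -> np.ndarray: ...
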