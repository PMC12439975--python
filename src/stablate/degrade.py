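"""In-silico data-quality ablation operators.

Three ways to make good data worse, applied to raw patch-level counts (before
the log transform) or to the histology image:

* reference-matched sparsification — zero a target entry wherever the paired
  lower-sensitivity reference has counts ≤ t (sweeps t over {0, 1, 5, 10, 15,
  20} in the standard design);
* additive Poisson noise — add independent Poisson(λ) draws to every entry
  (λ sweeps {5, 15, 45});
* Gaussian blur — normalized 2D Gaussian convolution of the image with kernel
  sizes {5, 25, 125} and σ = kernel_size / 6, reflect padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._rng import child_rng
from .rasterize import PatchExpression

__all__ = [
    "BlurSpec",
    "match_sparsity",
    "add_poisson_noise",
    "gaussian_blur",
    "blur_kernel",
    "sparsity_fraction",
    "SPARSITY_THRESHOLDS",
    "NOISE_RATES",
    "BLUR_KERNELS",
]

# standard sweep values
SPARSITY_THRESHOLDS = (0, 1, 5, 10, 15, 20)
NOISE_RATES = (5.0, 15.0, 45.0)
BLUR_KERNELS = (5, 25, 125)


@dataclass(frozen=True)
class BlurSpec:
    """Gaussian blur parameters; σ is derived as kernel_size / 6 (±3σ span)."""

    kernel_size: int

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")

    @property
    def sigma(self) -> float:
        return self.kernel_size / 6.0


def _aligned_counts(target, reference):
    if isinstance(target, PatchExpression) and isinstance(reference, PatchExpression):
        if target.counts.shape != reference.counts.shape:
            raise ValueError("target and reference shapes differ")
        if not np.array_equal(target.patch_ids, reference.patch_ids):
            raise ValueError("target and reference patch ids differ")
        if target.gene_names != reference.gene_names:
            raise ValueError("target and reference gene names differ")
        return target.counts, reference.counts
    t, r = np.asarray(target), np.asarray(reference)
    if t.shape != r.shape:
        raise ValueError("target and reference shapes differ")
    return t, r


def match_sparsity(target, reference, t: int):
    """Zero target[p, g] wherever reference[p, g] ≤ t; leave the rest untouched.

    ``target`` and ``reference`` must be aligned patch×gene matrices (or
    PatchExpression objects sharing patch ids and gene names). Raising ``t``
    only ever zeroes more entries, so per-gene sparsity is non-decreasing in
    ``t`` and the operator is idempotent for fixed (reference, t).
    """
    if t < 0:
        raise ValueError("threshold must be >= 0")
    tc, rc = _aligned_counts(target, reference)
    out = np.where(rc <= t, 0, tc)
    if isinstance(target, PatchExpression):
        return PatchExpression(out, target.patch_ids, target.gene_names)
    return out


def add_poisson_noise(counts: np.ndarray, lam: float, seed: int = 0) -> np.ndarray:
    """Add independent Poisson(λ) noise to every count entry.

    The output is elementwise ≥ the input; the added noise has mean and
    variance λ. One realization is drawn per call — degrade the dataset once,
    then split, so train/val/test all see the same degraded matrix.
    """
    if lam < 0:
        raise ValueError("noise rate lambda must be >= 0")
    counts = np.asarray(counts)
    if lam == 0:
        return counts.copy()
    rng = child_rng(seed, "poisson_noise")
    return counts + rng.poisson(lam, size=counts.shape)


def blur_kernel(kernel_size: int) -> np.ndarray:
    """1D Gaussian kernel of odd length ``kernel_size``, σ = size/6, sum 1."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd and >= 1")
    if kernel_size == 1:
        return np.ones(1)
    sigma = kernel_size / 6.0  # kernel spans ±3σ
    x = np.arange(kernel_size) - kernel_size // 2
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur(image: np.ndarray, kernel_size: int | BlurSpec) -> np.ndarray:
    """Per-channel convolution with a normalized 2D Gaussian, reflect padding.

    The 2D kernel is the outer product of the 1D kernel with itself, so the
    convolution is applied separably. ``kernel_size = 1`` is the identity; a
    constant image is returned unchanged for any kernel.
    """
    if isinstance(kernel_size, BlurSpec):
        kernel_size = kernel_size.kernel_size
    k = blur_kernel(kernel_size)
    if kernel_size == 1:
        return np.asarray(image).copy()
    img = np.asarray(image, dtype=float)
    out = ndimage.convolve1d(img, k, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, k, axis=1, mode="reflect")
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(np.asarray(image).dtype)
    return out


def sparsity_fraction(counts) -> np.ndarray:
    """Per-gene proportion of patches with a zero count."""
    c = counts.counts if isinstance(counts, PatchExpression) else np.asarray(counts)
    if c.shape[0] == 0:
        raise ValueError("sparsity undefined for zero patches")
    return (c == 0).mean(axis=0)
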