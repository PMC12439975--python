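"""Synthetic paired histology + spatial-expression data.

A :class:`SyntheticScene` is a 2D tissue of spatially clustered cell types:
each type's cells are drawn from a truncated Gaussian "niche", and a per-type
× per-gene rate matrix gives the expected number of molecules each cell emits
per gene. From one scene we derive every paired modality the downstream
pipeline needs:

* a rendered RGB image in which each cell is an ellipse with type-dependent
  colour and size over a pale background (morphology is therefore genuinely
  predictive of expression, which the prediction task presumes);
* an imaging-like readout — per-cell Poisson counts at high capture
  efficiency, with exact cell coordinates;
* a sequencing-like readout — counts pooled on a regular spot grid at low
  capture efficiency, with symmetric 4-neighbour lateral diffusion and
  independent per-entry dropout;
* serial-section replicates (same generative parameters, independent draws);
* known affine misalignments, creating the registration problem the
  registration module solves.

All samplers are deterministic for a fixed (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as _draw_ellipse

from ._rng import child_rng
from .registration import AffineTransform, transform_points

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "ImagingReadout",
    "SequencingReadout",
    "RenderStyle",
    "marker_rate_matrix",
    "generate_scene",
    "render_image",
    "sample_imaging_counts",
    "sample_sequencing_spots",
    "make_replicate",
    "apply_known_misalignment",
]


def marker_rate_matrix(
    n_cell_types: int,
    n_genes: int,
    marker_fraction: float = 0.8,
    marker_rate: float = 8.0,
    off_rate: float = 0.8,
    base_rate: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Build a type×gene expected-count matrix with type-specific markers.

    A ``marker_fraction`` share of genes is split evenly among the cell types
    as markers: rate ``marker_rate`` in the marked type, ``off_rate``
    elsewhere. Remaining genes are housekeeping-like with rate ``base_rate``
    in every type, jittered ±20% per gene so genes are not interchangeable.
    """
    if not 0 <= marker_fraction <= 1:
        raise ValueError("marker_fraction must be in [0, 1]")
    if min(marker_rate, off_rate, base_rate) < 0:
        raise ValueError("rates must be nonnegative")
    rng = child_rng(seed, "rate_matrix")
    n_marker = int(round(marker_fraction * n_genes))
    n_marker -= n_marker % max(n_cell_types, 1)  # even split across types
    rates = np.full((n_cell_types, n_genes), base_rate)
    rates *= rng.uniform(0.8, 1.2, size=n_genes)[None, :]
    per_type = n_marker // n_cell_types if n_cell_types else 0
    for t in range(n_cell_types):
        cols = slice(t * per_type, (t + 1) * per_type)
        rates[:, cols] = off_rate
        rates[t, cols] = marker_rate
    return rates


@dataclass(frozen=True)
class SceneConfig:
    """Generative parameters for one synthetic tissue scene.

    ``rate_matrix`` is the per-type per-gene expected molecule count per cell;
    ``niche_centers`` holds one (x, y) pixel center per cell type and
    ``niche_sd`` the isotropic Gaussian spread around it (truncated to the
    scene rectangle).
    """

    width_px: int = 416
    height_px: int = 416
    n_cell_types: int = 4
    n_genes: int = 24
    cells_per_type: int = 600
    niche_centers: tuple[tuple[float, float], ...] | None = None
    niche_sd: float = 110.0
    marker_fraction: float = 0.8
    rate_matrix: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.n_cell_types < 1 or self.n_genes < 1:
            raise ValueError("need at least one cell type and one gene")
        if self.cells_per_type < 0:
            raise ValueError("cells_per_type must be >= 0")
        if self.niche_centers is None:
            object.__setattr__(self, "niche_centers", self._default_centers())
        if len(self.niche_centers) != self.n_cell_types:
            raise ValueError("need one niche center per cell type")
        rm = self.rate_matrix
        if rm is None:
            rm = marker_rate_matrix(
                self.n_cell_types, self.n_genes, self.marker_fraction, seed=self.seed
            )
        rm = np.asarray(rm, dtype=float)
        if rm.shape != (self.n_cell_types, self.n_genes):
            raise ValueError("rate_matrix must be n_cell_types x n_genes")
        if (rm < 0).any():
            raise ValueError("rates must be nonnegative")
        object.__setattr__(self, "rate_matrix", rm)

    def _default_centers(self) -> tuple[tuple[float, float], ...]:
        # lay niches on a ring so every type touches several patch rows/cols
        angles = 2 * np.pi * np.arange(self.n_cell_types) / self.n_cell_types
        cx, cy = self.width_px / 2, self.height_px / 2
        r = 0.27 * min(self.width_px, self.height_px)
        return tuple(
            (float(cx + r * np.cos(a)), float(cy + r * np.sin(a))) for a in angles
        )

    @property
    def gene_names(self) -> list[str]:
        return [f"gene{g:03d}" for g in range(self.n_genes)]


@dataclass(frozen=True)
class SyntheticScene:
    """Ground truth: cell positions/types plus the generating config."""

    cell_xy: np.ndarray  # (n_cells, 2) pixel coordinates
    cell_type: np.ndarray  # (n_cells,) int type ids
    config: SceneConfig

    @property
    def rate_matrix(self) -> np.ndarray:
        return self.config.rate_matrix

    @property
    def n_cells(self) -> int:
        return self.cell_xy.shape[0]


@dataclass(frozen=True)
class ImagingReadout:
    """Per-cell integer counts at high capture efficiency (imaging-like)."""

    cell_counts: np.ndarray  # (n_cells, n_genes) nonnegative ints
    cell_coords: np.ndarray  # (n_cells, 2) px
    capture_efficiency: float


@dataclass(frozen=True)
class SequencingReadout:
    """Spot-grid integer counts with diffusion and dropout (sequencing-like)."""

    spot_counts: np.ndarray  # (n_spots, n_genes) nonnegative ints
    spot_centers: np.ndarray  # (n_spots, 2) px, regular grid
    spot_pitch: float
    capture_efficiency: float
    diffusion_mix: float
    dropout_prob: float


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Draw cell positions per type from truncated Gaussian niches.

    Truncation is by rejection sampling against the scene rectangle (with a
    clip fallback for extreme configurations), so ``niche_sd → 0`` collapses
    each type onto its niche center.
    """
    rng = child_rng(config.seed, "scene")
    xys, types = [], []
    for t, (cx, cy) in enumerate(config.niche_centers):
        n = config.cells_per_type
        if n == 0:
            continue
        pts = np.empty((0, 2))
        for _ in range(200):  # rejection-sample the truncation
            need = n - len(pts)
            if need <= 0:
                break
            cand = rng.normal([cx, cy], config.niche_sd, size=(2 * need + 8, 2))
            ok = (
                (cand[:, 0] >= 0)
                & (cand[:, 0] < config.width_px)
                & (cand[:, 1] >= 0)
                & (cand[:, 1] < config.height_px)
            )
            pts = np.vstack([pts, cand[ok][:need]])
        if len(pts) < n:  # pathological sd: clip the remainder into bounds
            extra = rng.normal([cx, cy], config.niche_sd, size=(n - len(pts), 2))
            extra[:, 0] = np.clip(extra[:, 0], 0, np.nextafter(config.width_px, 0))
            extra[:, 1] = np.clip(extra[:, 1], 0, np.nextafter(config.height_px, 0))
            pts = np.vstack([pts, extra])
        xys.append(pts)
        types.append(np.full(n, t, dtype=int))
    if xys:
        cell_xy = np.vstack(xys)
        cell_type = np.concatenate(types)
    else:
        cell_xy = np.empty((0, 2))
        cell_type = np.empty((0,), dtype=int)
    return SyntheticScene(cell_xy=cell_xy, cell_type=cell_type, config=config)


@dataclass(frozen=True)
class RenderStyle:
    """Rendering parameters for the histology-like image."""

    background: tuple[int, int, int] = (236, 228, 232)
    type_colors: tuple[tuple[int, int, int], ...] = (
        (120, 40, 140),  # purple nuclei-like
        (60, 110, 170),
        (170, 80, 60),
        (70, 140, 80),
        (150, 130, 40),
        (40, 140, 140),
        (140, 60, 110),
        (90, 90, 90),
    )
    base_radius: float = 3.0
    radius_per_type: float = 0.6  # type t radius = base + t * this
    jitter: float = 0.35  # relative size jitter per cell
    seed: int = 0


def render_image(scene: SyntheticScene, style: RenderStyle | None = None) -> np.ndarray:
    """Render each cell as a coloured ellipse over a pale background.

    Returns a (height, width, 3) uint8 array. Cells are drawn in scene order;
    overlapping cells simply overwrite, mimicking dense tissue.
    """
    style = style or RenderStyle()
    H, W = scene.config.height_px, scene.config.width_px
    img = np.empty((H, W, 3), dtype=np.uint8)
    img[:] = np.asarray(style.background, dtype=np.uint8)
    if scene.n_cells == 0:
        return img
    rng = child_rng(style.seed, "render", scene.config.seed)
    n = scene.n_cells
    size_jit = 1.0 + style.jitter * (rng.random(n) - 0.5)
    aspect = rng.uniform(0.7, 1.0, n)
    angle = rng.uniform(0.0, np.pi, n)
    color_jit = rng.integers(-12, 13, size=(n, 3))
    colors = np.asarray(style.type_colors)
    for i in range(n):
        t = scene.cell_type[i]
        r = (style.base_radius + style.radius_per_type * t) * size_jit[i]
        rr, cc = _draw_ellipse(
            scene.cell_xy[i, 1],  # row = y
            scene.cell_xy[i, 0],  # col = x
            r,
            r * aspect[i],
            rotation=angle[i],
            shape=(H, W),
        )
        col = np.clip(colors[t % len(colors)] + color_jit[i], 0, 255)
        img[rr, cc] = col.astype(np.uint8)
    return img


def sample_imaging_counts(
    scene: SyntheticScene, capture_efficiency: float = 0.8, seed: int = 0
) -> ImagingReadout:
    """Per-cell Poisson counts: ``c[i,g] ~ Poisson(eff · rate[type(i), g])``."""
    if not 0 < capture_efficiency <= 1:
        raise ValueError("capture_efficiency must be in (0, 1]")
    rng = child_rng(seed, "imaging", scene.config.seed)
    mu = capture_efficiency * scene.rate_matrix[scene.cell_type]
    counts = rng.poisson(mu).astype(np.int64)
    return ImagingReadout(
        cell_counts=counts,
        cell_coords=scene.cell_xy.copy(),
        capture_efficiency=capture_efficiency,
    )


def _spot_grid(width: float, height: float, pitch: float):
    n_cols = int(np.floor(width / pitch))
    n_rows = int(np.floor(height / pitch))
    xs = (np.arange(n_cols) + 0.5) * pitch
    ys = (np.arange(n_rows) + 0.5) * pitch
    gx, gy = np.meshgrid(xs, ys)  # row-major: row index = y
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    return centers, n_rows, n_cols


def expected_spot_rates(scene: SyntheticScene, spot_pitch: float, capture_efficiency: float):
    """Pre-diffusion expected counts per spot: eff · Σ_{cells in spot} rate."""
    centers, n_rows, n_cols = _spot_grid(
        scene.config.width_px, scene.config.height_px, spot_pitch
    )
    mu = np.zeros((n_rows, n_cols, scene.config.n_genes))
    if scene.n_cells:
        col = np.floor(scene.cell_xy[:, 0] / spot_pitch).astype(int)
        row = np.floor(scene.cell_xy[:, 1] / spot_pitch).astype(int)
        inside = (col >= 0) & (col < n_cols) & (row >= 0) & (row < n_rows)
        np.add.at(
            mu,
            (row[inside], col[inside]),
            capture_efficiency * scene.rate_matrix[scene.cell_type[inside]],
        )
    return mu, centers, n_rows, n_cols


def diffuse_spot_rates(mu_grid: np.ndarray, diffusion_mix: float) -> np.ndarray:
    """Symmetric 4-neighbour mixing: each spot keeps (1−m) and sends m/4 to
    each lateral neighbour; mass leaving the grid edge is lost (off-tissue)."""
    if diffusion_mix == 0:
        return mu_grid
    kernel = np.array(
        [
            [0.0, diffusion_mix / 4, 0.0],
            [diffusion_mix / 4, 1.0 - diffusion_mix, diffusion_mix / 4],
            [0.0, diffusion_mix / 4, 0.0],
        ]
    )
    out = np.empty_like(mu_grid)
    for g in range(mu_grid.shape[2]):
        out[:, :, g] = ndimage.convolve(mu_grid[:, :, g], kernel, mode="constant", cval=0.0)
    return out


def sample_sequencing_spots(
    scene: SyntheticScene,
    spot_pitch: float = 16.0,
    capture_efficiency: float = 0.2,
    diffusion_mix: float = 0.2,
    dropout_prob: float = 0.5,
    seed: int = 0,
) -> SequencingReadout:
    """Spot-grid counts with lateral diffusion, Poisson sampling and dropout.

    Per-spot expectation = efficiency · Σ_{cells in spot} rate, mixed with the
    4 lateral neighbours at weight ``diffusion_mix``, Poisson-sampled, then
    each spot×gene entry independently zeroed with ``dropout_prob``.
    """
    if not 0 < capture_efficiency <= 1:
        raise ValueError("capture_efficiency must be in (0, 1]")
    if not 0 <= diffusion_mix < 1:
        raise ValueError("diffusion_mix must be in [0, 1)")
    if not 0 <= dropout_prob < 1:
        raise ValueError("dropout_prob must be in [0, 1)")
    mu, centers, n_rows, n_cols = expected_spot_rates(scene, spot_pitch, capture_efficiency)
    mu = diffuse_spot_rates(mu, diffusion_mix)
    rng = child_rng(seed, "sequencing", scene.config.seed)
    counts = rng.poisson(mu.reshape(n_rows * n_cols, -1)).astype(np.int64)
    if dropout_prob > 0:
        keep = rng.random(counts.shape) >= dropout_prob
        counts = counts * keep
    return SequencingReadout(
        spot_counts=counts,
        spot_centers=centers,
        spot_pitch=float(spot_pitch),
        capture_efficiency=capture_efficiency,
        diffusion_mix=diffusion_mix,
        dropout_prob=dropout_prob,
    )


def save_scene(scene: SyntheticScene, outdir: str) -> None:
    """Write ground truth as plain CSVs: cells (x, y, type_id) and rate matrix."""
    import os

    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame(
        {"x": scene.cell_xy[:, 0], "y": scene.cell_xy[:, 1], "type_id": scene.cell_type}
    ).to_csv(os.path.join(outdir, "cells.csv"), index=False)
    pd.DataFrame(scene.rate_matrix, columns=scene.config.gene_names).to_csv(
        os.path.join(outdir, "rate_matrix.csv"), index=False
    )


def make_replicate(config: SceneConfig, new_seed: int) -> SyntheticScene:
    """A serial-section replicate: identical generative parameters (same rate
    matrix, niches, counts per type), independent cell placement."""
    return generate_scene(replace(config, seed=new_seed, rate_matrix=config.rate_matrix))


def apply_known_misalignment(modality, A: AffineTransform):
    """Perturb a modality by a known affine map (creates a registration task).

    Points — an (n, 2) array — are mapped exactly by ``A``. Images — (H, W)
    or (H, W, 3) arrays — are resampled under ``A`` with bilinear
    interpolation, so output pixel p takes its value from ``A⁻¹·p``.
    """
    det = np.linalg.det(A.linear)
    if abs(det) < 1e-12:
        raise np.linalg.LinAlgError("misalignment transform is singular")
    arr = np.asarray(modality)
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.dtype.kind in "fiu":
        return transform_points(A, arr)
    if arr.ndim in (2, 3):
        inv = A.inverse()
        # scipy's affine_transform works on (row, col) = (y, x): swap axes
        lin_rc = np.array(
            [[inv.linear[1, 1], inv.linear[1, 0]], [inv.linear[0, 1], inv.linear[0, 0]]]
        )
        off_rc = np.array([inv.translation[1], inv.translation[0]])
        if arr.ndim == 2:
            return ndimage.affine_transform(arr, lin_rc, offset=off_rc, order=1, mode="nearest")
        out = np.empty_like(arr)
        for c in range(arr.shape[2]):
            out[..., c] = ndimage.affine_transform(
                arr[..., c], lin_rc, offset=off_rc, order=1, mode="nearest"
            )
        return out
    raise TypeError("modality must be an (n,2) point array or an image array")
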