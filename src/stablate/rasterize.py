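"""Rasterization to a common patch resolution.

Molecule/cell/spot-level counts and a co-registered image are converted into
the unit consumed by training: a grid of square patches, pseudobulk counts per
patch, the matching image crops, natural-log(1+x) expression, and removal of
patches with zero total counts.

Patch (r, c) covers the half-open square
``[origin_x + c·P, origin_x + (c+1)·P) × [origin_y + r·P, origin_y + (r+1)·P)``
so every point belongs to exactly one patch; a point on a shared boundary is
assigned right/downward. Partial edge tiles are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import SequencingReadout

logger = logging.getLogger(__name__)

__all__ = [
    "PatchGrid",
    "PatchExpression",
    "PatchDataset",
    "build_patch_grid",
    "pseudobulk",
    "spots_to_patches",
    "extract_patches",
    "log1p_transform",
    "filter_zero_patches",
]


@dataclass(frozen=True)
class PatchGrid:
    """Square patch tiling of a rectangular region (pixel units)."""

    origin_xy: tuple[float, float]
    patch_size: float
    n_rows: int
    n_cols: int

    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols

    def patch_ids(self) -> np.ndarray:
        return np.arange(self.n_patches)

    def patch_rc(self, patch_id: np.ndarray | int):
        return np.divmod(patch_id, self.n_cols)

    def patch_origin(self, patch_id):
        r, c = self.patch_rc(np.asarray(patch_id))
        return np.stack(
            [self.origin_xy[0] + c * self.patch_size, self.origin_xy[1] + r * self.patch_size],
            axis=-1,
        )

    def patch_centers(self) -> np.ndarray:
        return self.patch_origin(self.patch_ids()) + self.patch_size / 2

    def locate(self, xy: np.ndarray):
        """Map (n, 2) points to (patch_id, inside) under the half-open rule."""
        xy = np.atleast_2d(np.asarray(xy, float))
        c = np.floor((xy[:, 0] - self.origin_xy[0]) / self.patch_size).astype(int)
        r = np.floor((xy[:, 1] - self.origin_xy[1]) / self.patch_size).astype(int)
        inside = (c >= 0) & (c < self.n_cols) & (r >= 0) & (r < self.n_rows)
        pid = np.where(inside, r * self.n_cols + c, -1)
        return pid, inside


@dataclass(frozen=True)
class PatchExpression:
    """Patch×gene counts plus (optionally) their log1p transform."""

    counts: np.ndarray
    patch_ids: np.ndarray
    gene_names: list[str]
    log_expr: np.ndarray | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2D patch x gene matrix")
        if counts.shape[1] != len(self.gene_names):
            raise ValueError("gene dimension mismatch")
        if counts.shape[0] != len(self.patch_ids):
            raise ValueError("patch dimension mismatch")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "patch_ids", np.asarray(self.patch_ids))

    @property
    def n_patches(self) -> int:
        return self.counts.shape[0]

    def with_log(self) -> "PatchExpression":
        return PatchExpression(
            self.counts, self.patch_ids, self.gene_names, log1p_transform(self.counts)
        )


@dataclass
class PatchDataset:
    """Patch images + expression + split labels: the training/evaluation unit."""

    patch_images: np.ndarray  # (n_patches, H, W, 3)
    expression: PatchExpression
    split_labels: np.ndarray | None = None  # "train"/"val"/"test" per patch

    def __post_init__(self):
        if self.patch_images.shape[0] != self.expression.n_patches:
            raise ValueError("one image per patch required")

    @property
    def n_patches(self) -> int:
        return self.expression.n_patches

    @property
    def log_expr(self) -> np.ndarray:
        if self.expression.log_expr is None:
            return log1p_transform(self.expression.counts)
        return self.expression.log_expr

    def subset(self, mask: np.ndarray) -> "PatchDataset":
        expr = PatchExpression(
            self.expression.counts[mask],
            self.expression.patch_ids[mask],
            self.expression.gene_names,
            None if self.expression.log_expr is None else self.expression.log_expr[mask],
        )
        return PatchDataset(
            self.patch_images[mask],
            expr,
            None if self.split_labels is None else self.split_labels[mask],
        )

    def split(self, name: str) -> "PatchDataset":
        if self.split_labels is None:
            raise ValueError("dataset has no split labels")
        return self.subset(self.split_labels == name)


def build_patch_grid(
    region_width: float,
    region_height: float,
    patch_size: float,
    origin_xy: tuple[float, float] = (0.0, 0.0),
) -> PatchGrid:
    """Tile the region with full square patches; partial edge tiles excluded."""
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    if region_width <= 0 or region_height <= 0:
        raise ValueError("region must be non-empty")
    n_cols = int(np.floor(region_width / patch_size))
    n_rows = int(np.floor(region_height / patch_size))
    if n_rows == 0 or n_cols == 0:
        logger.warning("region smaller than one patch: empty grid")
    return PatchGrid(origin_xy=origin_xy, patch_size=float(patch_size), n_rows=n_rows, n_cols=n_cols)


def pseudobulk(
    point_counts: np.ndarray,
    point_xy: np.ndarray,
    grid: PatchGrid,
    gene_names: list[str],
) -> PatchExpression:
    """Sum point-level (cell/molecule) counts into the patch containing each point.

    Points outside the grid are dropped; the number dropped is logged.
    Conservation holds exactly: total over patches = total over in-region points.
    """
    point_counts = np.asarray(point_counts)
    if point_counts.shape[1] != len(gene_names):
        raise ValueError("gene dimension mismatch")
    out = np.zeros((grid.n_patches, point_counts.shape[1]), dtype=point_counts.dtype)
    if point_counts.shape[0]:
        pid, inside = grid.locate(point_xy)
        n_out = int((~inside).sum())
        if n_out:
            logger.info("pseudobulk: dropped %d points outside the grid", n_out)
        np.add.at(out, pid[inside], point_counts[inside])
    return PatchExpression(out, grid.patch_ids(), list(gene_names))


def spots_to_patches(
    readout: SequencingReadout, grid: PatchGrid, gene_names: list[str]
) -> PatchExpression:
    """Identity mapping of spot counts onto the patch containing each spot center.

    The grid is expected to be built at the spot pitch so each retained patch
    holds at most one spot; two spots in one patch is an error. Spots outside
    the grid are dropped (and logged); patches with no spot get zero counts.
    """
    counts = np.zeros((grid.n_patches, len(gene_names)), dtype=readout.spot_counts.dtype)
    pid, inside = grid.locate(readout.spot_centers)
    n_out = int((~inside).sum())
    if n_out:
        logger.info("spots_to_patches: dropped %d spots outside the grid", n_out)
    kept = pid[inside]
    if len(np.unique(kept)) != len(kept):
        raise ValueError("two spots fall in one patch: grid pitch mismatch")
    counts[kept] = readout.spot_counts[inside]
    return PatchExpression(counts, grid.patch_ids(), list(gene_names))


def extract_patches(image: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Crop one (P, P, 3) tile per patch, in row-major patch order."""
    P = int(round(grid.patch_size))
    ox, oy = (int(round(v)) for v in grid.origin_xy)
    H, W = image.shape[:2]
    if oy + grid.n_rows * P > H or ox + grid.n_cols * P > W or ox < 0 or oy < 0:
        raise ValueError("grid extends past image bounds")
    tiles = np.empty((grid.n_patches, P, P, image.shape[2]), dtype=image.dtype)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            y0, x0 = oy + r * P, ox + c * P
            tiles[r * grid.n_cols + c] = image[y0 : y0 + P, x0 : x0 + P]
    return tiles


def log1p_transform(counts: np.ndarray) -> np.ndarray:
    """Natural log with a pseudo-count of 1: ``ln(c + 1)`` elementwise."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    return np.log1p(counts.astype(float))


def save_patch_stack(
    outdir: str, stem: str, patch_images: np.ndarray, grid: PatchGrid, patch_ids: np.ndarray
) -> None:
    """Write patch crops as one multi-page TIFF plus an index CSV.

    The CSV columns are (patch_id, row, col, x0, y0) with x0/y0 the patch's
    top-left corner in image pixels.
    """
    import os

    import pandas as pd
    import tifffile

    os.makedirs(outdir, exist_ok=True)
    tifffile.imwrite(os.path.join(outdir, f"{stem}.tiff"), np.asarray(patch_images))
    r, c = grid.patch_rc(np.asarray(patch_ids))
    origins = grid.patch_origin(patch_ids)
    pd.DataFrame(
        {"patch_id": patch_ids, "row": r, "col": c, "x0": origins[:, 0], "y0": origins[:, 1]}
    ).to_csv(os.path.join(outdir, f"{stem}.index.csv"), index=False)


def filter_zero_patches(
    expr: PatchExpression, images: np.ndarray | None = None
):
    """Drop patches whose total count over all genes is zero.

    Returns ``(filtered_expression, removed_patch_ids)``, or
    ``(filtered_expression, filtered_images, removed_patch_ids)`` when an
    image stack is given.
    """
    keep = expr.counts.sum(axis=1) > 0
    removed = expr.patch_ids[~keep]
    out = PatchExpression(
        expr.counts[keep],
        expr.patch_ids[keep],
        expr.gene_names,
        None if expr.log_expr is None else expr.log_expr[keep],
    )
    if images is None:
        return out, removed
    return out, images[keep], removed
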