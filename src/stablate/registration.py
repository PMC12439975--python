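"""Landmark-based affine registration between two pixel coordinate systems.

Convention: image coordinates are 0-based with the origin at the top-left
corner, x increasing rightward and y downward. An :class:`AffineTransform`
stores a 2×3 matrix ``[L | t]`` acting on column vectors ``(x, y, 1)``; the
fit minimizes the forward least-squares landmark error
``Σ ‖A·source − target‖²``.

Diffeomorphic refinement (LDDMM-style velocity-field registration) is out of
scope here; the affine fit is the seam where an external tool would plug in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LandmarkSet", "AffineTransform", "fit_affine", "transform_points", "residual_error"]


class DegenerateGeometryError(ValueError):
    """Landmark geometry does not determine an affine map (collinear/too few)."""


@dataclass(frozen=True)
class AffineTransform:
    """2×3 affine matrix mapping source pixel coordinates to target pixels."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_parts(cls, linear, translation) -> "AffineTransform":
        return cls(np.column_stack([np.asarray(linear, float), np.asarray(translation, float)]))

    def inverse(self) -> "AffineTransform":
        det = np.linalg.det(self.linear)
        if abs(det) < 1e-12:
            raise np.linalg.LinAlgError("affine linear part is singular")
        inv = np.linalg.inv(self.linear)
        return AffineTransform.from_parts(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        return AffineTransform.from_parts(
            self.linear @ other.linear, self.linear @ other.translation + self.translation
        )

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["matrix"], float))


@dataclass(frozen=True)
class LandmarkSet:
    """Paired (source, target) pixel coordinates, e.g. manually picked points."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.source, float))
        t = np.atleast_2d(np.asarray(self.target, float))
        if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 2:
            raise ValueError("source and target must both be (n, 2) arrays")
        object.__setattr__(self, "source", s)
        object.__setattr__(self, "target", t)

    def __len__(self) -> int:
        return self.source.shape[0]

    @classmethod
    def from_csv(cls, path: str) -> "LandmarkSet":
        df = pd.read_csv(path)
        return cls(
            df[["source_x", "source_y"]].to_numpy(),
            df[["target_x", "target_y"]].to_numpy(),
        )

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            np.column_stack([self.source, self.target]),
            columns=["source_x", "source_y", "target_x", "target_y"],
        ).to_csv(path, index=False)


def fit_affine(landmarks: LandmarkSet) -> AffineTransform:
    """Least-squares affine fit of target ≈ A·source over landmark pairs.

    Requires at least 3 pairs with non-collinear source points; with exactly 3
    non-collinear pairs (or any noiseless affine correspondence) the recovery
    is exact.
    """
    if len(landmarks) < 3:
        raise DegenerateGeometryError("affine fit needs at least 3 landmark pairs")
    src = np.column_stack([landmarks.source, np.ones(len(landmarks))])
    if np.linalg.matrix_rank(src) < 3:
        raise DegenerateGeometryError("source landmarks are collinear or coincident")
    coef, *_ = np.linalg.lstsq(src, landmarks.target, rcond=None)  # (3, 2)
    return AffineTransform(coef.T)


def transform_points(A: AffineTransform, points: np.ndarray) -> np.ndarray:
    """Apply the affine map to an (n, 2) array of pixel coordinates."""
    pts = np.atleast_2d(np.asarray(points, float))
    return pts @ A.linear.T + A.translation


def residual_error(A: AffineTransform, landmarks: LandmarkSet) -> float:
    """Root-mean-square Euclidean landmark residual of the fit, in pixels."""
    if len(landmarks) == 0:
        raise ValueError("empty landmark set")
    resid = transform_points(A, landmarks.source) - landmarks.target
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
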