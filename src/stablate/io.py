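"""Plain-text / image I/O for the formats used throughout the package.

Count matrices travel as MatrixMarket (.mtx) plus TSV sidecars (gene names and
spot/cell coordinates), images as PNG or TIFF, transforms as JSON — all
readable without this package.
"""

from __future__ import annotations

import json
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "save_counts",
    "load_counts",
    "save_image",
    "load_image",
    "save_json",
    "load_json",
]


def save_counts(
    outdir: str,
    prefix: str,
    counts: np.ndarray,
    gene_names: list[str],
    coords: np.ndarray | None = None,
) -> None:
    """Write a rows×genes count matrix as ``<prefix>.mtx`` with TSV sidecars.

    ``coords`` (rows×2, pixel x/y of each row's cell/spot/patch) is optional.
    """
    os.makedirs(outdir, exist_ok=True)
    mmwrite(os.path.join(outdir, f"{prefix}.mtx"), sparse.csr_matrix(np.asarray(counts)))
    pd.Series(gene_names, name="gene").to_csv(
        os.path.join(outdir, f"{prefix}.genes.tsv"), sep="\t", index=False
    )
    if coords is not None:
        pd.DataFrame(np.asarray(coords), columns=["x", "y"]).to_csv(
            os.path.join(outdir, f"{prefix}.coords.tsv"), sep="\t", index=False
        )


def load_counts(outdir: str, prefix: str):
    """Inverse of :func:`save_counts`; returns (counts, gene_names, coords|None)."""
    counts = np.asarray(mmread(os.path.join(outdir, f"{prefix}.mtx")).todense())
    genes = pd.read_csv(os.path.join(outdir, f"{prefix}.genes.tsv"), sep="\t")["gene"].tolist()
    coord_path = os.path.join(outdir, f"{prefix}.coords.tsv")
    coords = None
    if os.path.exists(coord_path):
        coords = pd.read_csv(coord_path, sep="\t")[["x", "y"]].to_numpy()
    return counts, genes, coords


def save_image(path: str, image: np.ndarray) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    iio.imwrite(path, np.asarray(image))


def load_image(path: str) -> np.ndarray:
    return np.asarray(iio.imread(path))


def save_json(path: str, obj) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def load_json(path: str):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")
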