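"""Grad-CAM saliency for a chosen gene output.

For a convolutional featurizer, the gradient of the target gene's raw output
with respect to the final conv block's feature maps is globally averaged into
one importance weight per channel; the weighted sum of the feature maps is
rectified (ReLU keeps only positively contributing regions) and bilinearly
upsampled to the input patch resolution. Heatmaps are max-normalized to
[0, 1] for storage; the dispersion statistic sum-normalizes the map into a
probability distribution and reports its Shannon entropy (nats), so a
single-peak map scores 0 and a uniform map scores ln(H·W).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .predict import TrainedModel

__all__ = ["SaliencyMap", "grad_cam", "saliency_dispersion", "save_saliency_maps"]


class UnsupportedFeaturizerError(TypeError):
    """The model's featurizer exposes no convolutional feature maps."""


@dataclass(frozen=True)
class SaliencyMap:
    """Nonnegative per-patch, per-gene heatmap at input-image resolution."""

    heatmap: np.ndarray  # (H, W), >= 0
    gene: str
    patch_id: int | None = None
    max_normalized: bool = True

    def __post_init__(self):
        if (self.heatmap < 0).any():
            raise ValueError("saliency heatmaps are nonnegative")


def grad_cam(
    model: TrainedModel,
    patch_image: np.ndarray,
    gene: str | int,
    patch_id: int | None = None,
    max_normalize: bool = True,
) -> SaliencyMap:
    """Grad-CAM heatmap for one patch and one gene output.

    ``patch_image`` is a single (H, W, 3) patch; ``gene`` is a name or column
    index into the model's outputs. Runs in inference mode (dropout off,
    batchnorm running statistics).
    """
    if not model.is_convolutional:
        raise UnsupportedFeaturizerError(
            "Grad-CAM needs a convolutional featurizer; the "
            f"{model.config.featurizer_kind!r} featurizer has no feature maps"
        )
    g = model.gene_names.index(gene) if isinstance(gene, str) else int(gene)
    x = model.normalize(patch_image[None])
    fmaps = model.conv_stack.forward(x, training=False)  # (1, C, h, w)
    embed = model.gap.forward(fmaps, training=False)
    out = model.head.forward(embed, training=False)
    dy = np.zeros_like(out)
    dy[0, g] = 1.0  # raw output unit for the target gene
    dembed = model.head.backward(dy)
    dfmaps = model.gap.backward(dembed)  # (1, C, h, w)
    weights = dfmaps[0].mean(axis=(1, 2))  # global-average importance per channel
    cam = np.maximum((weights[:, None, None] * fmaps[0]).sum(axis=0), 0.0)
    cam = resize(
        cam, patch_image.shape[:2], order=1, mode="edge", anti_aliasing=False
    )
    cam = np.maximum(cam, 0.0)
    if max_normalize and cam.max() > 0:
        cam = cam / cam.max()
    return SaliencyMap(
        heatmap=cam,
        gene=model.gene_names[g] if model.gene_names else str(g),
        patch_id=patch_id,
        max_normalized=max_normalize,
    )


def save_saliency_maps(maps: list[SaliencyMap], outdir: str, stem: str = "saliency") -> None:
    """Write heatmaps as a multi-page float32 TIFF plus an index CSV.

    The CSV (``<stem>.index.csv``) has one row per page: page, patch_id, gene.
    """
    import os

    import pandas as pd
    import tifffile

    os.makedirs(outdir, exist_ok=True)
    stack = np.stack([m.heatmap.astype(np.float32) for m in maps])
    tifffile.imwrite(os.path.join(outdir, f"{stem}.tiff"), stack, photometric="minisblack")
    pd.DataFrame(
        {
            "page": np.arange(len(maps)),
            "patch_id": [m.patch_id for m in maps],
            "gene": [m.gene for m in maps],
        }
    ).to_csv(os.path.join(outdir, f"{stem}.index.csv"), index=False)


def saliency_dispersion(smap: SaliencyMap | np.ndarray) -> float:
    """Shannon entropy (nats) of the sum-normalized heatmap.

    Higher values mean more diffuse saliency; a heatmap concentrated on one
    pixel scores 0 and a uniform heatmap scores ln(H·W). All-zero maps are
    undefined and raise.
    """
    h = smap.heatmap if isinstance(smap, SaliencyMap) else np.asarray(smap, float)
    total = h.sum()
    if total <= 0:
        raise ValueError("dispersion undefined for an all-zero heatmap")
    p = (h / total).ravel()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())
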