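"""Config-driven experiment runner.

Reproduces the study designs — technology comparison, sparsity sweep, noise
sweep, blur sweep, and imputation rescue — on synthetic paired data, with one
root seed governing every random draw.

Paired-arm discipline: within one experiment every condition shares the same
scene, patch grid, retained patches, split labels and model seeds; only the
configured factor (counts matrix or image) varies. Patches whose total count
is zero in either modality are excluded from both, so the arms stay aligned.

The evaluation protocol follows the study design: the held-out test split is
scored against the (possibly degraded or imputed) matrix the model was
trained on — the degraded matrix *is* the dataset — while the replicate
evaluation scores the same trained model, without retraining, against an
independent serial section's high-quality (imaging-like) counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from ._rng import child_seed
from .degrade import add_poisson_noise, gaussian_blur, match_sparsity
from .evaluate import aggregate_runs, per_gene_metrics
from .impute import DiffusionConfig, KnnSmoothConfig, diffusion_smooth, knn_smooth
from .predict import ModelConfig, SplitSpec, split_dataset, train_model, predict_expression
from .rasterize import (
    PatchDataset,
    PatchExpression,
    build_patch_grid,
    extract_patches,
    log1p_transform,
    pseudobulk,
    spots_to_patches,
)
from .synthetic import (
    RenderStyle,
    SceneConfig,
    generate_scene,
    make_replicate,
    render_image,
    sample_imaging_counts,
    sample_sequencing_spots,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AssayParams",
    "ExperimentConfig",
    "PairedBundle",
    "desk_model_config",
    "build_paired_bundle",
    "run_condition",
    "sparsity_sweep",
    "noise_sweep",
    "blur_sweep",
    "compare_modalities",
    "rescue_experiment",
    "run_experiment",
]


@dataclass(frozen=True)
class AssayParams:
    """Technology-regime parameters for the two emulated readouts."""

    imaging_efficiency: float = 0.8
    sequencing_efficiency: float = 0.2  # 4:1 capture ratio
    diffusion_mix: float = 0.2
    dropout_prob: float = 0.5


def desk_model_config(seed: int = 0, epochs: int = 35) -> ModelConfig:
    """Desk-scale small-cnn configuration used by the standard experiments."""
    return ModelConfig(
        featurizer_kind="small-cnn",
        embed_dim=32,
        hidden_dims=(64, 48, 32, 32),
        epochs=epochs,
        seed=seed,
    )


@dataclass
class PairedBundle:
    """One scene's aligned modalities plus an independent replicate section."""

    scene_config: SceneConfig
    patch_size: float
    gene_names: list[str]
    image: np.ndarray  # full rendered image
    patch_images: np.ndarray  # (n_kept, P, P, 3)
    imaging_counts: PatchExpression  # imaging-like pseudobulk, kept patches
    sequencing_counts: PatchExpression  # sequencing-like spots, kept patches
    rep_image: np.ndarray
    rep_patch_images: np.ndarray
    rep_imaging_counts: PatchExpression  # replicate's high-quality counts

    @property
    def n_patches(self) -> int:
        return self.imaging_counts.n_patches


def build_paired_bundle(
    scene_config: SceneConfig,
    patch_size: float = 16.0,
    assay: AssayParams = AssayParams(),
    seed: int = 0,
) -> PairedBundle:
    """Generate the scene, its replicate, both readouts and aligned patches."""
    cfg = replace(scene_config, seed=child_seed(seed, "scene"))
    scene = generate_scene(cfg)
    genes = cfg.gene_names
    image = render_image(scene, RenderStyle(seed=child_seed(seed, "render")))
    grid = build_patch_grid(cfg.width_px, cfg.height_px, patch_size)

    imaging = sample_imaging_counts(scene, assay.imaging_efficiency, seed=child_seed(seed, "img"))
    seq = sample_sequencing_spots(
        scene,
        spot_pitch=patch_size,
        capture_efficiency=assay.sequencing_efficiency,
        diffusion_mix=assay.diffusion_mix,
        dropout_prob=assay.dropout_prob,
        seed=child_seed(seed, "seq"),
    )
    img_expr = pseudobulk(imaging.cell_counts, imaging.cell_coords, grid, genes)
    seq_expr = spots_to_patches(seq, grid, genes)
    tiles = extract_patches(image, grid)
    keep = (img_expr.counts.sum(axis=1) > 0) & (seq_expr.counts.sum(axis=1) > 0)

    rep_scene = make_replicate(cfg, child_seed(seed, "replicate_scene"))
    rep_image = render_image(rep_scene, RenderStyle(seed=child_seed(seed, "replicate_render")))
    rep_imaging = sample_imaging_counts(
        rep_scene, assay.imaging_efficiency, seed=child_seed(seed, "replicate_img")
    )
    rep_expr = pseudobulk(rep_imaging.cell_counts, rep_imaging.cell_coords, grid, genes)
    rep_tiles = extract_patches(rep_image, grid)
    rep_keep = rep_expr.counts.sum(axis=1) > 0

    def _sub(expr: PatchExpression, mask) -> PatchExpression:
        return PatchExpression(expr.counts[mask], expr.patch_ids[mask], genes)

    return PairedBundle(
        scene_config=cfg,
        patch_size=patch_size,
        gene_names=genes,
        image=image,
        patch_images=tiles[keep],
        imaging_counts=_sub(img_expr, keep),
        sequencing_counts=_sub(seq_expr, keep),
        rep_image=rep_image,
        rep_patch_images=rep_tiles[rep_keep],
        rep_imaging_counts=_sub(rep_expr, rep_keep),
    )


def run_condition(
    patch_images: np.ndarray,
    log_targets: np.ndarray,
    gene_names: list[str],
    split_labels: np.ndarray,
    model_config: ModelConfig,
    run_seeds: list[int],
    replicate: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Train one model per run seed and evaluate on test split (+ replicate).

    ``log_targets`` is the patch×gene log-expression the models are trained
    on and scored against on the test split; ``replicate`` is an optional
    (patch_images, log_observed) pair evaluated with the same trained models.
    Returns test/replicate aggregates, per-run tables, and the trained models.
    """
    expr = PatchExpression(
        np.zeros_like(log_targets, dtype=np.int64), np.arange(len(log_targets)), list(gene_names),
        log_expr=np.asarray(log_targets, float),
    )
    dataset = PatchDataset(patch_images, expr, split_labels)
    test_mask = split_labels == "test"
    test_tables, rep_tables, models = [], [], []
    for s in run_seeds:
        t0 = time.perf_counter()
        model = train_model(dataset, replace(model_config, seed=s))
        pred_test = predict_expression(model, patch_images[test_mask])
        test_tables.append(
            per_gene_metrics(
                log_targets[test_mask], pred_test, gene_names, run_seed=s, eval_set="test"
            )
        )
        if replicate is not None:
            rep_images, rep_obs = replicate
            pred_rep = predict_expression(model, rep_images)
            rep_tables.append(
                per_gene_metrics(rep_obs, pred_rep, gene_names, run_seed=s, eval_set="replicate")
            )
        models.append(model)
        logger.info("run seed=%s trained in %.1fs", s, time.perf_counter() - t0)
    out = {
        "test": aggregate_runs(test_tables),
        "test_tables": test_tables,
        "models": models,
    }
    if replicate is not None:
        out["replicate"] = aggregate_runs(rep_tables)
        out["replicate_tables"] = rep_tables
    return out


def _trend_row(name: str, res: dict) -> list[dict]:
    rows = [
        {
            "condition": name,
            "eval_set": "test",
            "mean_pcc": res["test"]["mean_pcc"],
            "se_pcc": res["test"]["se_pcc"],
            "mean_nrmse": res["test"]["mean_nrmse"],
            "n_genes_used": res["test"]["n_genes_used"],
        }
    ]
    if "replicate" in res:
        r = res["replicate"]
        rows.append(
            {
                "condition": name,
                "eval_set": "replicate",
                "mean_pcc": r["mean_pcc"],
                "se_pcc": r["se_pcc"],
                "mean_nrmse": r["mean_nrmse"],
                "n_genes_used": r["n_genes_used"],
            }
        )
    return rows


def _common_setup(bundle: PairedBundle, seed: int, n_runs: int):
    split = split_dataset(bundle.n_patches, SplitSpec(seed=child_seed(seed, "split")))
    run_seeds = [child_seed(seed, "run", i) for i in range(n_runs)]
    rep = (bundle.rep_patch_images, log1p_transform(bundle.rep_imaging_counts.counts))
    return split, run_seeds, rep


def sparsity_sweep(
    bundle: PairedBundle,
    thresholds=(0, 1, 5),
    model_config: ModelConfig | None = None,
    n_runs: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference-matched sparsification of the imaging-like counts.

    Baseline plus one condition per threshold t: zero the imaging count where
    the paired sequencing count is ≤ t, retrain, re-evaluate.
    """
    model_config = model_config or desk_model_config()
    split, run_seeds, rep = _common_setup(bundle, seed, n_runs)
    rows = []
    conditions = [("baseline", bundle.imaging_counts.counts)]
    for t in thresholds:
        conditions.append(
            (f"t<={t}", match_sparsity(bundle.imaging_counts, bundle.sequencing_counts, t).counts)
        )
    for name, counts in conditions:
        res = run_condition(
            bundle.patch_images,
            log1p_transform(counts),
            bundle.gene_names,
            split,
            model_config,
            run_seeds,
            replicate=rep,
        )
        rows += _trend_row(name, res)
    return pd.DataFrame(rows)


def noise_sweep(
    bundle: PairedBundle,
    lams=(5.0, 15.0, 45.0),
    model_config: ModelConfig | None = None,
    n_runs: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Additive Poisson noise on the imaging-like counts (one draw per λ)."""
    model_config = model_config or desk_model_config()
    split, run_seeds, rep = _common_setup(bundle, seed, n_runs)
    rows = []
    conditions = [("baseline", bundle.imaging_counts.counts)]
    for lam in lams:
        noisy = add_poisson_noise(
            bundle.imaging_counts.counts, lam, seed=child_seed(seed, "noise", str(lam))
        )
        conditions.append((f"lambda={lam:g}", noisy))
    for name, counts in conditions:
        res = run_condition(
            bundle.patch_images,
            log1p_transform(counts),
            bundle.gene_names,
            split,
            model_config,
            run_seeds,
            replicate=rep,
        )
        rows += _trend_row(name, res)
    return pd.DataFrame(rows)


def blur_sweep(
    bundle: PairedBundle,
    kernels=(1, 5, 25, 125),
    model_config: ModelConfig | None = None,
    n_runs: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Gaussian blur of the whole image before patch extraction.

    The same kernel is applied to training and evaluation images, including
    the replicate's. Returns the trend table and the per-kernel results
    (models included, for downstream saliency analysis).
    """
    model_config = model_config or desk_model_config()
    split, run_seeds, _ = _common_setup(bundle, seed, n_runs)
    cfg = bundle.scene_config
    grid = build_patch_grid(cfg.width_px, cfg.height_px, bundle.patch_size)
    keep = np.isin(grid.patch_ids(), bundle.imaging_counts.patch_ids)
    rep_keep = np.isin(grid.patch_ids(), bundle.rep_imaging_counts.patch_ids)
    log_targets = log1p_transform(bundle.imaging_counts.counts)
    rep_obs = log1p_transform(bundle.rep_imaging_counts.counts)
    rows, results = [], {}
    for k in kernels:
        tiles = extract_patches(gaussian_blur(bundle.image, k), grid)[keep]
        rep_tiles = extract_patches(gaussian_blur(bundle.rep_image, k), grid)[rep_keep]
        res = run_condition(
            tiles,
            log_targets,
            bundle.gene_names,
            split,
            model_config,
            run_seeds,
            replicate=(rep_tiles, rep_obs),
        )
        res["patch_images"] = tiles
        rows += _trend_row(f"kernel={k}", res)
        results[k] = res
    return pd.DataFrame(rows), results


def compare_modalities(
    bundle: PairedBundle,
    model_config: ModelConfig | None = None,
    n_runs: int = 3,
    seed: int = 0,
) -> dict:
    """Imaging-like vs sequencing-like counts on identical images and splits.

    Returns per-arm aggregates, the trend table and per-gene paired PCC
    differences (imaging − sequencing).
    """
    model_config = model_config or desk_model_config()
    split, run_seeds, rep = _common_setup(bundle, seed, n_runs)
    arms = {}
    rows = []
    for name, counts in [
        ("imaging", bundle.imaging_counts.counts),
        ("sequencing", bundle.sequencing_counts.counts),
    ]:
        res = run_condition(
            bundle.patch_images,
            log1p_transform(counts),
            bundle.gene_names,
            split,
            model_config,
            run_seeds,
            replicate=rep,
        )
        arms[name] = res
        rows += _trend_row(name, res)
    shared = arms["imaging"]["test"]["per_gene"].index.intersection(
        arms["sequencing"]["test"]["per_gene"].index
    )
    paired_diff = (
        arms["imaging"]["test"]["per_gene"].loc[shared, "pcc"]
        - arms["sequencing"]["test"]["per_gene"].loc[shared, "pcc"]
    )
    return {"arms": arms, "trend": pd.DataFrame(rows), "paired_pcc_diff": paired_diff}


def rescue_experiment(
    bundle: PairedBundle,
    knn_config: KnnSmoothConfig | None = None,
    diffusion_config: DiffusionConfig | None = None,
    model_config: ModelConfig | None = None,
    n_runs: int = 3,
    seed: int = 0,
) -> dict:
    """Imputation rescue of the sequencing-like matrix.

    Trains on raw vs KNN-smoothed counts (and optionally graph-diffused
    log-expression), evaluating each arm on the test split and on the
    replicate section with no retraining.
    """
    model_config = model_config or desk_model_config()
    if knn_config is None:
        knn_config = KnnSmoothConfig(
            k=min(50, bundle.n_patches - 1), d=min(20, len(bundle.gene_names))
        )
    split, run_seeds, rep = _common_setup(bundle, seed, n_runs)
    raw = bundle.sequencing_counts.counts
    conditions = [("raw", log1p_transform(raw)), ("knn_smooth", log1p_transform(knn_smooth(raw, knn_config)))]
    if diffusion_config is not None:
        conditions.append(
            ("diffusion", diffusion_smooth(log1p_transform(raw), diffusion_config))
        )
    arms, rows = {}, []
    for name, log_targets in conditions:
        res = run_condition(
            bundle.patch_images,
            log_targets,
            bundle.gene_names,
            split,
            model_config,
            run_seeds,
            replicate=rep,
        )
        arms[name] = res
        rows += _trend_row(name, res)
    trend = pd.DataFrame(rows)
    effects = {
        "test_gain": arms["knn_smooth"]["test"]["mean_pcc"] - arms["raw"]["test"]["mean_pcc"],
        "replicate_gain": arms["knn_smooth"]["replicate"]["mean_pcc"]
        - arms["raw"]["replicate"]["mean_pcc"],
    }
    return {"arms": arms, "trend": trend, "effects": effects}


# ---------------------------------------------------------------------------
# YAML-driven entry point


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: scene + assay + model + sweep factor + bookkeeping."""

    experiment: str = "baseline"  # baseline|modality|sparsity|noise|blur|rescue
    scene: dict = field(default_factory=dict)
    assay: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    patch_size: float = 16.0
    thresholds: tuple = (0, 1, 5)
    noise_rates: tuple = (5.0, 15.0, 45.0)
    blur_kernels: tuple = (1, 5, 25, 125)
    n_runs: int = 5
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("thresholds", "noise_rates", "blur_kernels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one configured experiment end to end; fully re-runnable.

    Returns a result bundle with the trend table and provenance; if
    ``config.outdir`` is set, writes the trend table (CSV), per-run metric
    tables (CSV) and provenance (JSON) there.
    """
    t0 = time.perf_counter()
    scene_cfg = SceneConfig(**config.scene)
    assay = AssayParams(**config.assay)
    model_cfg = dataclasses.replace(desk_model_config(), **config.model)
    bundle = build_paired_bundle(scene_cfg, config.patch_size, assay, seed=config.seed)
    logger.info("bundle: %d patches, %d genes", bundle.n_patches, len(bundle.gene_names))

    kind = config.experiment
    extras: dict = {}
    if kind == "baseline":
        split, run_seeds, rep = _common_setup(bundle, config.seed, config.n_runs)
        res = run_condition(
            bundle.patch_images,
            log1p_transform(bundle.imaging_counts.counts),
            bundle.gene_names,
            split,
            model_cfg,
            run_seeds,
            replicate=rep,
        )
        trend = pd.DataFrame(_trend_row("baseline", res))
        extras["tables"] = res["test_tables"]
    elif kind == "modality":
        out = compare_modalities(bundle, model_cfg, config.n_runs, config.seed)
        trend = out["trend"]
        extras["paired_pcc_diff"] = out["paired_pcc_diff"]
    elif kind == "sparsity":
        trend = sparsity_sweep(bundle, config.thresholds, model_cfg, config.n_runs, config.seed)
    elif kind == "noise":
        trend = noise_sweep(bundle, config.noise_rates, model_cfg, config.n_runs, config.seed)
    elif kind == "blur":
        trend, _ = blur_sweep(bundle, config.blur_kernels, model_cfg, config.n_runs, config.seed)
    elif kind == "rescue":
        out = rescue_experiment(
            bundle, model_config=model_cfg, n_runs=config.n_runs, seed=config.seed
        )
        trend = out["trend"]
        extras["effects"] = out["effects"]
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")

    provenance = {
        "experiment": kind,
        "seed": config.seed,
        "n_runs": config.n_runs,
        "n_patches": bundle.n_patches,
        "n_genes": len(bundle.gene_names),
        "config": dataclasses.asdict(config),
        "wall_time_s": round(time.perf_counter() - t0, 2),
    }
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        trend.to_csv(os.path.join(config.outdir, "trend.csv"), index=False)
        with open(os.path.join(config.outdir, "provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=2, default=str)
    return {"trend": trend, "provenance": provenance, **extras}
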