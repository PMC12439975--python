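"""Per-gene prediction metrics and aggregation over independent runs.

Two metrics, computed per gene across evaluation patches:

* Pearson correlation coefficient (PCC) — covariance of observed and
  predicted over the square root of the product of their variances
  (population 1/n normalization; the factor cancels). Higher is better.
* normalized rMSE — root-mean-square error divided by the range
  ``y_max − y_min`` of the observed values on the evaluation set. Lower is
  better; 0 is a perfect prediction.

Genes with zero variance in either observed or predicted values on the
evaluation set are excluded from means, flagged with a reason, and counted.
The replicate evaluation set reuses the SAME trained model — no retraining.
Run-to-run variability is summarized as the mean over genes within each run,
then mean ± standard error over runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "pearson_cc",
    "normalized_rmse",
    "per_gene_metrics",
    "aggregate_runs",
]


def pearson_cc(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between two equal-length vectors.

    Raises on vectors shorter than 2 or with zero variance; callers that need
    flagged exclusion instead of an exception use :func:`per_gene_metrics`.
    """
    x = np.asarray(observed, float).ravel()
    y = np.asarray(predicted, float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    xc, yc = x - x.mean(), y - y.mean()
    vx, vy = np.mean(xc**2), np.mean(yc**2)
    if vx == 0 or vy == 0:
        raise ValueError("zero-variance input")
    return float(np.mean(xc * yc) / np.sqrt(vx * vy))


def normalized_rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """RMSE divided by the observed range ``y_max − y_min``."""
    y = np.asarray(observed, float).ravel()
    yhat = np.asarray(predicted, float).ravel()
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("need two equal-length vectors")
    rng = y.max() - y.min()
    if rng == 0:
        raise ValueError("constant observed vector: range is zero")
    return float(np.sqrt(np.mean((y - yhat) ** 2)) / rng)


def per_gene_metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    gene_names: list[str],
    run_seed: int = 0,
    eval_set: str = "test",
) -> pd.DataFrame:
    """One row per gene: PCC and normalized rMSE on an evaluation set.

    ``observed`` and ``predicted`` are aligned patch×gene matrices restricted
    to the evaluation patches. Zero-variance genes get ``excluded=True`` with
    a reason and NaN metrics rather than propagating NaN into means.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted shapes differ")
    if obs.shape[1] != len(gene_names):
        raise ValueError("gene dimension mismatch")
    rows = []
    for g, gene in enumerate(gene_names):
        o, p = obs[:, g], pred[:, g]
        row = {
            "gene": gene,
            "run_seed": run_seed,
            "eval_set": eval_set,
            "n_obs": len(o),
            "pcc": np.nan,
            "nrmse": np.nan,
            "excluded": False,
            "reason": "",
        }
        if len(o) < 2:
            row.update(excluded=True, reason="fewer than 2 observations")
        elif o.var() == 0:
            row.update(excluded=True, reason="zero variance in observed")
        elif p.var() == 0:
            row.update(excluded=True, reason="zero variance in predicted")
        else:
            row["pcc"] = pearson_cc(o, p)
            row["nrmse"] = normalized_rmse(o, p)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_runs(tables: list[pd.DataFrame]) -> dict:
    """Aggregate per-gene metric tables from independently trained runs.

    Within each run the mean PCC is taken over genes included in ALL runs;
    the grand mean and its standard error are then computed across runs.
    Returns a dict with ``per_gene`` (mean PCC/nrmse per gene), ``mean_pcc``,
    ``se_pcc``, ``mean_nrmse``, ``n_runs`` and ``n_genes_used``.
    """
    if not tables:
        raise ValueError("need at least one metric table")
    all_genes = set(tables[0]["gene"])
    included = set(tables[0].loc[~tables[0]["excluded"], "gene"])
    for t in tables[1:]:
        if set(t["gene"]) != all_genes:
            import warnings

            warnings.warn("inconsistent gene sets across runs; intersecting")
            all_genes &= set(t["gene"])
        included &= set(t.loc[~t["excluded"], "gene"])
    genes_used = sorted(included)
    run_means, run_nrmse, per_gene = [], [], []
    for t in tables:
        sub = t[t["gene"].isin(genes_used)].set_index("gene").loc[genes_used]
        run_means.append(sub["pcc"].mean())
        run_nrmse.append(sub["nrmse"].mean())
        per_gene.append(sub[["pcc", "nrmse"]])
    per_gene_mean = (
        sum(per_gene) / len(per_gene) if per_gene else pd.DataFrame(columns=["pcc", "nrmse"])
    )
    run_means = np.array(run_means, float)
    se = float(run_means.std(ddof=1) / np.sqrt(len(run_means))) if len(run_means) > 1 else 0.0
    return {
        "per_gene": per_gene_mean,
        "mean_pcc": float(run_means.mean()) if len(genes_used) else float("nan"),
        "se_pcc": se,
        "mean_nrmse": float(np.mean(run_nrmse)) if len(genes_used) else float("nan"),
        "n_runs": len(tables),
        "n_genes_used": len(genes_used),
    }
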