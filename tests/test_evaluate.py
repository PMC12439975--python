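"""Metric oracles (independent recomputation), exclusion rules, run aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stablate.evaluate import aggregate_runs, normalized_rmse, pearson_cc, per_gene_metrics


class TestPearson:
    def test_perfect_and_reversed(self):
        assert pearson_cc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_cc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_independent_recomputation_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x, y = rng.normal(size=30), rng.normal(size=30)
            assert pearson_cc(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_worked_example_against_direct_formula(self):
        x, y = np.array([1.0, 2.0, 4.0, 8.0]), np.array([1.0, 3.0, 2.0, 7.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / np.sqrt(np.mean((x - x.mean()) ** 2) * np.mean((y - y.mean()) ** 2))
        assert pearson_cc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        base = pearson_cc(x, y)
        assert pearson_cc(3.0 * x + 7.0, y) == pytest.approx(base, abs=1e-9)
        assert pearson_cc(x, 0.1 * y - 2.0) == pytest.approx(base, abs=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_cc([1, 1, 1], [1, 2, 3])


class TestNormalizedRmse:
    def test_perfect_prediction_is_zero(self):
        assert normalized_rmse([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]) == 0.0

    def test_unit_errors_over_unit_range(self):
        assert normalized_rmse([0.0, 1.0], [1.0, 0.0]) == pytest.approx(1.0)

    def test_matches_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(2)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        expected = np.sqrt(np.mean((y - yhat) ** 2)) / (y.max() - y.min())
        assert normalized_rmse(y, yhat) == pytest.approx(expected, abs=1e-12)

    def test_shift_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(3)
        y, yhat = rng.normal(size=20), rng.normal(size=20)
        base = normalized_rmse(y, yhat)
        assert normalized_rmse(y + 5.0, yhat + 5.0) == pytest.approx(base, abs=1e-12)
        assert normalized_rmse(3.0 * y, 3.0 * yhat) == pytest.approx(base, abs=1e-12)

    def test_constant_observed_raises(self):
        with pytest.raises(ValueError):
            normalized_rmse([2.0, 2.0], [1.0, 3.0])


class TestPerGeneMetrics:
    def test_perfect_single_gene(self):
        obs = np.array([[0.0], [1.0], [2.0]])
        table = per_gene_metrics(obs, obs, ["g"])
        row = table.iloc[0]
        assert row.pcc == pytest.approx(1.0) and row.nrmse == 0.0 and not row.excluded

    def test_zero_variance_gene_excluded_with_reason(self):
        obs = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 4.0]])
        pred = np.array([[0.1, 1.0], [0.2, 2.0], [0.3, 4.0]])
        table = per_gene_metrics(obs, pred, ["flat", "ok"])
        assert table.iloc[0].excluded and "variance" in table.iloc[0].reason
        assert not table.iloc[1].excluded

    def test_one_row_per_gene_including_excluded(self):
        rng = np.random.default_rng(4)
        obs, pred = rng.normal(size=(10, 6)), rng.normal(size=(10, 6))
        obs[:, 2] = 0.0
        table = per_gene_metrics(obs, pred, [f"g{i}" for i in range(6)])
        assert len(table) == 6


class TestAggregateRuns:
    def _table(self, pccs, seed):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(pccs))],
                "run_seed": seed,
                "eval_set": "test",
                "n_obs": 10,
                "pcc": pccs,
                "nrmse": [0.1] * len(pccs),
                "excluded": [False] * len(pccs),
                "reason": [""] * len(pccs),
            }
        )

    def test_single_run_equals_its_own_mean(self):
        summary = aggregate_runs([self._table([0.2, 0.6], 0)])
        assert summary["mean_pcc"] == pytest.approx(0.4)
        assert summary["se_pcc"] == 0.0 and summary["n_genes_used"] == 2

    def test_two_point_standard_error(self):
        summary = aggregate_runs([self._table([0.4], 0), self._table([0.6], 1)])
        assert summary["mean_pcc"] == pytest.approx(0.5)
        assert summary["se_pcc"] == pytest.approx(0.1)

    def test_run_order_does_not_matter(self):
        t1, t2, t3 = (self._table([0.1, 0.5, 0.9], s) for s in (0, 1, 2))
        a = aggregate_runs([t1, t2, t3])
        b = aggregate_runs([t3, t1, t2])
        assert a["mean_pcc"] == b["mean_pcc"] and a["se_pcc"] == b["se_pcc"]

    def test_gene_excluded_in_any_run_is_dropped_from_means(self):
        t1 = self._table([0.4, 0.8], 0)
        t2 = self._table([0.6, 0.2], 1)
        t2.loc[1, "excluded"] = True
        summary = aggregate_runs([t1, t2])
        assert summary["n_genes_used"] == 1
        assert summary["mean_pcc"] == pytest.approx(0.5)
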