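import numpy as np
import pytest

import tabimpute as ti
from tabimpute.evaluation import derive_seed
from tabimpute.imputation import ImputerSpec, impute_simple
from tabimpute.tabular_io import CATEGORICAL

from conftest import make_dataset


def oracle_imputer(truth):
    """Test double: an 'imputer' that fills hidden cells with the truth."""

    def run(masked, seed):
        completed = impute_simple(masked, "mean")
        completed.dataset.values[masked.mask] = truth[masked.mask]
        return completed

    return run


class TestMaskMcar:
    def test_floor_count_on_complete_table(self):
        d = make_dataset(np.arange(50.0).reshape(10, 5))
        masked, plan = ti.mask_mcar(d, 0.2, seed=0)
        assert plan.hidden_cells.shape[0] == 10
        assert masked.mask.sum() == 10

    def test_same_seed_same_cells(self):
        d = make_dataset(np.arange(50.0).reshape(10, 5))
        _, a = ti.mask_mcar(d, 0.3, seed=7)
        _, b = ti.mask_mcar(d, 0.3, seed=7)
        assert np.array_equal(a.hidden_cells, b.hidden_cells)

    def test_rate_grid_counts_on_100x20(self):
        rng = np.random.default_rng(0)
        d = make_dataset(rng.standard_normal((100, 20)))
        for i, rate in enumerate(np.arange(0.1, 0.95, 0.1)):
            masked, plan = ti.mask_mcar(d, float(rate), seed=i)
            assert plan.hidden_cells.shape[0] == int(np.floor(rate * 2000))
            assert (~masked.mask).sum(axis=0).min() >= 1

    def test_unmask_restores_original(self, small_mixed):
        masked, plan = ti.mask_mcar(small_mixed, 0.2, seed=3)
        assert ti.unmask(masked, plan).equals(small_mixed)

    def test_eligibility_excludes_preexisting_missing(self, small_mixed):
        masked, plan = ti.mask_mcar(small_mixed, 0.25, seed=1)
        eligible = int((~small_mixed.mask).sum())
        assert plan.hidden_cells.shape[0] == int(np.floor(0.25 * eligible))
        hidden = set(map(tuple, plan.hidden_cells))
        pre = set(map(tuple, np.argwhere(small_mixed.mask)))
        assert not hidden & pre

    def test_column_left_empty_raises(self):
        d = make_dataset(np.ones((1, 3)))
        with pytest.raises(ValueError, match="lower rate"):
            ti.mask_mcar(d, 0.4, seed=0)


class TestErrorMetrics:
    def test_perfect_imputation_gives_zero_rmse(self):
        d = make_dataset(np.arange(20.0).reshape(5, 4))
        masked, plan = ti.mask_mcar(d, 0.2, seed=1)
        assert ti.rmse_on_masked(plan, oracle_imputer(d.values)(masked, 0)) == 0.0

    def test_constant_offset_gives_that_rmse(self):
        d = make_dataset(np.arange(20.0).reshape(5, 4))
        masked, plan = ti.mask_mcar(d, 0.25, seed=2)
        completed = oracle_imputer(d.values)(masked, 0)
        completed.dataset.values[masked.mask] += 1.5
        assert ti.rmse_on_masked(plan, completed) == pytest.approx(1.5, abs=1e-12)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(5)
        d = make_dataset(rng.standard_normal((30, 6)))
        masked, plan = ti.mask_mcar(d, 0.3, seed=4)
        completed = impute_simple(masked, "mean")
        got = ti.rmse_on_masked(plan, completed)
        total = 0.0
        for (i, j), truth in zip(plan.hidden_cells, plan.true_values):
            total += (completed.values[i, j] - truth) ** 2
        expected = np.sqrt(total / plan.hidden_cells.shape[0])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_non_hidden_cells(self):
        rng = np.random.default_rng(6)
        d = make_dataset(rng.standard_normal((20, 4)))
        masked, plan = ti.mask_mcar(d, 0.2, seed=9)
        a = impute_simple(masked, "mean")
        b = impute_simple(masked, "median")
        hidden = plan.hidden_cells
        b.dataset.values[hidden[:, 0], hidden[:, 1]] = a.values[
            hidden[:, 0], hidden[:, 1]
        ]
        assert ti.rmse_on_masked(plan, a) == ti.rmse_on_masked(plan, b)

    def test_zscore_scale_matches_manual_standardisation(self):
        rng = np.random.default_rng(8)
        d = make_dataset(5.0 + 3.0 * rng.standard_normal((40, 3)))
        masked, plan = ti.mask_mcar(d, 0.2, seed=2)
        completed = impute_simple(masked, "mean")
        got = ti.rmse_on_masked(plan, completed, scale="zscore")
        cols = plan.hidden_cells[:, 1]
        mu, sd = plan.col_mean[cols], plan.col_sd[cols]
        est = completed.values[plan.hidden_cells[:, 0], cols]
        expected = np.sqrt(
            np.mean(((est - mu) / sd - (plan.true_values - mu) / sd) ** 2)
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_pfc_counts_wrong_levels(self):
        # 20 hidden categorical cells, 7 imputed wrongly -> 0.35
        vals = np.zeros((20, 2))
        vals[:, 1] = 1.0
        d = make_dataset(vals, col_types=[CATEGORICAL, CATEGORICAL],
                         cat_levels=[["a", "b"], ["a", "b"]])
        masked, plan = ti.mask_mcar(d, 0.5, seed=0)
        completed = oracle_imputer(d.values)(masked, 0)
        flip = plan.hidden_cells[:7]
        completed.dataset.values[flip[:, 0], flip[:, 1]] = (
            1.0 - completed.dataset.values[flip[:, 0], flip[:, 1]]
        )
        assert ti.pfc_on_masked(plan, completed) == pytest.approx(0.35)

    def test_no_continuous_hidden_cells_directs_to_pfc(self):
        d = make_dataset(np.zeros((10, 1)), col_types=[CATEGORICAL],
                         cat_levels=[["a"]])
        masked, plan = ti.mask_mcar(d, 0.2, seed=0)
        with pytest.raises(ValueError, match="pfc"):
            ti.rmse_on_masked(plan, impute_simple(masked))


class TestBenchmarkGrid:
    def test_replicate_rows_and_exact_mean(self):
        rng = np.random.default_rng(1)
        d = make_dataset(rng.standard_normal((20, 5)))
        report = ti.benchmark_grid(d, [ImputerSpec("mean")], rates=[0.2],
                                   n_replicates=3, base_seed=0)
        rows = report.per_run
        assert len(rows) == 3
        agg = report.aggregate()
        assert agg["mean"].iloc[0] == pytest.approx(rows["value"].mean(), abs=1e-15)

    def test_oracle_double_scores_zero_everywhere(self):
        rng = np.random.default_rng(2)
        d = make_dataset(rng.standard_normal((20, 5)))
        report = ti.benchmark_grid(d, [("oracle", oracle_imputer(d.values))],
                                   rates=[0.1, 0.3], n_replicates=2, base_seed=1)
        assert (report.per_run["value"] == 0).all()

    def test_masks_shared_across_methods_within_replicate(self):
        rng = np.random.default_rng(3)
        d = make_dataset(rng.standard_normal((15, 4)))
        seen = {}

        def recorder(label):
            def run(masked, seed):
                seen.setdefault(label, []).append(masked.mask.copy())
                return impute_simple(masked, "mean")

            return run

        ti.benchmark_grid(d, [("a", recorder("a")), ("b", recorder("b"))],
                          rates=[0.2], n_replicates=3, base_seed=5)
        for ma, mb in zip(seen["a"], seen["b"]):
            assert np.array_equal(ma, mb)

    def test_single_replicate_equals_manual_chain(self):
        rng = np.random.default_rng(4)
        d = make_dataset(rng.standard_normal((20, 5)))
        report = ti.benchmark_grid(d, [ImputerSpec("mean")], rates=[0.3],
                                   n_replicates=1, base_seed=9)
        seed = derive_seed(9, 0, 0)
        masked, plan = ti.mask_mcar(d, 0.3, seed)
        expected = ti.rmse_on_masked(plan, impute_simple(masked, "mean"))
        assert report.per_run["value"].iloc[0] == pytest.approx(expected, abs=1e-15)

    def test_failures_recorded_without_aborting(self):
        rng = np.random.default_rng(5)
        d = make_dataset(rng.standard_normal((20, 3)))

        def broken(masked, seed):
            raise RuntimeError("boom")

        report = ti.benchmark_grid(d, [("broken", broken), ImputerSpec("mean")],
                                   rates=[0.2], n_replicates=2, base_seed=0)
        rows = report.per_run
        assert rows[rows.method == "broken"]["error"].notna().all()
        assert rows[rows.method == "mean"]["error"].isna().all()


class TestHoldoutDiagnostic:
    def test_oracle_imputer_gives_perfect_correlation(self):
        rng = np.random.default_rng(6)
        d = make_dataset(rng.standard_normal((100, 4)))
        stats = ti.holdout_correlation_diagnostic(
            d, oracle_imputer(d.values), fraction=0.1, seed=0
        )
        assert all(s.kind == "pearson_r" and s.statistic == pytest.approx(1.0)
                   for s in stats)

    def test_small_holdout_flagged_with_absolute_error(self):
        rng = np.random.default_rng(7)
        d = make_dataset(rng.standard_normal((40, 2)))
        stats = ti.holdout_correlation_diagnostic(
            d, oracle_imputer(d.values), fraction=0.05, seed=0
        )
        # floor(0.05 * 40) = 2 holdout cells per column -> flagged
        assert all(s.n_holdout == 2 and s.flagged and s.kind == "mean_abs_error"
                   for s in stats)

    def test_boosted_recovers_planted_linear_column(self, suite):
        complete = ti.complete_dataset_from(suite["linear"])
        stats = ti.holdout_correlation_diagnostic(
            complete, ImputerSpec("boosted"), fraction=0.05, seed=1
        )
        dep = next(s for s in stats if s.name == complete.col_names[3])
        assert dep.kind == "pearson_r" and dep.statistic > 0.9
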