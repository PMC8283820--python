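import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tabimpute as ti
from tabimpute.imputation import (
    CONTINUE,
    STOP_RETURN_CURRENT,
    STOP_RETURN_PREVIOUS,
    IterState,
    _sweep_deltas,
    stopping_criterion,
)
from tabimpute.learners import boosted_fit_predict
from tabimpute.tabular_io import CATEGORICAL

from conftest import make_dataset

ALL_SPECS = [
    ti.ImputerSpec("mean"),
    ti.ImputerSpec("median"),
    ti.ImputerSpec("knn", {"k": 3}),
    ti.ImputerSpec("soft_svd"),
    ti.ImputerSpec("chained", {"n_cycles": 3}),
    ti.ImputerSpec("boosted", {"max_iter": 2, "n_estimators": 20}),
]


class TestImputeSimple:
    def test_mean_fill(self):
        d = make_dataset([[1.0], [np.nan], [3.0]])
        assert ti.impute_simple(d, "mean").values[1, 0] == 2.0

    def test_median_fill(self):
        d = make_dataset([[1.0], [np.nan], [3.0], [100.0]])
        assert ti.impute_simple(d, "median").values[1, 0] == 3.0

    def test_categorical_mode_fill(self):
        d = make_dataset(
            [[0.0], [0.0], [1.0], [np.nan]],
            col_types=[CATEGORICAL],
            cat_levels=[["a", "b"]],
        )
        assert ti.impute_simple(d).values[3, 0] == 0.0

    def test_modal_tie_resolves_to_lowest_code(self):
        d = make_dataset(
            [[1.0], [0.0], [np.nan]], col_types=[CATEGORICAL],
            cat_levels=[["a", "b"]],
        )
        assert ti.impute_simple(d).values[2, 0] == 0.0

    def test_fully_missing_column_raises_with_name(self):
        d = make_dataset([[1.0, np.nan], [2.0, np.nan]], names=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            ti.impute_simple(d)


class TestColumnOrdering:
    def test_sorted_by_ascending_missing_count(self):
        mask = np.zeros((5, 3), bool)
        mask[:3, 0] = True  # 3 missing
        mask[0, 2] = True  # 1 missing
        assert ti.sort_columns_by_missingness(mask).tolist() == [1, 2, 0]

    def test_all_equal_counts_keep_original_order(self):
        mask = np.zeros((4, 5), bool)
        assert ti.sort_columns_by_missingness(mask).tolist() == [0, 1, 2, 3, 4]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_argsort_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(20, 50)) < rng.uniform(0, 0.5)
        got = ti.sort_columns_by_missingness(mask)
        counts = mask.sum(axis=0)
        oracle = np.lexsort((np.arange(50), counts))
        assert got.tolist() == oracle.tolist()


class TestStoppingCriterion:
    def _state(self, deltas, iteration):
        return IterState(None, None, np.arange(2), iteration,
                         [(d, 0.0) for d in deltas])

    def test_first_sweep_continues(self):
        assert stopping_criterion(self._state([0.5], 1), 10) == CONTINUE

    def test_increase_returns_previous_iterate(self):
        assert (
            stopping_criterion(self._state([0.5, 0.2, 0.3], 3), 10)
            == STOP_RETURN_PREVIOUS
        )

    def test_monotone_deltas_stop_at_cap(self):
        assert (
            stopping_criterion(self._state([0.5, 0.4, 0.3], 3), 3)
            == STOP_RETURN_CURRENT
        )

    def test_categorical_delta_increase_also_stops(self):
        state = IterState(None, None, np.arange(2), 2,
                          [(0.5, 0.1), (0.4, 0.3)])
        assert stopping_criterion(state, 10) == STOP_RETURN_PREVIOUS


class TestObservedCellsNeverModified:
    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.method)
    def test_observed_cells_bit_identical(self, small_mixed, spec):
        completed = ti.run_imputer(small_mixed, spec, seed=0)
        obs = ~small_mixed.mask
        assert np.array_equal(completed.values[obs], small_mixed.values[obs])
        assert not np.isnan(completed.values).any()


class TestImputeBoosted:
    def test_no_missing_cells_returns_unchanged_zero_sweeps(self):
        d = make_dataset(np.arange(12.0).reshape(4, 3))
        completed = ti.impute_boosted(d, seed=0)
        assert np.array_equal(completed.values, d.values)
        assert completed.iter_state.iteration == 0

    def test_single_sweep_matches_independent_oracle_fits(self, suite):
        # 3-column fixture: one sweep must equal per-column oracle models
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 3))
        X[:, 2] = X[:, 0] + 0.1 * rng.standard_normal(60)
        mask = np.zeros((60, 3), bool)
        mask[:6, 2] = True
        vals = X.copy()
        vals[mask] = np.nan
        d = make_dataset(vals, mask)
        spec = ti.ImputerSpec("boosted", {"max_iter": 1, "n_estimators": 30})
        completed = ti.impute_boosted(d, spec, seed=11)
        # oracle: same initial mean fill, same learner, one fit on column 2
        filled = vals.copy()
        filled[mask] = np.nanmean(vals[:, 2])
        obs = ~mask[:, 2]
        pred = boosted_fit_predict(
            filled[obs][:, :2], filled[obs, 2], filled[~obs][:, :2],
            "regression", {}, seed=11, n_estimators=30,
        )
        assert np.array_equal(completed.values[~obs, 2], pred)

    def test_delta_history_recomputes_from_stored_iterates(self, suite):
        fx = ti.generate(ti.FixtureSpec(n_samples=80, n_continuous=4,
                                        latent_rank=2, noise_sd=0.1,
                                        missing_rates=[0.2] * 4, seed=8))
        completed = ti.impute_boosted(
            fx.dataset, ti.ImputerSpec("boosted", {"n_estimators": 30}), seed=1
        )
        state = completed.iter_state
        cont = fx.dataset.continuous_columns
        cat_missing = fx.dataset.mask & ~np.broadcast_to(cont, fx.dataset.mask.shape)
        recomputed = _sweep_deltas(state.X_old_imp, state.X_new_imp, cont, cat_missing)
        assert recomputed[0] == pytest.approx(state.delta_history[-1][0], abs=1e-12)
        assert recomputed[1] == pytest.approx(state.delta_history[-1][1], abs=1e-12)

    def test_planted_linear_recovery_beats_mean_by_half(self, suite):
        complete = ti.complete_dataset_from(suite["linear"])
        # mask 10% of the dependent column only
        rng = np.random.default_rng(17)
        rows = rng.choice(500, size=50, replace=False)
        vals = complete.values.copy()
        mask = np.zeros_like(complete.mask)
        mask[rows, 3] = True
        vals[mask] = np.nan
        d = make_dataset(vals, mask, names=complete.col_names)
        boosted = ti.impute_boosted(d, seed=0)
        mean = ti.impute_simple(d, "mean")
        truth = complete.values[rows, 3]
        rmse_b = np.sqrt(np.mean((boosted.values[rows, 3] - truth) ** 2))
        rmse_m = np.sqrt(np.mean((mean.values[rows, 3] - truth) ** 2))
        assert rmse_b < 0.5 * rmse_m

    def test_deterministic_in_inputs(self, small_mixed):
        spec = ti.ImputerSpec("boosted", {"max_iter": 2, "n_estimators": 20})
        a = ti.impute_boosted(small_mixed, spec, seed=4)
        b = ti.impute_boosted(small_mixed, spec, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_too_few_observed_rows_raises_with_column_name(self):
        vals = np.full((6, 2), np.nan)
        vals[:, 0] = np.arange(6.0)
        vals[0, 1] = 1.0
        d = make_dataset(vals, names=["full", "sparse"])
        with pytest.raises(ValueError, match="sparse"):
            ti.impute_boosted(d)


class TestImputeChained:
    def test_zero_masked_cells_unchanged(self):
        d = make_dataset(np.arange(12.0).reshape(4, 3))
        assert np.array_equal(ti.impute_chained(d, seed=0).values, d.values)

    def test_beats_mean_on_planted_linear(self, suite):
        complete = ti.complete_dataset_from(suite["linear"])
        masked, plan = ti.mask_mcar(complete, 0.1, seed=5)
        rmse_c = ti.rmse_on_masked(plan, ti.impute_chained(masked, seed=0))
        rmse_m = ti.rmse_on_masked(plan, ti.impute_simple(masked, "mean"))
        assert rmse_c < rmse_m

    def test_bit_identical_reruns(self, small_mixed):
        a = ti.impute_chained(small_mixed, n_cycles=3, seed=2)
        b = ti.impute_chained(small_mixed, n_cycles=3, seed=2)
        assert np.array_equal(a.values, b.values)


class TestImputeKnn:
    def test_exact_neighbor_with_k1(self):
        vals = np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 7.0], [9.0, 9.0, 0.0]])
        d = make_dataset(vals)
        assert ti.impute_knn(d, k=1).values[0, 2] == 7.0

    def test_identical_rows_share_value_for_any_k(self):
        vals = np.tile([1.0, 2.0, 3.0], (6, 1))
        vals[0, 1] = np.nan
        d = make_dataset(vals)
        for k in (1, 3, 5):
            assert ti.impute_knn(d, k).values[0, 1] == 2.0

    def test_matches_brute_force_oracle_on_mixed_fixture(self):
        fx = ti.generate(
            ti.FixtureSpec(n_samples=30, n_continuous=3, n_categorical=2,
                           latent_rank=2, noise_sd=0.3,
                           missing_rates=[0.2, 0.1, 0.2, 0.15, 0.1], seed=21)
        )
        d = fx.dataset
        completed = ti.impute_knn(d, k=3)
        n, m = d.values.shape
        cont = d.continuous_columns
        for i, j in zip(*np.nonzero(d.mask)):
            # O(n^2) oracle: partial distances computed cell by cell
            dists = []
            for r in range(n):
                if r == i or d.mask[r, j]:
                    continue
                ss, usable = 0.0, 0
                for c in range(m):
                    if d.mask[i, c] or d.mask[r, c]:
                        continue
                    usable += 1
                    if cont[c]:
                        ss += (d.values[i, c] - d.values[r, c]) ** 2
                    else:
                        ss += float(d.values[i, c] != d.values[r, c])
                if usable:
                    dists.append(((m / usable) * ss, r))
            dists.sort()
            donors = [r for _, r in dists[:3]]
            vals = d.values[donors, j]
            if cont[j]:
                expected = vals.mean()
            else:
                counts = np.bincount(vals.astype(int), minlength=3)
                expected = float(np.argmax(counts))
            assert completed.values[i, j] == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_sklearn_on_continuous_data(self):
        from sklearn.impute import KNNImputer

        fx = ti.generate(
            ti.FixtureSpec(n_samples=40, n_continuous=5, latent_rank=2,
                           noise_sd=0.5, missing_rates=[0.1] * 5, seed=13)
        )
        d = fx.dataset
        ours = ti.impute_knn(d, k=4).values
        X = d.values.copy()
        theirs = KNNImputer(n_neighbors=4).fit_transform(X)
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_k_larger_than_rows_raises(self):
        d = make_dataset(np.ones((3, 2)))
        with pytest.raises(ValueError):
            ti.impute_knn(d, k=3)


class TestImputeSoftSvd:
    def test_no_missing_cells_identity(self):
        d = make_dataset(np.arange(12.0).reshape(4, 3))
        assert np.array_equal(ti.impute_soft_svd(d).values, d.values)

    def test_rank1_completion_recovers_cell(self):
        rng = np.random.default_rng(7)
        u = np.abs(rng.standard_normal(20)) + 0.1
        v = np.abs(rng.standard_normal(5)) + 0.1
        M = np.outer(u, v)
        vals = M.copy()
        vals[3, 2] = np.nan
        d = make_dataset(vals)
        c = ti.impute_soft_svd(d, lam=0.0, max_iter=500, tol=1e-9)
        assert abs(c.values[3, 2] - M[3, 2]) / abs(M[3, 2]) < 1e-6

    def test_total_shrinkage_gives_column_means(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((10, 4))
        vals[2, 1] = np.nan
        d = make_dataset(vals)
        c = ti.impute_soft_svd(d, lam=1e12)
        expected = np.nanmean(vals[:, 1])
        assert c.values[2, 1] == pytest.approx(expected, rel=1e-9)

    def test_negative_lam_raises(self, small_mixed):
        with pytest.raises(ValueError):
            ti.impute_soft_svd(small_mixed, lam=-1.0)


class TestRankTwoBenchmark:
    def test_all_methods_beat_mean_at_20_percent(self, suite):
        """One seed of the paired comparison; the full 10-seed sweep runs in
        the acceptance suite."""
        complete = ti.complete_dataset_from(suite["rank2"])
        masked, plan = ti.mask_mcar(complete, 0.2, seed=0)
        rmse_mean = ti.rmse_on_masked(plan, ti.impute_simple(masked, "mean"))
        for spec in (ti.ImputerSpec("knn"), ti.ImputerSpec("soft_svd"),
                     ti.ImputerSpec("chained")):
            rmse = ti.rmse_on_masked(plan, ti.run_imputer(masked, spec, 0))
            assert rmse < rmse_mean, spec.method
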