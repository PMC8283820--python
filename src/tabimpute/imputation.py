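"""Imputation methods for mixed-type tables.

The centrepiece is :func:`impute_boosted`, an iterative column-wise imputer
in the missForest family that replaces the random forest with a gradient
boosted tree learner.  Columns are visited in order of increasing
missingness; each incomplete column is regressed (or classified) on all
other columns' current imputed values, its missing entries are overwritten
with the model's predictions, and sweeps repeat until the convergence delta
first worsens (the previous iterate is then returned) or an iteration cap is
reached.

Baselines share the same :class:`Dataset` contract: column mean/median/mode
(:func:`impute_simple`), partial-distance k-nearest-neighbour
(:func:`impute_knn`), soft-thresholded-SVD matrix completion
(:func:`impute_soft_svd`), and chained-equations imputation with penalised
linear/logistic models (:func:`impute_chained`).  Every imputer is a pure
function of ``(Dataset, spec, seed)`` and never modifies observed cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import learners
from .tabular_io import CATEGORICAL, CONTINUOUS, Dataset

CONTINUE = "continue"
STOP_RETURN_PREVIOUS = "stop_return_previous"
STOP_RETURN_CURRENT = "stop_return_current"

_METHODS = ("mean", "median", "knn", "soft_svd", "chained", "boosted")

_ALLOWED_PARAMS = {
    "mean": set(),
    "median": set(),
    "knn": {"k"},
    "soft_svd": {"lam", "max_iter", "tol", "rank"},
    "chained": {"n_cycles", "alpha"},
    "boosted": {"backend", "n_estimators", "max_iter", "learner_params"},
}


@dataclass
class ImputerSpec:
    """Which imputer to run and with what settings.

    ``params`` is validated against ``method`` before any computation;
    ``init`` selects the initial fill (mean or median) for the iterative
    methods.
    """

    method: str
    params: dict = field(default_factory=dict)
    init: str = "mean"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.init not in ("mean", "median"):
            raise ValueError("init must be 'mean' or 'median'")
        extra = set(self.params) - _ALLOWED_PARAMS[self.method]
        if extra:
            raise ValueError(
                f"parameters {sorted(extra)} are not valid for method {self.method!r}"
            )

    def to_dict(self) -> dict:
        return {"method": self.method, "params": dict(self.params), "init": self.init}


@dataclass
class IterState:
    """Loop state of the iterative boosted imputer.

    ``delta_history`` holds one ``(delta_continuous, delta_categorical)``
    pair per completed sweep; ``order_k`` is the column visit order
    (ascending missing count, ties by original index).
    """

    X_old_imp: np.ndarray | None
    X_new_imp: np.ndarray | None
    order_k: np.ndarray
    iteration: int
    delta_history: list[tuple[float, float]]
    converged_reason: str | None = None


@dataclass
class CompletedDataset:
    """A fully observed table plus provenance of how it was completed.

    Originally observed cells are bit-identical to the input; only cells
    under ``original_mask`` were imputed.
    """

    dataset: Dataset
    spec: ImputerSpec
    original_mask: np.ndarray
    iter_state: IterState | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.dataset.values


def _wrap(d: Dataset, X: np.ndarray, spec: ImputerSpec, state=None, warns=None) -> CompletedDataset:
    X = X.copy()
    obs = ~d.mask
    X[obs] = d.values[obs]  # observed cells pass through untouched
    completed = Dataset(
        X,
        np.zeros_like(d.mask),
        list(d.col_names),
        list(d.col_types),
        [None if lv is None else list(lv) for lv in d.cat_levels],
    )
    return CompletedDataset(completed, spec, d.mask.copy(), state, list(warns or []))


# ---------------------------------------------------------------------------
# simple column statistics
# ---------------------------------------------------------------------------

def _column_fill_value(d: Dataset, j: int, strategy: str) -> float:
    obs = d.values[~d.mask[:, j], j]
    if obs.size == 0:
        raise ValueError(
            f"column {d.col_names[j]!r} has no observed cells; cannot impute"
        )
    if d.col_types[j] == CATEGORICAL:
        counts = np.bincount(obs.astype(int), minlength=len(d.cat_levels[j]))
        return float(np.argmax(counts))  # ties -> lowest level code
    return float(obs.mean() if strategy == "mean" else np.median(obs))


def _initial_fill(d: Dataset, strategy: str) -> np.ndarray:
    X = d.values.copy()
    for j in range(d.n_features):
        col_mask = d.mask[:, j]
        if col_mask.any() or np.isnan(X[:, j]).any():
            X[col_mask, j] = _column_fill_value(d, j, strategy)
    return X


def impute_simple(d: Dataset, strategy: str = "mean") -> CompletedDataset:
    """Column mean (or median) for continuous cells, modal level for
    categorical cells; modal ties resolve to the lowest level code."""
    if strategy not in ("mean", "median"):
        raise ValueError("strategy must be 'mean' or 'median'")
    X = _initial_fill(d, strategy)
    return _wrap(d, X, ImputerSpec(strategy))


# ---------------------------------------------------------------------------
# column ordering and stopping rule
# ---------------------------------------------------------------------------

def sort_columns_by_missingness(mask: np.ndarray) -> np.ndarray:
    """Column indices sorted by ascending missing count, stable in the
    original index on ties."""
    counts = np.asarray(mask, dtype=bool).sum(axis=0)
    return np.argsort(counts, kind="stable")


def _sweep_deltas(
    X_old: np.ndarray, X_new: np.ndarray, cont_cols: np.ndarray, cat_missing: np.ndarray
) -> tuple[float, float]:
    """Convergence deltas between consecutive sweeps.

    Continuous: sum of squared changes over continuous cells divided by the
    squared norm of the new continuous cells.  Categorical: fraction of
    missing categorical cells whose imputed level changed (0 when none).
    """
    cont = X_new[:, cont_cols]
    denom = float(np.sum(cont**2))
    num = float(np.sum((cont - X_old[:, cont_cols]) ** 2))
    delta_cont = num / denom if denom > 0 else 0.0
    n_cat = int(cat_missing.sum())
    if n_cat == 0:
        delta_cat = 0.0
    else:
        changed = (X_new != X_old) & cat_missing
        delta_cat = float(changed.sum()) / n_cat
    return delta_cont, delta_cat


def stopping_criterion(state: IterState, max_iter: int) -> str:
    """Decide after a completed sweep whether to keep iterating.

    Returns ``stop_return_previous`` when either convergence delta strictly
    increased relative to the previous sweep, ``stop_return_current`` at the
    iteration cap, else ``continue``.
    """
    h = state.delta_history
    if not h:
        raise ValueError("stopping_criterion requires at least one completed sweep")
    if len(h) >= 2 and (h[-1][0] > h[-2][0] or h[-1][1] > h[-2][1]):
        return STOP_RETURN_PREVIOUS
    if state.iteration >= max_iter:
        return STOP_RETURN_CURRENT
    return CONTINUE


# ---------------------------------------------------------------------------
# shared column-sweep skeleton (boosted and chained imputers)
# ---------------------------------------------------------------------------

def _check_sweep_preconditions(d: Dataset, min_obs: int = 5) -> None:
    if d.n_features < 2:
        raise ValueError("column-sweep imputation needs at least 2 columns")
    for j in range(d.n_features):
        n_obs = int((~d.mask[:, j]).sum())
        if n_obs == 0:
            raise ValueError(f"column {d.col_names[j]!r} has no observed cells")
        if d.mask[:, j].any() and n_obs < min_obs:
            raise ValueError(
                f"column {d.col_names[j]!r} has only {n_obs} observed rows; "
                f"need at least {min_obs} to fit a model"
            )


def _cat_positions_excluding(d: Dataset, s: int) -> dict[int, int]:
    """Positions (after dropping column s) and level counts of categorical
    predictor columns."""
    out = {}
    pos = 0
    for j in range(d.n_features):
        if j == s:
            continue
        if d.col_types[j] == CATEGORICAL:
            out[pos] = len(d.cat_levels[j])
        pos += 1
    return out


FitPredict = Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray]


def _run_sweeps(
    d: Dataset,
    fit_predict: FitPredict,
    init: str,
    max_sweeps: int,
    use_stopping_rule: bool,
) -> tuple[np.ndarray, IterState, list[str]]:
    """Shared skeleton: initial fill, ordered column visits, repeated sweeps.

    ``fit_predict(X_obs, y_obs, X_mis, s)`` fits the per-column model on the
    observed rows of column ``s`` and returns predictions for the missing
    rows.  With ``use_stopping_rule`` the divergence rule picks the returned
    iterate; otherwise exactly ``max_sweeps`` sweeps run and the final one is
    returned.
    """
    order = sort_columns_by_missingness(d.mask)
    cont_cols = d.continuous_columns
    cat_missing = d.mask & ~np.broadcast_to(cont_cols, d.mask.shape)
    state = IterState(None, None, order, 0, [])
    warns: list[str] = []

    if not d.mask.any():
        return d.values.copy(), state, warns

    X = _initial_fill(d, init)
    targets = [int(s) for s in order if d.mask[:, s].any()]
    while True:
        X_old = X.copy()
        state.iteration += 1
        for s in targets:
            obs = ~d.mask[:, s]
            X_others = np.delete(X, s, axis=1)
            y_obs = X[obs, s]
            try:
                pred = fit_predict(X_others[obs], y_obs, X_others[~obs], s)
            except Exception as exc:  # pragma: no cover - learner failure path
                raise RuntimeError(
                    f"learner failed while imputing column {d.col_names[s]!r}: {exc}"
                ) from exc
            X[~obs, s] = pred
        state.X_old_imp, state.X_new_imp = X_old.copy(), X.copy()
        state.delta_history.append(_sweep_deltas(X_old, X, cont_cols, cat_missing))
        if not use_stopping_rule:
            if state.iteration >= max_sweeps:
                state.converged_reason = "max_iter"
                return X, state, warns
            continue
        decision = stopping_criterion(state, max_sweeps)
        if decision == STOP_RETURN_PREVIOUS:
            state.converged_reason = "delta_increased"
            return X_old, state, warns
        if decision == STOP_RETURN_CURRENT:
            state.converged_reason = "max_iter"
            return X, state, warns


def impute_boosted(
    d: Dataset, spec: ImputerSpec | None = None, seed: int = 0
) -> CompletedDataset:
    """Iterative gradient-boosted-tree imputation.

    After an initial mean/median fill, each incomplete column (in order of
    increasing missingness) is modelled from all other columns with a
    boosted regressor (continuous) or classifier (categorical) and its
    missing cells replaced by predictions.  Sweeps repeat until a
    convergence delta first increases — the previous iterate is returned —
    or ``max_iter`` sweeps complete.  Identical ``(d, spec, seed)`` produce
    identical output.
    """
    spec = spec or ImputerSpec("boosted")
    if spec.method != "boosted":
        raise ValueError(f"spec.method is {spec.method!r}, expected 'boosted'")
    _check_sweep_preconditions(d)
    backend = spec.params.get("backend", "lightgbm")
    n_estimators = spec.params.get("n_estimators", learners.DEFAULT_N_ESTIMATORS)
    max_iter = spec.params.get("max_iter", 10)
    learner_params = spec.params.get("learner_params")

    def fit_predict(X_obs, y_obs, X_mis, s):
        task = "classification" if d.col_types[s] == CATEGORICAL else "regression"
        return learners.boosted_fit_predict(
            X_obs,
            y_obs,
            X_mis,
            task,
            _cat_positions_excluding(d, s),
            seed=seed,
            backend=backend,
            n_estimators=n_estimators,
            learner_params=learner_params,
        )

    X, state, warns = _run_sweeps(d, fit_predict, spec.init, max_iter, True)
    return _wrap(d, X, spec, state, warns)


def impute_chained(
    d: Dataset, n_cycles: int = 10, seed: int = 0, spec: ImputerSpec | None = None
) -> CompletedDataset:
    """Chained-equations imputation with penalised linear/logistic models.

    The same column-sweep skeleton as the boosted imputer, but each column is
    fitted with a ridge regression (continuous target) or an L2-penalised
    logistic regression (categorical target) and exactly ``n_cycles`` sweeps
    run; the final sweep is returned.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression, Ridge

    spec = spec or ImputerSpec("chained", {"n_cycles": n_cycles})
    if spec.method != "chained":
        raise ValueError(f"spec.method is {spec.method!r}, expected 'chained'")
    n_cycles = spec.params.get("n_cycles", n_cycles)
    alpha = spec.params.get("alpha", 1.0)
    _check_sweep_preconditions(d)
    warns: list[str] = []

    def fit_predict(X_obs, y_obs, X_mis, s):
        cat_pos = _cat_positions_excluding(d, s)
        # one-hot expand categorical predictors for the linear models
        def expand(X):
            cols = []
            for pos in range(X.shape[1]):
                if pos in cat_pos:
                    n_levels = cat_pos[pos]
                    onehot = np.equal.outer(X[:, pos], np.arange(n_levels)).astype(float)
                    cols.append(onehot)
                else:
                    cols.append(X[:, pos : pos + 1])
            return np.hstack(cols)

        Xo, Xm = expand(X_obs), expand(X_mis)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                if d.col_types[s] == CATEGORICAL:
                    if len(np.unique(y_obs)) == 1:
                        return np.full(Xm.shape[0], y_obs[0])
                    model = LogisticRegression(C=1.0 / alpha, max_iter=500)
                    model.fit(Xo, y_obs.astype(int))
                    return model.predict(Xm).astype(float)
                model = Ridge(alpha=alpha)
                model.fit(Xo, y_obs)
                return model.predict(Xm)
        except Exception:
            warns.append(
                f"singular fit in column {d.col_names[s]!r}; fell back to column statistic"
            )
            warnings.warn(warns[-1])
            return np.full(Xm.shape[0], _column_fill_value(d, s, "mean"))

    X, state, _ = _run_sweeps(d, fit_predict, spec.init, n_cycles, False)
    return _wrap(d, X, spec, state, warns)


# ---------------------------------------------------------------------------
# k-nearest-neighbour imputation with partial distances
# ---------------------------------------------------------------------------

def _partial_distances(d: Dataset) -> np.ndarray:
    """All-pairs squared distances over mutually observed columns.

    Continuous columns contribute squared differences, categorical columns a
    0/1 mismatch; the sum is rescaled by ``n_features / n_usable`` (the
    partial-distance convention) so rows sharing few columns are not
    artificially close.  Pairs sharing no column get +inf.
    """
    n, m = d.values.shape
    obs = ~d.mask
    cont = d.continuous_columns
    D2 = np.empty((n, n))
    for i in range(n):
        both = obs[i] & obs
        diff = d.values[i] - d.values
        sq = np.where(cont, diff**2, (d.values[i] != d.values).astype(float))
        sq = np.where(both, sq, 0.0)
        usable = both.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            D2[i] = np.where(usable > 0, (m / np.maximum(usable, 1)) * sq.sum(axis=1), np.inf)
    np.fill_diagonal(D2, np.inf)
    return D2


def impute_knn(d: Dataset, k: int = 5) -> CompletedDataset:
    """Fill each missing cell from the ``k`` nearest donor rows.

    Donors must have the target column observed; nearness uses the partial
    Euclidean distance of :func:`_partial_distances` with ties broken by row
    index.  Continuous cells take the donor mean, categorical cells the
    donor modal level (ties to the lowest code).  A row sharing no observed
    column with any donor falls back to the column mean/mode with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if d.n_samples < k + 1:
        raise ValueError(f"need at least k+1={k + 1} rows, have {d.n_samples}")
    for j in range(d.n_features):
        if not (~d.mask[:, j]).any():
            raise ValueError(f"column {d.col_names[j]!r} has no observed cells")
    D2 = _partial_distances(d)
    X = d.values.copy()
    warns: list[str] = []
    obs = ~d.mask
    for i, j in zip(*np.nonzero(d.mask)):
        donors = np.nonzero(obs[:, j] & np.isfinite(D2[i]))[0]
        if donors.size == 0:
            X[i, j] = _column_fill_value(d, j, "mean")
            msg = (
                f"row {i} shares no observed column with any donor for "
                f"column {d.col_names[j]!r}; used column statistic"
            )
            warns.append(msg)
            warnings.warn(msg)
            continue
        nearest = donors[np.argsort(D2[i, donors], kind="stable")][:k]
        vals = d.values[nearest, j]
        if d.col_types[j] == CATEGORICAL:
            counts = np.bincount(vals.astype(int), minlength=len(d.cat_levels[j]))
            X[i, j] = float(np.argmax(counts))
        else:
            X[i, j] = float(vals.mean())
    return _wrap(d, X, ImputerSpec("knn", {"k": k}), None, warns)


# ---------------------------------------------------------------------------
# soft-thresholded SVD matrix completion
# ---------------------------------------------------------------------------

def _one_hot_expand(d: Dataset) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int]]]:
    """Expand categorical columns to indicator blocks.

    Returns the expanded matrix, its mask, and ``(col, start, n_levels)``
    descriptors for reassembling categorical codes by block argmax.
    """
    blocks, mask_blocks, groups = [], [], []
    pos = 0
    for j in range(d.n_features):
        if d.col_types[j] == CONTINUOUS:
            blocks.append(d.values[:, j : j + 1])
            mask_blocks.append(d.mask[:, j : j + 1])
            pos += 1
        else:
            n_levels = len(d.cat_levels[j])
            codes = d.values[:, j]
            onehot = np.zeros((d.n_samples, n_levels))
            seen = ~d.mask[:, j]
            onehot[seen] = np.equal.outer(codes[seen], np.arange(n_levels)).astype(float)
            blocks.append(onehot)
            mask_blocks.append(np.repeat(d.mask[:, j : j + 1], n_levels, axis=1))
            groups.append((j, pos, n_levels))
            pos += n_levels
    return np.hstack(blocks), np.hstack(mask_blocks), groups


def _svd_refill(
    filled: np.ndarray,
    miss: np.ndarray,
    reconstruct: Callable[[np.ndarray], np.ndarray],
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool]:
    """Iterate standardise/reconstruct/refill until missing entries stabilise.

    Column means and standard deviations are re-estimated from the current
    completed matrix each iteration (EM-style), so the standardisation is
    self-consistent at the fixed point; ``reconstruct`` maps the
    standardised matrix to its shrunken/truncated approximation.  Returns
    the completed matrix (original scale), the relative residual of the
    final reconstruction on the observed standardised entries, and a
    convergence flag.
    """
    obs = ~miss
    converged = False
    resid = np.inf
    for _ in range(max_iter):
        mu = filled.mean(axis=0)
        sd = filled.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        C = (filled - mu) / sd
        Z = reconstruct(C)
        old_miss = filled[miss].copy()
        filled[miss] = (Z * sd + mu)[miss]
        resid = np.linalg.norm((Z - C)[obs]) / max(np.linalg.norm(C[obs]), 1e-12)
        change = np.linalg.norm(filled[miss] - old_miss)
        scale = max(np.linalg.norm(old_miss), 1e-12)
        if change / scale < tol:
            converged = True
            break
    return filled, float(resid), converged


def impute_soft_svd(
    d: Dataset,
    lam: float | None = None,
    max_iter: int = 1000,
    tol: float = 1e-5,
    rank: int | None = None,
) -> CompletedDataset:
    """Matrix completion by iterative soft-thresholded SVD.

    Columns are centred and scaled by observed statistics (categorical
    columns enter as one-hot indicators and are reassembled by block
    argmax); missing entries start at the column mean.  Each iteration
    re-standardises the current completed matrix, takes an SVD, shrinks the
    singular values by ``lam``, reconstructs, and refills the missing
    entries, stopping when their relative change drops below ``tol``.
    Re-estimating the column statistics from the completed matrix (rather
    than freezing the observed-only statistics) makes the standardisation
    self-consistent at convergence.

    ``lam=None`` picks the conventional default, 1/50 of the top singular
    value of the initial fill.  ``lam=0`` requests no shrinkage, for which a
    full SVD would be a no-op; it is therefore run as adaptive-rank hard
    imputation: a truncated-SVD iteration whose rank grows (from 1, or fixed
    at ``rank`` when given) until the observed entries are reproduced, which
    converges to the exact low-rank completion on low-rank data.
    """
    if lam is not None and lam < 0:
        raise ValueError("lam must be >= 0")
    spec = ImputerSpec(
        "soft_svd", {"lam": lam, "max_iter": max_iter, "tol": tol, "rank": rank}
    )
    if not d.mask.any():
        return _wrap(d, d.values.copy(), spec)

    Z, miss, groups = _one_hot_expand(d)
    obs = ~miss
    for j in range(Z.shape[1]):
        if not obs[:, j].any():
            raise ValueError("a column has no observed cells; cannot complete")
    filled = Z.copy()
    col_means = np.array([Z[obs[:, j], j].mean() for j in range(Z.shape[1])])
    filled[miss] = np.broadcast_to(col_means, Z.shape)[miss]

    warns: list[str] = []
    if lam is None:
        mu0, sd0 = filled.mean(axis=0), filled.std(axis=0)
        sd0 = np.where(sd0 > 0, sd0, 1.0)
        lam = float(np.linalg.svd((filled - mu0) / sd0, compute_uv=False)[0]) / 50.0

    if lam > 0:

        def reconstruct(F):
            U, s, Vt = np.linalg.svd(F, full_matrices=False)
            return (U * np.maximum(s - lam, 0.0)) @ Vt

        filled, _, converged = _svd_refill(filled, miss, reconstruct, max_iter, tol)
        if not converged:
            warns.append(f"soft-SVD did not converge within {max_iter} iterations")
            warnings.warn(warns[-1])
    else:
        max_rank = min(filled.shape) - 1 if min(filled.shape) > 1 else 1
        ranks = [min(rank, min(filled.shape))] if rank else range(1, max_rank + 1)
        for r in ranks:

            def reconstruct(F, r=r):
                U, s, Vt = np.linalg.svd(F, full_matrices=False)
                return (U[:, :r] * s[:r]) @ Vt[:r]

            filled, resid, _ = _svd_refill(filled, miss, reconstruct, max_iter, tol)
            if resid <= 1e-9:
                break

    full = filled
    X = d.values.copy()
    pos = 0
    group_start = {j: (start, n) for j, start, n in groups}
    for j in range(d.n_features):
        if d.col_types[j] == CONTINUOUS:
            col_miss = d.mask[:, j]
            X[col_miss, j] = full[col_miss, pos]
            pos += 1
        else:
            start, n_levels = group_start[j]
            col_miss = d.mask[:, j]
            X[col_miss, j] = np.argmax(full[col_miss, start : start + n_levels], axis=1)
            pos += n_levels
    return _wrap(d, X, spec, None, warns)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def run_imputer(d: Dataset, spec: ImputerSpec, seed: int = 0) -> CompletedDataset:
    """Run the imputer named by ``spec`` on ``d``."""
    if spec.method in ("mean", "median"):
        return impute_simple(d, spec.method)
    if spec.method == "knn":
        return impute_knn(d, spec.params.get("k", 5))
    if spec.method == "soft_svd":
        return impute_soft_svd(
            d,
            spec.params.get("lam"),
            spec.params.get("max_iter", 1000),
            spec.params.get("tol", 1e-5),
            spec.params.get("rank"),
        )
    if spec.method == "chained":
        return impute_chained(d, spec.params.get("n_cycles", 10), seed, spec=spec)
    return impute_boosted(d, spec, seed)
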