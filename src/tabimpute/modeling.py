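"""Feature ranking and response-excluded cross-validated prediction.

When imputation feeds a downstream predictor, the response column must be
excluded from the imputation step (otherwise information leaks from the
response into the imputed predictors and cross-validated performance is
optimistic).  :func:`exclude_response` performs that split;
:func:`rank_features` scores features by penalised linear/logistic
coefficients or boosted split gain; :func:`cv_predict` produces pooled
out-of-fold scores under a seeded stratified k-fold, and
:func:`roc_pr_metrics` turns scores into ROC/PR curves and a trapezoidal
AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imputation import CompletedDataset
from .tabular_io import CATEGORICAL, Dataset

PREDICTORS = ("penalized_linear", "random_forest", "boosted_trees", "knn")
RANKERS = ("boosted_importance", "lasso", "ridge", "elastic_net")


@dataclass
class FeatureRanking:
    method: str
    feature_names: list[str]
    scores: np.ndarray  # per-feature, >= 0
    order: np.ndarray  # features sorted by descending score, ties by index
    top_n: int

    @property
    def top_features(self) -> list[str]:
        return [self.feature_names[j] for j in self.order[: self.top_n]]


@dataclass
class PredictionReport:
    scores: np.ndarray  # per-sample out-of-fold predicted score
    folds: np.ndarray  # test-fold assignment per sample
    auc: float
    roc_points: np.ndarray  # (fpr, tpr) rows
    pr_points: np.ndarray  # (recall, precision) rows
    method: str
    params: dict = field(default_factory=dict)
    n_folds: int = 5
    seed: int = 0

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "params": self.params,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "auc": self.auc,
            "roc_points": self.roc_points.tolist(),
            "pr_points": self.pr_points.tolist(),
        }


def exclude_response(d: Dataset, response_name: str) -> tuple[Dataset, np.ndarray]:
    """Split off the response column so imputation never sees it.

    The response must be fully observed; missing entries are an error
    listing the affected row indices.  Returns the predictor table and the
    response vector (level codes for a categorical response).
    """
    j = d.column_index(response_name)
    missing_rows = np.flatnonzero(d.mask[:, j])
    if missing_rows.size:
        raise ValueError(
            f"response {response_name!r} has missing values at rows "
            f"{missing_rows.tolist()}"
        )
    predictors = d.select_columns([c for c in range(d.n_features) if c != j])
    return predictors, d.values[:, j].copy()


def attach_response(
    predictors: Dataset,
    response: np.ndarray,
    name: str,
    col_type: str = CATEGORICAL,
    levels: list[str] | None = None,
    position: int | None = None,
) -> Dataset:
    """Inverse of :func:`exclude_response`: re-insert the response column."""
    position = predictors.n_features if position is None else position
    values = np.insert(predictors.values, position, response, axis=1)
    mask = np.insert(predictors.mask, position, False, axis=1)
    names = list(predictors.col_names)
    names.insert(position, name)
    types = list(predictors.col_types)
    types.insert(position, col_type)
    cat = [None if lv is None else list(lv) for lv in predictors.cat_levels]
    cat.insert(position, levels)
    return Dataset(values, mask, names, types, cat)


def _feature_matrix(c) -> tuple[np.ndarray, list[str]]:
    if isinstance(c, CompletedDataset):
        return c.dataset.values, list(c.dataset.col_names)
    if isinstance(c, Dataset):
        if c.mask.any():
            raise ValueError("features still have missing cells; impute first")
        return c.values, list(c.col_names)
    X = np.asarray(c, dtype=float)
    return X, [f"f{j}" for j in range(X.shape[1])]


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    return (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


def _is_binary(y: np.ndarray) -> bool:
    return np.unique(y).size == 2


def rank_features(
    c,
    response: np.ndarray,
    method: str = "lasso",
    top_n: int | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Score features by importance for predicting ``response``.

    Penalised methods standardise the features and use the absolute
    coefficient at a penalty chosen by internal 5-fold cross-validation
    with the one-standard-error rule (the strongest penalty whose CV loss
    is within one standard error of the best), logistic link for a binary
    response and linear otherwise; ``boosted_importance`` uses total
    split-gain importance from a 100-tree boosted model.  Deterministic in
    ``seed``.
    """
    if method not in RANKERS:
        raise ValueError(f"unknown ranking method {method!r}")
    X, names = _feature_matrix(c)
    y = np.asarray(response, dtype=float)
    binary = _is_binary(y)
    Xs = _standardize(X)

    if method == "boosted_importance":
        import lightgbm as lgb

        cls = lgb.LGBMClassifier if binary else lgb.LGBMRegressor
        model = cls(n_estimators=100, random_state=seed, n_jobs=1,
                    verbosity=-1, importance_type="gain")
        model.fit(Xs, y.astype(int) if binary else y)
        scores = np.asarray(model.feature_importances_, dtype=float)
    else:
        scores = _penalized_coefficients(Xs, y, method, binary, seed)

    order = np.argsort(-scores, kind="stable")
    n_features = X.shape[1]
    if top_n is None:
        top_n = n_features
    elif top_n > n_features:
        warnings.warn(f"top_n={top_n} clipped to the {n_features} available features")
        top_n = n_features
    return FeatureRanking(method, names, scores, order, top_n)


def _logistic(method: str, C: float, seed: int):
    from sklearn.linear_model import LogisticRegression

    if method == "lasso":
        return LogisticRegression(l1_ratio=1, C=C, solver="liblinear",
                                  max_iter=2000, random_state=seed)
    if method == "ridge":
        return LogisticRegression(l1_ratio=0, C=C, solver="lbfgs", max_iter=2000)
    return LogisticRegression(l1_ratio=0.5, C=C, solver="saga", max_iter=3000,
                              random_state=seed)


def _linear(method: str, alpha: float, seed: int):
    from sklearn.linear_model import ElasticNet, Lasso, Ridge

    if method == "lasso":
        return Lasso(alpha=alpha, max_iter=5000, random_state=seed)
    if method == "ridge":
        return Ridge(alpha=alpha)
    return ElasticNet(alpha=alpha, l1_ratio=0.5, max_iter=5000, random_state=seed)


def _penalized_coefficients(Xs, y, method, binary, seed) -> np.ndarray:
    """Coefficients at the 1-SE penalty of an internal 5-fold CV grid.

    Penalties are scanned strongest-first; among those whose mean CV loss is
    within one standard error of the best, the strongest wins (the glmnet
    ``lambda.1se`` convention), which keeps null data fully shrunk.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.metrics import log_loss, mean_squared_error
    from sklearn.model_selection import KFold, StratifiedKFold

    if binary:
        grid = np.logspace(-4, 2, 13)  # C: small = strong penalty
        make = lambda c: _logistic(method, c, seed)
        splitter = StratifiedKFold(5, shuffle=True, random_state=seed)
        yy = y.astype(int)
        loss = lambda model, X, t: log_loss(
            t, model.predict_proba(X)[:, 1], labels=[0, 1]
        )
    else:
        grid = np.logspace(2, -4, 13)  # alpha descending = strongest first
        make = lambda a: _linear(method, a, seed)
        splitter = KFold(5, shuffle=True, random_state=seed)
        yy = y
        loss = lambda model, X, t: mean_squared_error(t, model.predict(X))

    folds = list(splitter.split(Xs, yy))
    cv_losses = np.empty((grid.size, len(folds)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for gi, g in enumerate(grid):
            for fi, (train, test) in enumerate(folds):
                model = make(g)
                model.fit(Xs[train], yy[train])
                cv_losses[gi, fi] = loss(model, Xs[test], yy[test])
        means = cv_losses.mean(axis=1)
        ses = cv_losses.std(axis=1, ddof=1) / np.sqrt(len(folds))
        best = int(np.argmin(means))
        threshold = means[best] + ses[best]
        chosen = next(gi for gi in range(grid.size) if means[gi] <= threshold)
        model = make(grid[chosen])
        model.fit(Xs, yy)
    coef = model.coef_[0] if binary else model.coef_
    return np.abs(np.asarray(coef, dtype=float))


class _TunedL1Logistic:
    """L1-penalised logistic regression with C chosen by internal 5-fold CV
    (lowest mean log-loss)."""

    def __init__(self, seed: int, Cs=None):
        self.seed = seed
        self.Cs = np.logspace(-4, 2, 10) if Cs is None else np.asarray(Cs)
        self.model_ = None

    def fit(self, X, y):
        from sklearn.metrics import log_loss
        from sklearn.model_selection import StratifiedKFold

        folds = list(
            StratifiedKFold(5, shuffle=True, random_state=self.seed).split(X, y)
        )
        means = []
        for C in self.Cs:
            losses = []
            for train, test in folds:
                m = _logistic("lasso", C, self.seed)
                m.fit(X[train], y[train])
                losses.append(
                    log_loss(y[test], m.predict_proba(X[test])[:, 1], labels=[0, 1])
                )
            means.append(np.mean(losses))
        self.C_ = float(self.Cs[int(np.argmin(means))])
        self.model_ = _logistic("lasso", self.C_, self.seed)
        self.model_.fit(X, y)
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


def _make_predictor(method: str, seed: int):
    if method == "penalized_linear":
        return _TunedL1Logistic(seed)
    if method == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if method == "boosted_trees":
        import lightgbm as lgb

        return lgb.LGBMClassifier(
            n_estimators=100, random_state=seed, n_jobs=1, verbosity=-1
        )
    if method == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown prediction method {method!r}")


def cv_predict(
    features,
    response: np.ndarray,
    method: str = "penalized_linear",
    n_folds: int = 5,
    seed: int = 0,
) -> PredictionReport:
    """Stratified k-fold out-of-fold prediction of a binary response.

    Each sample is scored exactly once, by the model trained on the other
    folds; scores are class-1 probabilities.  Both classes must have at
    least ``n_folds`` members so every training fold contains both classes.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.model_selection import StratifiedKFold

    X, _ = _feature_matrix(features)
    y = np.asarray(response, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("response must be binary")
    if counts.min() < n_folds:
        raise ValueError(
            f"a class has only {counts.min()} members; use fewer than "
            f"{n_folds} folds"
        )
    Xs = _standardize(X)
    y01 = (y == classes[1]).astype(int)
    skf = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
    scores = np.full(y.shape[0], np.nan)
    folds = np.full(y.shape[0], -1, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for fold, (train, test) in enumerate(skf.split(Xs, y01)):
            model = _make_predictor(method, seed)
            model.fit(Xs[train], y01[train])
            scores[test] = model.predict_proba(Xs[test])[:, 1]
            folds[test] = fold
    auc, roc, pr = roc_pr_metrics(scores, y01)
    return PredictionReport(
        scores=scores,
        folds=folds,
        auc=auc,
        roc_points=roc,
        pr_points=pr,
        method=method,
        params={},
        n_folds=n_folds,
        seed=seed,
    )


def roc_pr_metrics(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC and precision-recall curves with trapezoidal AUC.

    One ROC vertex per unique score (ties grouped); the ROC starts at
    (0, 0) and ends at (1, 1), and the trapezoidal area equals the
    Mann-Whitney probability that a random positive outscores a random
    negative with ties counted 1/2.
    """
    from sklearn.metrics import auc as _trapezoid_auc
    from sklearn.metrics import precision_recall_curve, roc_curve

    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if np.unique(truth).size != 2:
        raise ValueError("truth must contain both classes")
    fpr, tpr, _ = roc_curve(truth, scores, drop_intermediate=False)
    auc = float(_trapezoid_auc(fpr, tpr))
    precision, recall, _ = precision_recall_curve(truth, scores)
    roc_points = np.column_stack([fpr, tpr])
    pr_points = np.column_stack([recall[::-1], precision[::-1]])
    return auc, roc_points, pr_points
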