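"""Pluggable gradient-boosted learner backends for per-column imputation.

The iterative imputer only needs a fit/predict pair per column; both the
LightGBM and XGBoost flavours satisfy the same contract, so the choice of
boosting library is configuration, not code.  Categorical predictors are
passed as pandas ``category`` columns so the tree library can split on
levels natively instead of an arbitrary integer ordering.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

BACKENDS = ("lightgbm", "xgboost")

#: learner defaults: 100 trees, library defaults otherwise
DEFAULT_N_ESTIMATORS = 100


def _frame_with_categories(
    X: np.ndarray, cat_levels_by_pos: Mapping[int, int]
) -> pd.DataFrame:
    df = pd.DataFrame(X)
    for pos, n_levels in cat_levels_by_pos.items():
        df[pos] = pd.Categorical(df[pos].astype("Int64"), categories=range(n_levels))
    return df


def boosted_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_pred: np.ndarray,
    task: str,
    cat_levels_by_pos: Mapping[int, int],
    seed: int,
    backend: str = "lightgbm",
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    learner_params: Mapping | None = None,
) -> np.ndarray:
    """Fit one boosted model and predict.

    ``task`` is ``"regression"`` (continuous target) or ``"classification"``
    (categorical target, ``y_train`` holding level codes).  Deterministic in
    its inputs: single-threaded, seeded.
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown boosted backend {backend!r}")
    params = dict(learner_params or {})
    if task == "classification" and len(np.unique(y_train)) == 1:
        # degenerate target: every observed cell shares one level
        return np.full(X_pred.shape[0], y_train[0], dtype=float)

    Xtr = _frame_with_categories(X_train, cat_levels_by_pos)
    Xpr = _frame_with_categories(X_pred, cat_levels_by_pos)

    if backend == "lightgbm":
        import lightgbm as lgb

        common = dict(
            n_estimators=n_estimators,
            random_state=seed,
            n_jobs=1,
            verbosity=-1,
            **params,
        )
        if task == "regression":
            model = lgb.LGBMRegressor(**common)
            model.fit(Xtr, y_train)
            return np.asarray(model.predict(Xpr), dtype=float)
        model = lgb.LGBMClassifier(**common)
        model.fit(Xtr, y_train.astype(int))
        return np.asarray(model.predict(Xpr), dtype=float)

    import xgboost as xgb

    common = dict(
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        enable_categorical=True,
        verbosity=0,
        **params,
    )
    if task == "regression":
        model = xgb.XGBRegressor(**common)
        model.fit(Xtr, y_train)
        return np.asarray(model.predict(Xpr), dtype=float)
    codes = y_train.astype(int)
    # XGBoost wants contiguous class ids starting at 0
    uniq = np.unique(codes)
    remap = {c: i for i, c in enumerate(uniq)}
    model = xgb.XGBClassifier(**common)
    model.fit(Xtr, np.vectorize(remap.get)(codes))
    pred = np.asarray(model.predict(Xpr), dtype=int)
    return uniq[pred].astype(float)
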