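"""MCAR masking, imputation-error metrics, and the benchmark harness.

The evaluation design is paired: within one (rate, replicate) cell of the
benchmark grid, every imputation method sees the *same* deliberately hidden
cells, so method comparisons are paired comparisons.  Replicate seeds are
derived from ``(base_seed, rate_index, replicate_index)`` so adding a method
or a rate never changes previously drawn masks.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputation import CompletedDataset, ImputerSpec, run_imputer
from .tabular_io import CATEGORICAL, CONTINUOUS, Dataset


@dataclass
class MaskPlan:
    """The deliberately hidden cells of one masking draw.

    ``hidden_cells`` are unique 0-based ``(row, col)`` positions that were
    observed before masking; ``true_values`` are the pre-masking cell values
    at those positions.  ``col_mean``/``col_sd`` record the pre-masking
    observed per-column statistics used by z-scored error metrics.
    """

    hidden_cells: np.ndarray  # (n_hidden, 2) int
    true_values: np.ndarray
    rate: float
    seed: int
    col_mean: np.ndarray | None = None
    col_sd: np.ndarray | None = None


def mask_mcar(d: Dataset, rate: float, seed: int) -> tuple[Dataset, MaskPlan]:
    """Hide ``floor(rate * n_eligible)`` currently observed cells uniformly
    at random (without replacement).  Deterministic in ``(d, rate, seed)``.

    Raises if the draw would leave some column with no observed cell.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("rate must lie in (0, 1)")
    eligible = np.flatnonzero(~d.mask)
    if eligible.size == 0:
        raise ValueError("no observed cells to mask")
    n_hide = int(math.floor(rate * eligible.size))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_hide, replace=False)
    rows, cols = np.unravel_index(np.sort(chosen), d.mask.shape)

    new_mask = d.mask.copy()
    new_mask[rows, cols] = True
    remaining = (~new_mask).sum(axis=0)
    if (remaining == 0).any():
        bad = d.col_names[int(np.argmin(remaining))]
        raise ValueError(
            f"masking at rate {rate} would leave column {bad!r} with no "
            "observed cells; use a lower rate"
        )
    obs = ~d.mask
    col_mean = np.array(
        [d.values[obs[:, j], j].mean() for j in range(d.n_features)]
    )
    col_sd = np.array([d.values[obs[:, j], j].std() for j in range(d.n_features)])
    plan = MaskPlan(
        hidden_cells=np.column_stack([rows, cols]),
        true_values=d.values[rows, cols].copy(),
        rate=rate,
        seed=seed,
        col_mean=col_mean,
        col_sd=col_sd,
    )
    masked_values = d.values.copy()
    masked_values[rows, cols] = np.nan
    masked = Dataset(
        masked_values,
        new_mask,
        list(d.col_names),
        list(d.col_types),
        [None if lv is None else list(lv) for lv in d.cat_levels],
    )
    return masked, plan


def unmask(masked: Dataset, plan: MaskPlan) -> Dataset:
    """Restore the hidden cells of ``plan``, inverting :func:`mask_mcar`."""
    values = masked.values.copy()
    mask = masked.mask.copy()
    rows, cols = plan.hidden_cells[:, 0], plan.hidden_cells[:, 1]
    values[rows, cols] = plan.true_values
    mask[rows, cols] = False
    return Dataset(
        values,
        mask,
        list(masked.col_names),
        list(masked.col_types),
        [None if lv is None else list(lv) for lv in masked.cat_levels],
    )


def _split_hidden(plan: MaskPlan, completed: CompletedDataset):
    types = completed.dataset.col_types
    cols = plan.hidden_cells[:, 1]
    is_cont = np.array([types[j] == CONTINUOUS for j in cols])
    imputed = completed.values[plan.hidden_cells[:, 0], cols]
    return is_cont, imputed


def rmse_on_masked(
    plan: MaskPlan, completed: CompletedDataset, scale: str = "raw"
) -> float:
    """Root mean squared error over the hidden *continuous* cells.

    With ``scale="zscore"`` both true and imputed values are standardised by
    the pre-masking observed per-column mean/sd before differencing, which
    makes errors comparable across columns with different units.
    """
    if scale not in ("raw", "zscore"):
        raise ValueError("scale must be 'raw' or 'zscore'")
    is_cont, imputed = _split_hidden(plan, completed)
    if not is_cont.any():
        raise ValueError("no hidden continuous cells; use pfc_on_masked instead")
    truth = plan.true_values[is_cont]
    est = imputed[is_cont]
    if scale == "zscore":
        cols = plan.hidden_cells[is_cont, 1]
        mu, sd = plan.col_mean[cols], np.where(plan.col_sd[cols] > 0, plan.col_sd[cols], 1.0)
        truth = (truth - mu) / sd
        est = (est - mu) / sd
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def pfc_on_masked(plan: MaskPlan, completed: CompletedDataset) -> float:
    """Proportion of hidden categorical cells imputed with the wrong level."""
    is_cont, imputed = _split_hidden(plan, completed)
    if is_cont.all():
        raise ValueError("no hidden categorical cells")
    truth = plan.true_values[~is_cont]
    return float(np.mean(imputed[~is_cont] != truth))


def derive_seed(base_seed: int, *indices: int) -> int:
    """Stable sub-seed derivation; adding methods or rates never changes
    previously derived seeds."""
    ss = np.random.SeedSequence([int(base_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class EvaluationReport:
    """Tidy per-run benchmark results plus aggregation helpers."""

    per_run: pd.DataFrame  # method, rate, replicate, metric, value, seconds, seed, error
    rates: list[float]
    methods: list[str]
    n_replicates: int
    base_seed: int

    def aggregate(self) -> pd.DataFrame:
        ok = self.per_run[self.per_run["error"].isna()]
        agg = (
            ok.groupby(["method", "rate", "metric"])["value"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        return agg

    def to_csv(self, path) -> None:
        self.per_run.to_csv(path, index=False)

    def to_json_dict(self) -> dict:
        agg = self.aggregate()
        return {
            "rates": self.rates,
            "methods": self.methods,
            "n_replicates": self.n_replicates,
            "base_seed": self.base_seed,
            "grid": agg.to_dict(orient="records"),
        }


DEFAULT_RATES = tuple(round(0.1 * i, 1) for i in range(1, 10))


def _normalize_methods(methods) -> list[tuple[str, object]]:
    """Accept ImputerSpecs, (label, spec) pairs, or (label, callable) pairs
    where the callable maps (masked Dataset, seed) -> CompletedDataset."""
    out = []
    for entry in methods:
        if isinstance(entry, ImputerSpec):
            out.append((entry.method, entry))
        else:
            label, spec = entry
            out.append((str(label), spec))
    return out


def _invoke(spec, masked: Dataset, seed: int) -> CompletedDataset:
    if callable(spec) and not isinstance(spec, ImputerSpec):
        return spec(masked, seed)
    return run_imputer(masked, spec, seed)


def benchmark_grid(
    d: Dataset,
    methods,
    rates=DEFAULT_RATES,
    n_replicates: int = 10,
    base_seed: int = 0,
) -> EvaluationReport:
    """Mask/impute/score every method on a shared grid of MCAR draws.

    ``d`` must be complete.  For each (rate, replicate) one mask is drawn
    with a derived seed and shared by all methods; RMSE (continuous cells)
    and PFC (categorical cells) are recorded per run, and per-run wall-clock
    seconds are logged for information only.  A failing run is recorded in
    the grid without aborting the sweep.
    """
    if d.mask.any():
        raise ValueError("benchmark_grid needs a complete dataset")
    pairs = _normalize_methods(methods)
    rows = []
    has_cont = d.continuous_columns.any()
    has_cat = d.categorical_columns.any()
    for rate_idx, rate in enumerate(rates):
        for rep in range(n_replicates):
            seed = derive_seed(base_seed, rate_idx, rep)
            masked, plan = mask_mcar(d, rate, seed)
            for label, spec in pairs:
                t0 = time.perf_counter()
                try:
                    completed = _invoke(spec, masked, seed)
                    seconds = time.perf_counter() - t0
                    metrics = {}
                    if has_cont:
                        metrics["rmse"] = rmse_on_masked(plan, completed)
                    if has_cat:
                        metrics["pfc"] = pfc_on_masked(plan, completed)
                    for metric, value in metrics.items():
                        rows.append(
                            dict(
                                method=label,
                                rate=rate,
                                replicate=rep,
                                metric=metric,
                                value=value,
                                seconds=seconds,
                                seed=seed,
                                error=None,
                            )
                        )
                except Exception as exc:
                    rows.append(
                        dict(
                            method=label,
                            rate=rate,
                            replicate=rep,
                            metric="rmse" if has_cont else "pfc",
                            value=np.nan,
                            seconds=time.perf_counter() - t0,
                            seed=seed,
                            error=str(exc),
                        )
                    )
    per_run = pd.DataFrame(rows)
    return EvaluationReport(
        per_run=per_run,
        rates=[float(r) for r in rates],
        methods=[label for label, _ in pairs],
        n_replicates=n_replicates,
        base_seed=base_seed,
    )


@dataclass
class HoldoutStat:
    """Per-column recovery statistic from the holdout diagnostic."""

    name: str
    type: str
    n_holdout: int
    statistic: float
    kind: str  # pearson_r | accuracy | mean_abs_error
    flagged: bool


def holdout_correlation_diagnostic(
    d: Dataset, spec: ImputerSpec, fraction: float = 0.05, seed: int = 0
) -> list[HoldoutStat]:
    """Hide a small fraction of each column's observed cells, impute once,
    and report per-column recovery.

    Continuous columns with >= 3 holdout cells report the Pearson
    correlation between imputed and true values; smaller holdouts report
    mean absolute error and are flagged, as are constant-truth columns
    (undefined correlation).  Categorical columns report accuracy.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    holdouts: dict[int, np.ndarray] = {}
    values = d.values.copy()
    mask = d.mask.copy()
    for j in range(d.n_features):
        obs_rows = np.flatnonzero(~d.mask[:, j])
        if obs_rows.size == 0:
            continue
        n_hold = max(1, int(math.floor(fraction * obs_rows.size)))
        rows = np.sort(rng.choice(obs_rows, size=n_hold, replace=False))
        holdouts[j] = rows
        values[rows, j] = np.nan
        mask[rows, j] = True
    masked = Dataset(
        values, mask, list(d.col_names), list(d.col_types),
        [None if lv is None else list(lv) for lv in d.cat_levels],
    )
    completed = _invoke(spec, masked, seed)

    stats = []
    for j, rows in holdouts.items():
        truth = d.values[rows, j]
        est = completed.values[rows, j]
        if d.col_types[j] == CATEGORICAL:
            stats.append(
                HoldoutStat(
                    d.col_names[j], CATEGORICAL, rows.size,
                    float(np.mean(est == truth)), "accuracy", rows.size < 3,
                )
            )
        elif rows.size < 3:
            stats.append(
                HoldoutStat(
                    d.col_names[j], CONTINUOUS, rows.size,
                    float(np.mean(np.abs(est - truth))), "mean_abs_error", True,
                )
            )
        elif np.std(truth) == 0:
            stats.append(
                HoldoutStat(d.col_names[j], CONTINUOUS, rows.size, float("nan"),
                            "pearson_r", True)
            )
        else:
            r = float(np.corrcoef(truth, est)[0, 1]) if np.std(est) > 0 else float("nan")
            stats.append(
                HoldoutStat(d.col_names[j], CONTINUOUS, rows.size, r, "pearson_r",
                            not np.isfinite(r))
            )
    return stats
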