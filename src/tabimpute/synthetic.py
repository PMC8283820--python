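"""Deterministic generators of mixed-type tables with known ground truth.

Every generated table starts from a low-rank-plus-noise continuous block
``L @ R.T + noise`` — the correlation structure that makes imputation
informative in wide biomedical tables — onto which planted structure
(exact linear column relations, Gaussian cluster shifts, an informative
binary response) and per-column MCAR missingness are layered.  The RNG is
split into named substreams (base draw, noise, planted structure, masking)
so adding planted structure never perturbs the base draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tabular_io import CATEGORICAL, CONTINUOUS, Dataset


@dataclass
class PlantedStructure:
    """Optional ground-truth structure layered onto the base draw.

    linear_pairs
        ``(src, dst, slope)`` triples: column ``dst`` is overwritten with
        ``slope * column[src]`` plus Gaussian noise of sd ``linear_noise_sd``.
    cluster_centers
        ``(k, n_continuous)`` array of cluster mean shifts; samples are
        assigned to clusters in equal blocks and shifted accordingly.
    response_idx / response_effects
        Informative predictor indices and their log-odds effect sizes (per
        standardised predictor); a binary response is drawn from the induced
        logistic model.  An empty index list yields a pure-noise response.
    """

    linear_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    linear_noise_sd: float = 0.05
    cluster_centers: np.ndarray | None = None
    response_idx: list[int] | None = None
    response_effects: list[float] | None = None


@dataclass
class FixtureSpec:
    """Recipe for one synthetic table."""

    n_samples: int = 100
    n_continuous: int = 5
    n_categorical: int = 0
    latent_rank: int = 2
    noise_sd: float = 0.1
    n_levels: int = 3
    planted: PlantedStructure | None = None
    missing_rates: Sequence[float] | None = None  # per column, in [0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_continuous <= 0 or self.n_categorical < 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        m = self.n_continuous + self.n_categorical
        if self.latent_rank > min(self.n_samples, m):
            raise ValueError("latent_rank exceeds min(n_samples, n_features)")
        if self.missing_rates is not None:
            rates = list(self.missing_rates)
            if len(rates) != m:
                raise ValueError("missing_rates must give one rate per column")
            if any(not 0.0 <= r < 1.0 for r in rates):
                raise ValueError("missing rates must lie in [0, 1)")


@dataclass
class Fixture:
    """A generated dataset plus its complete ground truth."""

    dataset: Dataset
    truth: np.ndarray  # complete pre-masking cell values (codes for categorical)
    labels: dict[str, np.ndarray]
    spec: FixtureSpec

    @property
    def response(self) -> np.ndarray | None:
        return self.labels.get("response")

    @property
    def cluster_labels(self) -> np.ndarray | None:
        return self.labels.get("cluster")


def _quantile_codes(scores: np.ndarray, n_levels: int) -> np.ndarray:
    """Discretise a score vector into quantile bins (codes 0..n_levels-1)."""
    qs = np.quantile(scores, np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.searchsorted(qs, scores, side="right").astype(float)


def generate(spec: FixtureSpec) -> Fixture:
    """Materialise a :class:`Fixture` from a :class:`FixtureSpec`.

    Fully deterministic in ``spec.seed``.
    """
    n, m = spec.n_samples, spec.n_continuous + spec.n_categorical
    ss = np.random.SeedSequence(spec.seed)
    s_base, s_noise, s_plant, s_mask = ss.spawn(4)
    rng_base = np.random.default_rng(s_base)
    rng_noise = np.random.default_rng(s_noise)
    rng_plant = np.random.default_rng(s_plant)
    rng_mask = np.random.default_rng(s_mask)

    L = rng_base.standard_normal((n, spec.latent_rank))
    R = rng_base.standard_normal((m, spec.latent_rank))
    X = L @ R.T
    if spec.noise_sd > 0:
        X = X + spec.noise_sd * rng_noise.standard_normal((n, m))

    labels: dict[str, np.ndarray] = {}
    planted = spec.planted
    if planted is not None:
        for src, dst, slope in planted.linear_pairs:
            noise = (
                planted.linear_noise_sd * rng_plant.standard_normal(n)
                if planted.linear_noise_sd > 0
                else 0.0
            )
            X[:, dst] = slope * X[:, src] + noise
        if planted.cluster_centers is not None:
            centers = np.asarray(planted.cluster_centers, dtype=float)
            k = centers.shape[0]
            assignment = np.repeat(np.arange(k), math.ceil(n / k))[:n]
            X[:, : centers.shape[1]] += centers[assignment]
            labels["cluster"] = assignment
        if planted.response_idx is not None:
            idx = list(planted.response_idx)
            effects = np.asarray(planted.response_effects or [], dtype=float)
            if len(idx) != len(effects):
                raise ValueError("response_idx and response_effects lengths differ")
            if idx:
                Z = X[:, idx]
                Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
                lp = Z @ effects
            else:
                lp = np.zeros(n)
            p = 1.0 / (1.0 + np.exp(-lp))
            labels["response"] = (rng_plant.uniform(size=n) < p).astype(float)

    # categorical columns: discretise the continuous draw into quantile bins
    col_types = [CONTINUOUS] * spec.n_continuous + [CATEGORICAL] * spec.n_categorical
    cat_levels: list[list[str] | None] = [None] * spec.n_continuous
    values = X.copy()
    for j in range(spec.n_continuous, m):
        values[:, j] = _quantile_codes(X[:, j], spec.n_levels)
        cat_levels.append([f"level{c}" for c in range(spec.n_levels)])

    truth = values.copy()
    mask = np.zeros((n, m), dtype=bool)
    if spec.missing_rates is not None:
        for j, rate in enumerate(spec.missing_rates):
            n_hide = int(math.floor(rate * n))
            if n_hide:
                rows = rng_mask.choice(n, size=n_hide, replace=False)
                mask[rows, j] = True
    masked_values = values.copy()
    masked_values[mask] = np.nan

    names = [f"x{j}" for j in range(spec.n_continuous)] + [
        f"c{j}" for j in range(spec.n_categorical)
    ]
    dataset = Dataset(masked_values, mask, names, col_types, cat_levels)
    return Fixture(dataset=dataset, truth=truth, labels=labels, spec=spec)


def complete_dataset_from(fixture: Fixture) -> Dataset:
    """The fixture's table with its ground truth restored (no missing cells)."""
    d = fixture.dataset
    return Dataset(
        fixture.truth.copy(),
        np.zeros_like(d.mask),
        list(d.col_names),
        list(d.col_types),
        [None if lv is None else list(lv) for lv in d.cat_levels],
    )


def with_response_column(fixture: Fixture, name: str = "response") -> Dataset:
    """Append the planted binary response as a fully observed categorical column."""
    y = fixture.response
    if y is None:
        raise ValueError("fixture has no planted response")
    d = fixture.dataset
    values = np.column_stack([d.values, y.astype(float)])
    mask = np.column_stack([d.mask, np.zeros(d.n_samples, dtype=bool)])
    return Dataset(
        values,
        mask,
        list(d.col_names) + [name],
        list(d.col_types) + [CATEGORICAL],
        [None if lv is None else list(lv) for lv in d.cat_levels] + [["0", "1"]],
    )


def standard_suite(seed: int = 20210702) -> dict[str, Fixture]:
    """The five canonical fixtures used across the test examples.

    - ``rank2``: 500x10 continuous, latent rank 2, noise sd 0.1, complete.
    - ``linear``: 500x6 with column 3 = 2 * column 1 + N(0, 0.05).
    - ``clusters3``: 300x5, three Gaussian clusters (100 samples each) whose
      centres sit 10 within-cluster standard deviations apart.
    - ``signal``: 500x20 correlated block with three informative predictors
      (indices 0, 5, 10; log-odds effects 1.0 each) driving a binary response.
    - ``null``: 500x20 with a response independent of every feature.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)]

    suite: dict[str, Fixture] = {}
    suite["rank2"] = generate(
        FixtureSpec(n_samples=500, n_continuous=10, latent_rank=2, noise_sd=0.1, seed=seeds[0])
    )
    suite["linear"] = generate(
        FixtureSpec(
            n_samples=500,
            n_continuous=6,
            latent_rank=2,
            noise_sd=0.1,
            planted=PlantedStructure(linear_pairs=[(1, 3, 2.0)], linear_noise_sd=0.05),
            seed=seeds[1],
        )
    )
    # centres: an equilateral triangle in a 2-plane spread across all five
    # dimensions, side length 10 within-cluster sds, so the cluster geometry
    # survives per-column standardisation and 2-D projection
    within_sd = math.sqrt(1.0 + 2.0**2)  # latent_rank + noise_sd^2 per column
    a = np.ones(5) / math.sqrt(5.0)
    b = np.array([1.0, -1.0, 1.0, -1.0, 0.0]) / 2.0
    rho = 10.0 * within_sd / math.sqrt(3.0)
    angles = [2.0 * math.pi * i / 3.0 for i in range(3)]
    centers = np.stack([rho * (math.cos(t) * a + math.sin(t) * b) for t in angles])
    suite["clusters3"] = generate(
        FixtureSpec(
            n_samples=300,
            n_continuous=5,
            latent_rank=1,
            noise_sd=2.0,
            planted=PlantedStructure(cluster_centers=centers),
            seed=seeds[2],
        )
    )
    # informative predictors each have a tightly coupled twin column, so
    # their signal is recoverable by imputation when they are masked but the
    # background correlation stays weak
    suite["signal"] = generate(
        FixtureSpec(
            n_samples=500,
            n_continuous=20,
            latent_rank=2,
            noise_sd=2.0,
            planted=PlantedStructure(
                linear_pairs=[(0, 1, 1.0), (5, 6, 1.0), (10, 11, 1.0)],
                linear_noise_sd=0.3,
                response_idx=[0, 5, 10],
                response_effects=[1.5, 1.5, 1.5],
            ),
            seed=seeds[3],
        )
    )
    suite["null"] = generate(
        FixtureSpec(
            n_samples=500,
            n_continuous=20,
            latent_rank=2,
            noise_sd=2.0,
            planted=PlantedStructure(response_idx=[], response_effects=[]),
            seed=seeds[4],
        )
    )
    return suite
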