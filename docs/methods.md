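# Methods

This note documents the statistical procedures implemented in `tabimpute`,
the defaults and why they were chosen, what the synthetic fixtures do and
do not emulate, and the numerical decisions that were genuinely open.

## Data model

A `Dataset` is an *n* × *m* cell matrix with an explicit boolean mask
(`True` = missing), per-column types (continuous or categorical) and, for
categorical columns, an ordered list of level labels. Masked cells store
`NaN` and are never consulted. On input, cells matching a configurable
token set ({"", "NA", "NaN", "nan", "NULL"} by default, exact match after
trimming) are masked; columns whose observed cells all parse as numbers
are continuous, everything else is categorical with levels in sorted label
order. Numeric columns with few distinct values (integer-coded lab
readings) deliberately stay continuous unless a type hint says otherwise —
treating them as categorical would silently remove them from RMSE-based
evaluation. All cell coordinates are 0-based (row, column).

## Iterative boosted-tree imputation

The imputer follows the established iterative-conditional scheme: initial
mean (or median/mode) fill; columns visited in order of increasing missing
count (stable ties by original index); per column, a gradient-boosted
model fitted on the observed rows with all other columns (current imputed
values) as predictors; missing entries replaced by predictions; repeated
sweeps. Two deltas are tracked per sweep:

- continuous: Σ(Xⁿᵉʷ − Xᵒˡᵈ)² / Σ(Xⁿᵉʷ)² over continuous cells,
- categorical: the fraction of missing categorical cells whose imputed
  level changed (0 when there are none).

**Stopping rule.** The sweep loop stops the first time either delta
strictly increases, returning the *previous* iterate — the convention of
the iterative-forest family this method modifies, where the first
divergence signals the fit has started chasing noise — or at a hard cap
`max_iter` (default 10), returning the current iterate. Whether to return
the previous or current iterate on divergence is a genuine open choice; we
return the previous one because the delta measures exactly how much the
imputed values moved, and a growing move is evidence the last sweep was
harmful. The full loop state (both iterates, the visit order, the delta
history, the stop reason) is attached to the result for inspection and is
echoed into CLI provenance.

**Learner.** 100 trees, single-threaded, seeded, library defaults
otherwise. The backend satisfies a minimal fit/predict contract, so
LightGBM (default) and XGBoost are configurations of the same algorithm,
not separate code paths. Categorical predictors are passed as pandas
`category` columns so trees split on levels natively; categorical targets
use the boosted classifier (a column whose observed cells are all one
level short-circuits to that constant). The seed controls learner
randomness only; the column order is deterministic. Columns without
missing cells are never fitted but always serve as predictors.

**Preconditions.** At least two columns; every column at least one
observed cell; a column that needs imputation must have ≥ 5 observed rows
(below that a tree fit is meaningless). Violations name the offending
column.

## Baseline imputers

- **mean / median**: column statistic for continuous cells, modal level
  for categorical cells, ties to the lowest level code.
- **kNN** (default k = 5): distance between two rows is the Euclidean
  distance over columns observed in both (categorical columns contribute a
  0/1 mismatch), rescaled by m / m_usable — the partial-distance
  convention, so rows sharing few columns are not artificially close.
  Donors must have the target column observed; ties break by row index;
  the fill is the donor mean (continuous) or donor mode. A row sharing no
  column with any donor falls back to the column statistic with a warning.
- **soft-thresholded SVD**: categorical columns enter as one-hot
  indicators (reassembled by block argmax); columns are standardised;
  missing entries start at the column mean; each iteration takes an SVD,
  shrinks singular values by λ, reconstructs, and refills the missing
  entries until their relative change is below `tol` (default 1e-5,
  `max_iter` 1000 — convergence is geometric and slow for small λ, so the
  cap is generous; hitting it sets a warning flag). Column statistics are
  re-estimated from the current completed matrix each iteration
  (EM-style) rather than frozen at their observed-only values: frozen
  statistics leave the incomplete column with a centering offset that
  makes exact low-rank completion unattainable even on exactly low-rank
  data. λ defaults to 1/50 of the top singular value of the initial fill
  (the customary heuristic). λ = 0 (no shrinkage) would make a full-SVD
  iteration a no-op, so it runs as adaptive-rank hard imputation: the
  truncated rank grows from 1 until the observed entries are reproduced
  (relative residual ≤ 1e-9), which converges to the exact completion on
  low-rank data; a `rank` argument fixes the rank instead.
- **chained equations**: the same sweep skeleton with ridge regression
  (continuous targets) and L2 logistic regression (categorical targets),
  run for exactly `n_cycles` sweeps (default 10) and returning the final
  sweep; singular fits fall back to the column statistic with a warning.

All imputers are pure functions of (data, spec, seed), and observed cells
pass through bit-identically.

## Evaluation harness

`mask_mcar` hides ⌊rate × #eligible⌋ currently observed cells, uniformly
without replacement — eligibility excludes already-missing cells so the
harness also works on incomplete tables, and the floor makes counts exact
and deterministic. A draw that would empty a column is an error naming the
column. The plan records positions, true values, and the pre-masking
per-column observed mean/sd used by the z-scored error variant.

RMSE is computed over hidden continuous cells only; the default scale is
raw (per-dataset figures need no normalisation), with `zscore` offered for
cross-dataset aggregation. PFC is the fraction of hidden categorical cells
imputed with the wrong level.

`benchmark_grid` derives one seed per (rate index, replicate index) from
the base seed via a stable seed sequence, draws one mask per cell of the
grid, and scores *every* method on that same mask — paired comparisons by
construction, and adding a method or a rate never changes existing masks.
Per-run wall-clock seconds are recorded for information only and are never
asserted (they are hardware facts, not properties of the method). A
failing run is recorded in the grid without aborting the sweep.

The holdout diagnostic hides max(1, ⌊fraction × n_observed⌋) observed
cells per column (default 5%), all simultaneously, imputes once, and
reports per-column Pearson correlation between imputed and true values
(continuous, ≥ 3 holdout cells, non-constant truth), accuracy
(categorical), or a flagged mean absolute error when the holdout is too
small for a correlation.

## Exploration backends

All outputs are plot-ready tables, not figures. The missingness pattern is
the 0/1 mask; optional feature clustering uses average linkage on
Euclidean distances between the binary indicator columns — the linkage and
metric were an open choice; average/Euclidean is the common default for
indicator data and is frozen here so merge heights are reproducible. PCA
operates on z-standardised features with the component sign fixed so the
largest-magnitude loading is positive (determinism); t-SNE defaults to
perplexity 30, learning rate 200, 1000 iterations, seeded. k-means is
best-of-`n_init` (default 10) restarts; the elbow rule is formalised as
the interior k maximising the second difference of the within-cluster sum
of squares, ties to the smallest k — the elbow method is usually stated
informally, and the second difference is the standard deterministic
formalisation. The WCSS curve must be non-increasing in k; a violation
(possible only through unlucky restarts) is retried with 5× restarts and
raised as a diagnostic rather than silently accepted.

## Feature ranking and prediction

When a response is to be predicted downstream, it is removed before
imputation (`exclude_response`); imputing with the response present leaks
outcome information into the predictors and biases cross-validated
performance upward. The response must be fully observed.

Penalised rankings standardise features and score each by its absolute
coefficient at a penalty chosen by internal 5-fold cross-validation with
the **one-standard-error rule**: among penalties whose mean CV loss is
within one SE of the best, the strongest wins. This is the standard
parsimony convention; the practical consequence is that data carrying no
signal shrink fully to zero instead of retaining noise coefficients at the
CV-best penalty. Binary responses use the logistic link (lasso = L1,
ridge = L2, elastic net l1_ratio 0.5); continuous responses the linear
analogues. `boosted_importance` is total split-gain from a 100-tree
boosted model. Ties in scores keep original feature order.

`cv_predict` uses seeded *stratified* k-fold (default 5) — stratification
was not a forced choice but stabilises AUC at modest n — trains on k−1
folds, scores the held-out fold with class-1 probabilities, and pools the
out-of-fold scores: each sample is scored exactly once by a model that
never saw it. ROC/PR curves group tied scores (one vertex per unique
score); AUC is the trapezoidal area, which equals the Mann–Whitney
probability that a random positive outscores a random negative with ties
counted ½.

## Synthetic fixtures

The generator draws a low-rank-plus-noise continuous block L·Rᵀ + ε
(seeded substreams for base draw, noise, planted structure, and masking,
so adding structure never perturbs the base draw), discretises designated
columns into quantile bins for categorical data, then layers planted
structure: exact linear column relations, Gaussian cluster shifts, and a
binary response from a logistic model on standardised planted predictors.

The standard suite (sizes chosen to keep the full test run in minutes on
one CPU while leaving clear statistical margins):

- `rank2` — 500×10, latent rank 2, noise sd 0.1: the correlated benchmark
  where conditional imputers must beat the mean fill.
- `linear` — 500×6 with column 3 = 2 × column 1 + N(0, 0.05): a planted
  deterministic relation for recovery tests.
- `clusters3` — 300×5, three clusters of 100, centres at the vertices of
  an equilateral triangle spread across all five dimensions with side 10
  within-cluster sds. Axis-aligned centres would concentrate the
  between-cluster variance in two coordinates and lose it to per-column
  standardisation; spreading the triangle across dimensions keeps the
  cluster geometry in the top two principal components.
- `signal` — 500×20 over a weak latent background (noise sd 2), with three
  informative predictors (log-odds effects 1.5 each) that each have a
  tightly coupled twin column (slope 1, noise sd 0.3). The twin design is
  deliberate: with purely low-rank correlation, a downstream linear model
  recovers masked-feature signal from proxy columns no matter how cells
  are imputed, and imputation quality becomes invisible; a twin makes the
  masked informative cell recoverable by conditional imputation while the
  linear model cannot substitute the twin nonadaptively per sample. The
  effect sizes were verified by direct simulation to give cross-validated
  AUC well above 0.8 at n = 500 before the suite was frozen. With twins
  nearly collinear, a sparse ranker keeps one representative per pair —
  tests treat {planted, twin} pairs as the informative ground truth.
- `null` — the same background with a response independent of every
  feature, for chance-level AUC and full lasso shrinkage checks.

**What the fixtures do not emulate:** structured (non-random)
missingness, mixed measurement scales and units, code-absence semantics
(whether an unrecorded diagnosis is negative or missing), longitudinal
aggregation, or multi-table relational structure. Passing tests therefore
demonstrate correctness of the algorithms and the claimed relative
orderings under MCAR with correlated features — not performance on any
particular clinical dataset.

## Numerical and interface decisions

- Level labels serialise as labels (never integer codes); levels are kept
  in sorted label order so codes round-trip through text files.
- Continuous cells serialise with the shortest exact float representation
  (`repr`), so a write/read round-trip is lossless.
- Replicate seeds derive from `SeedSequence([base, rate_idx, rep_idx])`
  reduced mod 2³¹; all public entry points take explicit seeds and no code
  path seeds from the clock.
- Degenerate inputs have defined behaviour throughout: constant features
  flag an undefined correlation rather than raising; single-level
  categorical targets short-circuit; a fully missing column is always an
  error naming the column.
- GAIN-style adversarial imputation is documented as out of scope (its
  usual parameters — batch_size, hint_rate, alpha, iteration — have no
  counterpart here); there is no multiple imputation or between-imputation
  variance pooling; masking is MCAR only.

## Known limitations

Single imputation understates uncertainty: downstream standard errors
treat imputed cells as observed. The boosted imputer's stopping rule
bounds work but does not guarantee a global optimum; on near-independent
columns it simply returns something close to the initial fill. The kNN
imputer is O(n²) in rows. The soft-SVD completion assumes approximate
low-rankness after standardisation and can be slow to converge for tiny
shrinkage. Runtime comparisons between methods are logged but never
asserted, as they are dominated by hardware and library builds.
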