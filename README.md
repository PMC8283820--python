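# tabimpute

Imputation and downstream analysis of mixed-type tabular biomedical data —
the wide samples × features tables typical of electronic health records,
where laboratory values and coded diagnoses are heavily and unevenly
missing. Most modelling tools require complete data, so the practical
questions are: *how should the holes be filled, how good is the fill, and
does it help the prediction you actually care about?* `tabimpute` answers
all three with a single `Dataset` contract (values + explicit missingness
mask + per-column types), a library API, and a `tabimpute` command-line
tool.

## The core algorithm

The centrepiece is an iterative column-wise imputer in the missForest
family with a gradient-boosted tree learner (LightGBM by default, XGBoost
as a drop-in backend). For an *n* × *m* matrix **X** with missing entries:

1. make an initial guess by column mean (or median) imputation;
2. let *k* be the column indices sorted by increasing number of missing
   values;
3. while the stopping rule γ is not met, for each column *s* in *k*:
   fit a boosted model *y*ₒᵦₛ(s) ~ **X**ₒᵦₛ(s) on the rows where column
   *s* is observed (all other columns at their current imputed values),
   predict *y*ₘᵢₛₛ(s) from **X**ₘᵢₛₛ(s), and write the predictions into
   the imputed matrix;
4. return the completed matrix.

γ compares successive sweeps: the relative squared change
Σ(**X**ⁿᵉʷ − **X**ᵒˡᵈ)² / Σ(**X**ⁿᵉʷ)² over continuous cells (and the
fraction of changed categorical imputations). When a delta first
*increases*, the previous iterate is returned; a sweep cap (default 10)
bounds the work. Continuous targets use a boosted regressor, categorical
targets a boosted classifier with native categorical splits.

Around it, under the same interface:

- **Baselines** — column mean/median, partial-distance k-nearest-neighbour
  (default k = 5), soft-thresholded-SVD matrix completion, and
  chained-equations imputation with ridge / logistic models.
- **Evaluation harness** — MCAR masking at chosen rates, RMSE (continuous)
  and proportion-falsely-classified (categorical) on the hidden cells, and
  a method × rate benchmark grid in which all methods share the same masks
  per replicate (paired comparisons), plus a per-column holdout-recovery
  diagnostic.
- **Exploration backends** — missing-rate summaries, feature-pair
  correlations, missingness-pattern matrices with an average-linkage
  dendrogram, PCA/t-SNE embeddings, k-means with elbow-based selection of
  the cluster count (k in 1..9 by default).
- **Prediction stage** — response-excluded imputation (the response never
  leaks into the fill), feature ranking (lasso / ridge / elastic net with
  CV-chosen penalties, or boosted split gain), and stratified five-fold
  out-of-fold prediction with ROC/PR curves and trapezoidal AUC.
- **Synthetic fixtures** — seeded generators of correlated mixed-type
  tables with known ground truth (low-rank structure, planted linear
  relations, planted clusters, planted informative response features), so
  everything is testable without any data download.

## Worked example

```python
import tabimpute as ti

suite = ti.standard_suite()
table = ti.complete_dataset_from(suite["rank2"])      # 500 x 10, rank-2 + noise
masked, plan = ti.mask_mcar(table, rate=0.2, seed=1)  # hide 20% of the cells

for method in ("mean", "knn", "soft_svd", "chained", "boosted"):
    completed = ti.run_imputer(masked, ti.ImputerSpec(method), seed=1)
    print(f"{method:>9}: RMSE = {ti.rmse_on_masked(plan, completed):.3f}")

boosted = ti.impute_boosted(masked, seed=1)
print("sweeps:", boosted.iter_state.iteration,
      "| stop:", boosted.iter_state.converged_reason)
```

prints

```
     mean: RMSE = 1.185
      knn: RMSE = 0.209
 soft_svd: RMSE = 0.136
  chained: RMSE = 0.121
  boosted: RMSE = 0.193
sweeps: 7 | stop: delta_increased
```

Every conditional method beats the mean baseline by a factor of 5–10 on
this correlated table: RMSE is computed only over the deliberately hidden
cells against their true values, so 1.185 for the mean fill is essentially
the marginal standard deviation while the structured methods exploit the
inter-column correlation. The boosted imputer stopped after 7 sweeps
because its convergence delta first increased (the previous iterate is
returned).

The same stages are available from the shell, writing CSV/JSON artifacts
plus a provenance file that makes each run exactly repeatable:

```bash
tabimpute explore  --input data.csv --out-dir out/explore
tabimpute impute   --input data.csv --out-dir out/impute --method boosted --seed 1
tabimpute evaluate --input complete.csv --out-dir out/eval \
    --methods mean,boosted --rates 0.1,0.3 --n-replicates 10
tabimpute predict  --input data.csv --response outcome --out-dir out/pred
```

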