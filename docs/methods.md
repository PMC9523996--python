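# Methods

## The selection procedure

`pfbs` implements a hybrid wrapper/embedded feature-selection pipeline for
wide classification tables (n features ≫ n informative features), built
from three stages that repeat over independent runs:

1. **Positioned bootstrap (PFBS).** A with-replacement sample of the
   table's own size is drawn from the empirical distribution function
   F̂_O(t) = (1/O) Σ I(X_i ≤ t). The draw can sit at three positions
   relative to the selector: *outer* (once per run, before any
   selection; every forest tree then sees the whole resampled table),
   *inner* (no outer draw; each tree of the forest resamples its own
   bootstrap), or *outer_inner* (both). `none` disables resampling
   entirely and serves as the plain RFS-RFE ablation baseline.
2. **Random-forest importance selection (RFS).** A forest of M trees is
   grown on the selection table and each feature is scored by mean
   impurity decrease, normalized to sum to one. Features scoring below
   a threshold are eliminated. The threshold rule is configurable
   (mean importance by default; median and fixed quantile available)
   because no canonical rule exists — the mean is the common
   select-from-model convention and on wide tables retains roughly the
   set-size fractions seen in practice for this family of methods.
3. **Recursive feature elimination (RFE).** An L2-regularized logistic
   model is fitted on the survivors, features are ranked by coefficient
   magnitude, and the lowest-ranked are removed; this repeats until one
   feature remains. Each elimination stage is scored by mean stratified
   k-fold accuracy of the same estimator, and the stage with the best
   mean accuracy is kept, ties broken toward fewer features (RFECV).
   A fixed target size can be requested instead.

Each run evaluates the selected columns with a roster of classifiers
(logistic regression, SVM, random forest, bagging) under stratified
k-fold cross-validation. Across runs, metrics are averaged and the
per-run final feature sets are intersected: features selected in
*every* run form the **stable set**, the pipeline's
reproducibility-oriented output. The across-run standard deviation of
every metric is reported alongside the mean.

## Parameters and defaults

| Parameter | Default | Meaning |
|---|---|---|
| runs | 20 | independent pipeline repetitions feeding the intersection |
| trees (M) | 100 | forest size in the RFS stage |
| criterion | entropy | split-quality measure for the forest |
| min_samples_leaf | 100 | leaf size; suited to tables of thousands of rows |
| threshold | mean | importance cutoff rule in RFS |
| C | 0.05 | inverse regularization strength of the RFE estimator |
| max_iterations | 100 | RFE estimator iteration cap |
| tolerance | 1e-4 | RFE estimator stopping tolerance |
| rfe step | 1 (≤100 features) else 10% | features removed per RFE iteration |
| cv_folds | 10 | folds for both RFECV and the final evaluation |

`min_samples_leaf=100` degenerates every tree to a stump on small
tables, so when it exceeds n/4 the fit logs a warning and falls back to
`max(1, n // 20)`; the configured value remains the default for
large-table use. `max_features_per_split` defaults to `sqrt`, the
standard forest heuristic for the "smallest useful candidate subset per
node". The RFE estimator standardizes features on the training portion
of each fit so that coefficient magnitudes are comparable across
feature scales; without this, "smallest weight" is meaningless when
features live on different scales. Raw data is never mutated.

## Seeds and determinism

A single master seed drives everything: per-run seeds are spawned
through `numpy.random.SeedSequence([master_seed, run_index])`, and each
run's seed parameterizes its bootstrap draw, forest, RFE fold plan and
evaluation fold plan. Two invocations with the same table and master
seed produce identical reports (timing fields excluded). Bootstrap
draws that miss a rare class are retried with an incremented seed up to
100 times before erroring, which keeps downstream stratified CV
well defined without stratifying the draw itself.

## Evaluation and metrics

Accuracy, precision, recall and F1 come from the standard
confusion-matrix definitions; multiclass problems macro-average
one-vs-rest precision and recall and take F1 as the harmonic mean of
the two macro values (micro averaging is intentionally not the default:
the benchmark tables this mirrors report single unweighted values for
5–6-class data). The overfitting gap is train-minus-test accuracy in
percentage points, fold variance is the population variance of
per-fold held-out accuracies on the 0–1 scale, and AUC is the
fold-mean trapezoidal ROC area (macro one-vs-rest for multiclass),
computed from class-probability estimates where the classifier provides
them and min-max-scaled decision values otherwise.

Evaluation defaults to the **original** table. An alternative
`bootstrap_sample` mode evaluates on the outer draw instead; this is
provided for comparison with published protocols but is statistically
leaky — duplicated rows straddle CV folds, so held-out scores are
optimistically biased — and both the documentation and the runtime log
say so.

## The synthetic generator

Synthetic tables place a small set of informative columns among
label-independent Gaussian noise. Informative columns are Gaussian
with class-dependent means evenly spaced across a total range of
`effect_size · noise_sd` (for two classes this is exactly an
`effect_size`-SD mean shift), with the class ordering permuted
independently per feature so no single direction dominates. Keeping
the *total* spread at the nominal effect size — rather than the
adjacent-class spacing — means the per-feature signal strength does not
silently grow with the number of classes. Informative columns sit at
random positions, not a prefix, so index/name confusions surface in
tests. Class counts follow largest-remainder rounding of the requested
proportions. A Student-t noise option stress-tests the importance
ranking under heavy tails.

What the generator does *not* emulate: correlated feature blocks,
batch effects, count-valued or segment-structured measurements, label
noise, and class-dependent variance. Passing recovery tests therefore
demonstrates that the pipeline finds independent Gaussian-shifted
signal among independent noise, not that it handles the full structure
of real omics tables.

## Problem sizes used in the test and acceptance runs

The recovery experiments use 400 samples × 210 features with 10
informative columns at effect size 2.0 over 5 outer-bootstrap runs,
which is large enough that forest importance and RFECV operate in their
intended regime while the whole suite stays quick on one CPU. The
bootstrap distribution check uses 200 draws at n = 1000; exhaustive
oracle comparisons cover all binary label patterns up to n = 12.

## Numerical choices and edge cases

- Importance ties sort by original column index, so rankings are
  reproducible.
- The retained RFS set is never empty: the top importance score is
  always at least any mean/median/quantile threshold of the scores.
- RFE removes `min(step, current − target)` features per iteration,
  never fewer than one; fractional steps resolve against the current
  survivor count.
- Convergence warnings from the heavily regularized logistic estimator
  on wide data are logged, not raised.
- Multiclass RFE ranks feature j by the Euclidean norm of its
  coefficient column across classes, which reduces to |coef| for
  binary problems.
- Zero-denominator precision/recall contribute 0 with a logged
  warning; single-class AUC is reported as NaN and excluded from fold
  means.
- Fold variance returns exactly 0.0 when all folds score identically.
- Missing values are rejected at load with the offending row/column
  named; imputation is deliberately out of scope.

## Known limitations

- The stability intersection is strict: one aberrant run empties it.
  The report flags an empty intersection rather than softening to a
  majority vote.
- `bootstrap_sample` evaluation reproduces optimistic published-style
  scores by construction; numbers obtained in that mode should not be
  read as generalization estimates.
- Selection on the outer draw means selection-stage CV scores are
  computed on a table with duplicated rows; the final reported metrics
  avoid this by defaulting to the original table.
- The pipeline assumes numeric, complete, untransformed input; any
  scaling or encoding of categorical attributes is upstream
  preprocessing.
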