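# Methods

## Problem and approach

`sizeval` evaluates — retrospectively, from the study's own data — whether
a decided sample size is adequate for a two-class classification study.
Prospective power formulas need an effect size taken from earlier
literature, which imports publication bias and design mismatches; here the
effect sizes and the classifier performance are both measured on the data
at hand, across a range of subsample sizes, and a decision rule is applied
to the result.

The pipeline has four stages: (1) compute aggregate effect sizes,
(2) estimate learning curves by repeated balanced subsampling with
cross-validation, (3) apply two adequacy criteria at the decided size,
(4) if inadequate, map the observed trends onto a remediation. A simulator
with controlled ground-truth effect sizes provides test beds for all of
it.

## Effect sizes

Per variable, Cohen's d with the standard two-group pooled SD
(weights $n_c - 1$, denominator $n_1 + n_2 - 2$) and sample SDs
(`ddof=1`) throughout. Classes are ordered by sorted label value and the
per-variable sign is (class 1 − class 2); this ordering is documented, not
configurable.

Two aggregates:

* **Average effect size** `d_average`: the mean of per-variable
  *magnitudes* |d_j|. Averaging signed values would let opposite-direction
  variables cancel, making a panel of strong but opposing markers look
  null; magnitudes keep each variable's discriminative contribution. This
  absolute convention is a deliberate package choice and is what makes
  `d_average` and `d_grand` diverge diagnostically (below).
* **Grand effect size** `d_grand`: per class, the grand mean is the mean
  over variables of per-variable means and the grand SD is the mean over
  variables of per-variable SDs; `d_grand` is the absolute standardized
  difference of the grand means using the pooled grand SDs.

When every variable carries the same class means and SDs the two
statistics agree to rounding. When variable effects are heterogeneous in
*direction*, they diverge: the opposite shifts cancel in the grand means
(`d_grand` → 0) while `d_average` stays large. A large gap between the two
is therefore itself informative — a single-number power analysis would be
unstable on such data — and criterion 1 passes if *either* statistic
clears the bar.

Degenerate inputs: a constant variable makes the pooled SD zero; the
default is a typed `DegenerateVarianceError` (silent infinities would
corrupt the average), with `on_constant="drop"` available to discard such
variables with a warning. Both classes need at least two samples; exactly
two classes are required; missing values must be cleaned upstream (the
CSV loader rejects them by column name).

## Simulator

Each variable is sampled independently as Gaussian: class 1 ~
N(0, σ²), class 2 ~ N(d_j·σ, σ²), with σ = `noise_sd` (default 1, units
arbitrary). The population Cohen's d of variable j then equals the target
d_j exactly, which is the property every downstream test leans on.
Targets are uniform over a regime-specific range: good (0.5–1.4), poor
(0.01–0.2), or a custom range. Defaults: 100 variables; classes balanced;
`n_per_class >= 8` so the smallest evaluated total of 16 is always
reachable.

The data-quality manipulation starts from a poor dataset and regenerates
the *class-2* values of a fraction of variables with good-regime mean
shifts — one group is perturbed, the other left intact. The fraction
counts variables (it is independent of sample size), is continuous in
[0, 1], and substituted subsets are nested across fractions under a fixed
seed: the variable order is drawn once, so fraction 0.5 substitutes a
superset of fraction 0.3's variables and measured effect sizes are
monotone in the fraction by construction, not just in expectation.
Fraction 0 reproduces the untouched poor dataset bit for bit; fraction 1
yields a fully good dataset.

Randomness: one master seed feeds a `SeedSequence`, which spawns fixed,
named child streams (targets, values, substitution selection,
substitution values). Adding a stage can never silently reshuffle another
stage's draws, and every dataset is bit-reproducible from its config.

What the simulator does *not* emulate: correlated features (a correlation
matrix hook exists but defaults to identity), non-Gaussian noise,
heteroscedastic classes other than through substitution, class imbalance,
and categorical variables. Passing tests on simulated data therefore
demonstrate correctness of the machinery and the qualitative
regime-to-accuracy relationships; they do not certify behaviour on real
data with strong feature dependence, where the effective number of
independent variables is smaller and accuracies will generally be lower
at equal `d_average`.

## Evaluation protocol

For each total size n in the schedule, and each of `repetitions` random
draws: one balanced subsample (n/2 per class, without replacement), one
measurement of both effect sizes on that subsample, and one stratified
k-fold cross-validation per classifier family.

* **Schedule**: doubling from 16 (16, 32, 64, …) capped at the largest
  even count available, which is appended if the doubling misses it. The
  floor of 16 reflects the common view of 16–32 samples as the smallest
  meaningful study size. Custom size lists are accepted and validated.
* **Folds**: k = 10 by default. At n = 16 there are only 8 samples per
  class, so stratified 10-fold is impossible; the fold count drops to
  `min(k, smaller class size)`. This reduction is the package's explicit
  choice for tiny subsamples.
* **Accuracy**: pooled over folds — every sample is predicted once by a
  model that never saw it, and accuracy is the fraction of correct
  out-of-fold predictions. (Fold-averaged accuracy differs negligibly for
  stratified folds of near-equal size; pooled is exactly defined even
  when fold sizes differ.) Optional metrics (AUC-ROC, precision, recall,
  F1) are computed on the same pooled predictions, scores taken from
  `predict_proba` or `decision_function`, positive class = larger sorted
  label.
* **Classifier bank** (hyperparameters recorded in every result row, all
  overridable): linear-kernel SVC with C = 1; L2 logistic regression
  (C = 1, 1000 iterations); depth-unlimited decision tree with seeded
  tie-breaking; one-hidden-layer (100 unit) MLP with a 200-iteration cap
  and fixed seed; Gaussian naive Bayes. SVM, LR and the MLP sit behind a
  pipeline whose standardiser is fit on the training fold only — scaling
  without leakage; the tree and naive Bayes are scale-invariant and get
  none.
* **Aggregation**: per (classifier, size) the mean, SD and a
  normal-approximation 95% CI (mean ± 1.96·SD/√reps) of accuracy across
  repetitions (at least two repetitions required); per size the mean/SD
  of both effect sizes. The between-size change is
  100·|acc(next) − acc(size)|/acc(size) per classifier, i.e. a *relative*
  percent change with the smaller size as the base; a zero base yields an
  explicit NaN with a warning rather than an infinity.
* **Determinism and parallelism**: the master seed spawns one child seed
  per (size, repetition) cell up front; repetitions may run in parallel
  via joblib but the record table depends only on the seed, never on
  execution order.

## Adequacy criteria

* **Criterion 1**: `max(d_average, d_grand) >= 0.5`, boundary inclusive.
* **Criterion 2**: accuracy at the decided size `>= 0.80` (inclusive),
  and — only when larger sizes that themselves reach 0.80 were evaluated —
  the relative change to the next such size `< 10%` (strictly; a change of
  exactly 10% fails). Comparing against *every* larger qualifying size
  instead of the next one is available via `stability_comparison="any"`.
* "The accuracy of a size" defaults to the best family's mean accuracy:
  the criteria make a claim about the data's separability, not about one
  algorithm, and the benchmark families (typically NN/SVM) define what is
  achievable. `selector` switches to the median or a named family.
* **Trends for remediation**: a quantity "increases" when its relative
  first-to-last rise across the schedule exceeds `trend_tolerance`
  (default 5% — small enough to catch the slow creep of an indeterminate
  dataset, large enough to ignore repetition noise). The mapping is
  exhaustive over the four (accuracy up? effect size up?) combinations:
  effect size rising → `more_samples` (whether or not accuracy also
  rises, since an improving effect size is cured by samples alone);
  accuracy rising alone → `more_samples_and_features`; neither →
  `revise_design_or_features`. A single-size curve returns an explicit
  `insufficient_schedule` outcome instead of guessing.
* Artifact lineage: effect-size summaries and curves carry a dataset
  fingerprint (SHA-256 of values and labels); combining artifacts from
  different datasets warns rather than silently mixing studies.

## Problem sizes used by the test and acceptance runs

The package's own verification uses scaled simulation sizes chosen to
keep the full suite comfortably runnable on a single CPU while leaving
the statistical conclusions unambiguous: the strongly separated regime is
checked at 512 samples per class with 20 replicate seeds (d ~ U(0.9,
1.4), 100 variables), the barely separated regime across sizes 16–1024
with 20 repetitions per size, generator recovery at 1000 per class, and
the oracle equivalence of the effect-size algebra on 200 small random
matrices against an independently coded loop-wise implementation.

## Known limitations

* The criteria thresholds (0.5 / 80% / 10%) are conventions carried over
  from effect-size and power-analysis practice, not quantities estimated
  from the data; the config makes them explicit and overridable.
* Multi-class problems, regression targets, hyperparameter tuning and
  classifier families beyond the five are out of scope.
* The normal-approximation CI understates uncertainty for accuracies
  near 0 or 1 with few repetitions.
* Real-data learning curves flatten for reasons the independent-Gaussian
  simulator cannot produce (feature correlation, label noise); the
  simulator's role is controlled ground truth, not realism.
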