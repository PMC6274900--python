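# Methods

This note records the statistical model behind `incompfs`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic-data
experiments do and do not demonstrate.

## The selection statistic

For a feature *A* discretised into *m* ordered categories and a class
variable *d* with *l* observed values, the augmented frequency table has an
extra row for samples missing *A* and an extra column for samples missing
*d*. Writing row_i, col_j, N for the marginals and total of the fully
observed m × l block, each observed cell is updated as

    f'_ij = f_ij + f_i? · col_j/N + f_?j · row_i/N + f_?? · f_ij/N .

Interpretation: a sample missing *A* but with class d_j is spread over the
rows of column j in proportion to the observed column profile; symmetrically
for missing *d*; samples missing both are spread over all cells in
proportion to the observed joint profile. Summing the update shows the
redistributed table totals the full sample count — missing mass is moved,
never lost (tested to 1e−9 on random tables).

The statistic is the Pearson form χ² = Σ (E_ij − f'_ij)²/E_ij with
E_ij = r_i c_j/N computed from the *redistributed* marginals, compared to a
χ² distribution with (m′−1)(l−1) degrees of freedom, where m′ is the row
count after aggregation (below). With no missing data this reduces exactly
to the textbook test (verified against an independent implementation to
1e−9 on 1,000 random tables).

**Calibration caveat.** The redistribution adds mass *proportional to the
observed marginals*, i.e. shaped exactly like the independence expectation.
Under the null this deflates χ² by roughly the observed fraction
N/N_total, so the test is slightly conservative in proportion to
missingness: at 10% MCAR missingness the measured fraction of null features
with p < 0.05 is ≈ 0.038 rather than 0.05, while on fully observed data it
is ≈ 0.046 (inside 3 binomial SDs). This is inherent to the redistribution
— a missing cell cannot contribute evidence of dependence — and costs some
power at a fixed α rather than producing false positives.

## Recursive element aggregation

The χ² approximation is unreliable when expected frequencies are small; the
classical rule of thumb wants at least 80% of E_ij above 5. While that
fraction is below 0.8 and more than two rows remain, the row containing the
globally smallest E_ij is merged (element-wise sum) with an adjacent row —
rows are ordered bins, so adjacency is meaningful. Deterministic tie rules:

- smallest E_ij: first in row-major order;
- choice of neighbour: the one with more E_ij entries below 5 (counted in
  the expected table); boundary rows have one neighbour;
- equal counts: the neighbour with the smaller total expected mass;
- still equal: the upper neighbour (smaller index).

The first two rules and the "smaller expected mass" tie-break follow the
design notes shipped with the interface contract; the final upper-neighbour
rule is this package's own determinism choice for the residual exact-tie
case. Columns are never merged (classes are not ordered); zero-sum rows or
columns are instead dropped before scoring, with the degrees of freedom
reduced accordingly. Aggregation performs at most m−2 merges and preserves
the grand total. Empirically it also improves null calibration (0.025 →
0.038 selected fraction at α = 0.05 under 10% missingness).

## Discretisation

Continuous expression values must be binned before tabulation; nothing in
the method prescribes how. Defaults: equal-frequency bins with
n_bins = min(5, ⌊√n_observed⌋), clamped to ≥ 2. Equal-frequency keeps
expected frequencies balanced (so aggregation rarely degenerates) and the
bins are ordered, which the row-adjacency merging requires. Quantile edges
are computed on observed values only; duplicate edges collapse (heavily
tied features end with fewer categories); a value equal to a cut point
stays in the lower bin. `equal_width` and `distinct` (one category per
distinct value — for data that is already categorical) are available.
Constant or all-missing features are flagged degenerate and receive
p-value 1; they rank last and are never selected.

## Imputation

Imputation runs **after** selection, on the selected columns only. Mean
imputation uses the per-feature observed mean. KNN imputation fills cell
(s, f) with the 1/(d+ε)-weighted average (ε = 1e−8) of feature f over the
k = 10 nearest samples that observe f, distances Euclidean over the
features both samples observe, computed on internally min–max-rescaled
values so features are commensurate; if no donor observes f the feature
mean is used. Both imputers follow fit/transform so cross-validation can
learn statistics on training folds only (fold-safe, the default; an
impute-before-CV switch exists for comparability with older protocols).

## ELM and the voting ensemble

An extreme learning machine draws hidden weights and biases once, uniformly
from [−1, 1], applies a sigmoid, and solves the output weights in closed
form, β = H†T, with one-hot class targets and the pseudoinverse truncated
at 1e−12 · σ_max. Parameters are drawn per neuron, so models sharing a seed
nest as the hidden layer grows (training residual is non-increasing in the
hidden count — tested). Default hidden count min(100, n_train − 1): ELM
training accuracy saturates as the hidden layer approaches the training
size, and larger layers only add cost. The V-ELM ensemble trains 30
independently seeded ELMs on identical data and predicts by majority vote;
ties go to the summed continuous outputs, then the class index. The whole
train/predict path is bit-reproducible for a fixed seed.

## Forward best-first search

Prefixes of the p-value ranking are evaluated at sizes
⌈t · pof/100 · n⌉, t = 1…100/pof (default pof = 5%), with two conventions
adopted here: consecutive steps that land on the same prefix size are
evaluated once (short rankings otherwise re-test the identical prefix), and
all rounds share one evaluation seed so every prefix is scored on identical
CV folds — improvements then reflect features, not fold luck. "Improvement"
is strict (no epsilon). The search stops after k = 5 consecutive
non-improving rounds, or when the list is exhausted; with k ≥ K it is an
exhaustive search over all prefixes (tested against brute force). The
evaluator is stratified CV (10-fold; 5-fold when any class has fewer than
10 members; further reduced, with a warning, when a class is rarer than the
fold count) of the imputation + V-ELM pipeline. By default each prefix's
sub-matrix is imputed inside the evaluator (select-then-impute, per
prefix); a flag imputes the full selected set once up front instead.

Because the wrapper optimises cross-validated accuracy, it deliberately
prunes *redundant* informative genes: if five genes carry the same class
signal, a one-gene prefix can win. Recovery of the full informative set is
a property of the filter ranking (all informative genes in the top ranks),
not of the final wrapper subset.

## Metrics

Binary (one-vs-rest) confusion metrics use the textbook formulas; the
`as_printed` mode changes exactly one quantity — balanced accuracy =
(precision + recall)/2 instead of (recall + specificity)/2 — because some
expression-classification reports use that form as their headline metric.
Ratios of 0/0 are reported as undefined (None) and excluded from macro
averages with a log line. AUC is the Mann–Whitney rank statistic with
midranks; on ties-free scores it equals the trapezoidal ROC integral
(tested against an independent implementation).

## Synthetic data

The generator emulates what the method assumes about real data: a few
class-discriminative genes among many noise genes, with missing entries.
Informative features receive class means spaced `effect_size` SDs apart
(centred, consecutive classes one step); noise features are independent
standard normals; labels are balanced and shuffled. MCAR masks cells
independently; MAR raises a sample's masking probability with its value of
a designated fully observed driver feature via a logistic link whose
intercept is bisection-calibrated to the requested overall rate. Values are
finally min–max normalised to [−0.9, 0.9] per feature over observed cells
(constant features map to the 0 midpoint). Defaults — 60 samples, 100
features, 5 informative, 3 classes, effect 2.0, 10% MCAR — describe a
small-cohort expression study.

Deliberately not modelled: platform noise (dye bias, spatial artefacts),
correlated gene blocks, class imbalance, missing-not-at-random mechanisms.
Passing tests therefore show the machinery is correct and recovers planted
signal under idealised conditions; they do not certify performance on real
microarray data.

## Problem sizes in the test-suite experiments

Worked-example checks are exact and instantaneous. Randomised oracles use
1,000 tables (redistribution mass conservation; complete-data agreement)
and 200 tables (aggregation simulation). Stochastic experiments use the
generator defaults: nesting across α on 10 datasets; null calibration on
10 × 500 null features; recovery on 10 seeds with the full V-ELM evaluator;
classifier sanity on 20 seeds of 40-sample blob data. These sizes keep the
whole suite within a couple of minutes on a laptop while leaving the
binomial/rank-test tolerances meaningful.

## Known limitations

- The selection test is conservative under missingness (see above); very
  high missing rates cost power at fixed α.
- When aggregation hits the two-row floor on very small cohorts the χ²
  approximation may still be poor; the p-value is then reported as-is.
- The KNN imputer is O(n² p) per transform; adequate at cohort scale, not
  for single-cell atlases.
- Discretisation is univariate and unsupervised; supervised binning might
  sharpen the filter but would entangle it with the labels.
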