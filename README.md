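# incompfs

Feature selection and classification for **incomplete gene-expression
matrices** — without imputing first.

Expression matrices from microarray (and sparse single-cell) experiments
routinely contain missing values. The usual workflow imputes them before any
feature selection, which lets the imputer's assumptions (typically missing
at random) leak into which genes look informative. `incompfs` implements the
opposite order: score and select genes **directly on the incomplete
matrix**, impute only the small selected subset, then search that subset for
the best top-ranked prefix with a wrapper classifier. It is aimed at
bioinformaticians analysing small-cohort, high-dimensional expression data
with non-trivial missingness.

## The method

**1. Missing-data chi-square filter (MCFS).** Each feature *A* (discretised
into *m* ordered bins) is tabulated against the class *d* (*l* values) in an
augmented frequency table whose trailing row/column hold the counts with *A*
and/or *d* missing. The missing mass is redistributed into the observed
m × l cells proportionally to the observed marginals,

```
f'_ij = f_ij + f_i? · col_j/N + f_?j · row_i/N + f_?? · f_ij/N
```

with row_i, col_j, N sums over fully observed cells. The redistribution
conserves the total sample count. Because cohorts are small, the table is
stabilised by *recursive element aggregation*: while fewer than 80% of
expected frequencies E_ij = r_i c_j / N exceed 5 and more than two rows
remain, the row holding the globally smallest E_ij is merged with an
adjacent row. The Pearson statistic χ² = Σ (E_ij − f'_ij)²/E_ij with
(rows−1)(l−1) degrees of freedom gives each feature a p-value; features with
p < α (default 0.001) are kept, ranked by ascending p.

**2. Impute the selected subset.** Mean or k-nearest-neighbour imputation
(donors are samples observing the target gene; Euclidean distance over
commonly observed genes; 1/(d+ε) weights) — applied only to the columns that
survived the filter.

**3. Forward best-first search (FBFS) with a voting ELM.** Prefixes of the
ranking are grown in `pof`-percent steps; each prefix is scored by
stratified cross-validation of a 30-member majority-vote ensemble of extreme
learning machines (random sigmoid hidden layer, output weights β = H†T by
pseudoinverse). The search stops after `k` (default 5) consecutive
non-improving rounds and returns the incumbent best prefix.

## Worked example

```python
from incompfs import FBMCFS, MCFS, PipelineConfig, SyntheticSpec, generate_dataset

X, y, informative = generate_dataset(SyntheticSpec(seed=1))   # 60×100, 5 informative, 10% missing
print(MCFS(X, y).fit().summary(top=5))

res = FBMCFS(X, y, config=PipelineConfig(seed=1, trials=5)).fit()
print(res.summary())
```

prints

```
Modified chi-square feature selection (MCFS)
  samples: 60   features: 100   classes: 3
  alpha: 0.001   selected: 5

feature    chi2  df   p_value  rank  selected  degenerate
     g2 39.7091   2 2.384e-09     1      True       False
     g1 36.6229   2 1.115e-08     2      True       False
     g0 28.8401   2 5.463e-07     3      True       False
     g4 26.1720   2 2.074e-06     4      True       False
     g3 26.1176   2 2.131e-06     5      True       False

FB-MCFS pipeline
  samples: 60   features: 100   classes: 3
  filter: alpha=0.001 -> 5 features
  search: pof=5% patience=5 imputer=mean
  trajectory (size:score): 1:0.750, 2:0.733, 3:0.517, 4:0.450, 5:0.633
  best subset (1 features, CV score 0.7500):
    g2
```

The filter puts exactly the five planted informative genes (g0–g4) at the
top with p-values far below α = 0.001; every noise gene is rejected. The
wrapper then prunes further: the five informative genes all carry the same
class signal, so a single one (g2) already achieves the best cross-validated
accuracy and the redundant four are dropped. `res.evaluate()` reports
repeated-CV accuracy and one-vs-rest per-class metrics (accuracy, recall,
specificity, precision, balanced accuracy, F1, G-mean, AUC) for the final
subset.

The same pipeline is available from the shell:

```sh
incompfs simulate --spec spec.yaml --out data.tsv
incompfs rank --input data.tsv --alpha 0.001 --out scores.tsv
incompfs run --config cfg.yaml --input data.tsv --outdir out/
```

## Layout

- `incompfs.io_preprocess` — TSV/CSV readers/writers, [−0.9, 0.9] min–max
  normalisation, ordered discretisation
- `incompfs.mcfs` — frequency tables, redistribution, aggregation, χ²
  scoring; the `MCFS` model
- `incompfs.imputation` — mean and KNN imputers (fit/transform, fold-safe)
- `incompfs.velm` — `ELMClassifier`, `VELMClassifier`
- `incompfs.fbfs` — forward best-first search
- `incompfs.metrics` — confusion metrics, one-vs-rest, rank-statistic AUC,
  seeded stratified CV
- `incompfs.synthetic` — ground-truth data generator
- `incompfs.pipeline` — the `FBMCFS` model / results objects
- `incompfs.cli` — `incompfs` command-line tool

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
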