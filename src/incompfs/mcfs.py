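"""Modified chi-square feature selection (MCFS) for incomplete data.

A feature is scored against the class label without any pre-imputation.  The
joint counts of (discretised feature value, class) are tabulated in an
augmented frequency table whose trailing row/column hold the
feature-missing and class-missing counts.  That missing mass is then
redistributed into the observed m x l cells proportionally to the observed
marginals:

    f'_ij = f_ij + f_{i,?} * col_j / N + f_{?,j} * row_i / N + f_{?,?} * f_ij / N

where row_i, col_j and N are sums over the fully observed cells.  The
redistribution conserves total mass: the resulting contingency table sums to
the full sample count.  Because expression studies are small, the table is
then stabilised by recursively merging the row holding the globally smallest
expected frequency with an adjacent row until at least 80% of expected
frequencies exceed 5 (the classical validity rule for the chi-square
approximation) or only two rows remain.  Finally the Pearson statistic
chi2 = sum (E_ij - f'_ij)^2 / E_ij with E_ij = r_i c_j / N gives an
upper-tail p-value on (rows - 1)(cols - 1) degrees of freedom; features are
ranked by ascending p-value and selected below a significance level alpha
(default 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DiscretizedFeature, IncompleteMatrix, LabelVector
from .exceptions import ConfigError, UnsupervisedInputError
from .io_preprocess import discretize_feature

#: classical chi-square validity constants: the aggregation loop runs until
#: at least VALIDITY_FRACTION of expected frequencies exceed VALIDITY_COUNT
VALIDITY_COUNT = 5.0
VALIDITY_FRACTION = 0.8


@dataclass
class FrequencyTable:
    """Raw (m+1) x (l+1) co-occurrence counts with trailing missing row/col.

    ``F[i, j]`` for i < m, j < l counts samples with feature category i and
    class j; row m collects feature-missing samples, column l class-missing
    samples.  ``N`` is the fully observed total.
    """

    F: np.ndarray
    row_labels: list
    col_labels: list

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)

    @property
    def m(self) -> int:
        return self.F.shape[0] - 1

    @property
    def l(self) -> int:
        return self.F.shape[1] - 1

    @property
    def observed(self) -> np.ndarray:
        return self.F[: self.m, : self.l]

    @property
    def N(self) -> float:
        return float(self.observed.sum())

    @property
    def total(self) -> float:
        return float(self.F.sum())


@dataclass
class ContingencyTable:
    """m x l redistributed frequencies with their expected-frequency grid."""

    M: np.ndarray
    col_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)

    @property
    def row_sums(self) -> np.ndarray:
        return self.M.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.M.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.M.sum())

    @property
    def expected(self) -> np.ndarray:
        return expected_frequencies(self)


@dataclass
class FeatureScore:
    """Chi-square score of one feature against the class."""

    chi2: float
    df: int
    p_value: float
    degenerate: bool = False

    @classmethod
    def degenerate_score(cls) -> "FeatureScore":
        return cls(chi2=0.0, df=0, p_value=1.0, degenerate=True)


def build_frequency_table(feature: DiscretizedFeature,
                          labels: LabelVector) -> FrequencyTable:
    """Tabulate discretised feature codes against class labels.

    Missing feature values and/or missing labels are routed to the trailing
    row/column.  Raises if fewer than two classes are observed.
    """
    codes = feature.codes
    if len(codes) != len(labels):
        raise ConfigError("feature and labels must have equal length")
    classes = labels.classes
    if len(classes) < 2:
        raise UnsupervisedInputError(
            f"need >= 2 observed classes, got {classes}")
    m = feature.m
    l = len(classes)
    ccodes = labels.codes()
    F = np.zeros((m + 1, l + 1))
    rows = np.where(codes >= 0, codes, m)
    cols = np.where(ccodes >= 0, ccodes, l)
    np.add.at(F, (rows, cols), 1.0)
    return FrequencyTable(F, list(range(m)), classes)


def redistribute_missing(F: FrequencyTable) -> ContingencyTable | None:
    """Redistribute the missing row/column mass into the observed cells.

    Returns None when no fully observed sample exists (N = 0), in which case
    the feature is unscorable and receives p-value 1 downstream.
    """
    N = F.N
    if N <= 0:
        return None
    f = F.observed
    row = f.sum(axis=1)
    col = f.sum(axis=0)
    f_rowmiss = F.F[: F.m, F.l]          # (a_i, ?) counts
    f_colmiss = F.F[F.m, : F.l]          # (?, d_j) counts
    f_bothmiss = F.F[F.m, F.l]           # (?, ?) count
    M = (f
         + np.outer(f_rowmiss, col) / N
         + np.outer(row, f_colmiss) / N
         + f_bothmiss * f / N)
    return ContingencyTable(M, list(F.col_labels))


def expected_frequencies(M: ContingencyTable | np.ndarray) -> np.ndarray:
    """Expected grid E_ij = r_i c_j / N from the table's own marginals."""
    A = M.M if isinstance(M, ContingencyTable) else np.asarray(M, dtype=float)
    N = A.sum()
    if N <= 0:
        raise ConfigError("expected_frequencies requires a positive grand total")
    return np.outer(A.sum(axis=1), A.sum(axis=0)) / N


def _pick_merge_rows(M: np.ndarray, E: np.ndarray) -> tuple[int, int]:
    """Row pair to merge: the row of the globally smallest expected frequency
    and the adjacent row with more expected entries below the validity count.

    Ties: smallest E_ij first in row-major order; neighbor-count ties go to
    the neighbor with the smaller total expected mass, then to the upper
    neighbor.
    """
    i, _ = np.unravel_index(int(np.argmin(E)), E.shape)
    last = M.shape[0] - 1
    if i == 0:
        return 0, 1
    if i == last:
        return last, last - 1
    up, down = i - 1, i + 1
    n_up = int((E[up] < VALIDITY_COUNT).sum())
    n_down = int((E[down] < VALIDITY_COUNT).sum())
    if n_up != n_down:
        return i, (up if n_up > n_down else down)
    return i, (up if E[up].sum() <= E[down].sum() else down)


def aggregate_rows(M: ContingencyTable) -> ContingencyTable:
    """Recursively merge adjacent rows until the chi-square validity rule
    holds (>= 80% of expected frequencies above 5) or only 2 rows remain.

    Each iteration element-wise sums the row holding the globally smallest
    expected frequency with one adjacent row; the grand total is unchanged.
    """
    A = M.M.copy()
    while A.shape[0] > 2:
        E = expected_frequencies(A)
        if (E > VALIDITY_COUNT).mean() >= VALIDITY_FRACTION:
            break
        i, nb = _pick_merge_rows(A, E)
        lo, hi = min(i, nb), max(i, nb)
        A[lo] = A[lo] + A[hi]
        A = np.delete(A, hi, axis=0)
    return ContingencyTable(A, list(M.col_labels))


def chi_square_pvalue(M: ContingencyTable) -> FeatureScore:
    """Pearson statistic and upper-tail p-value of an (aggregated) table.

    Zero-sum rows/columns are dropped before scoring (their expected
    frequencies would be 0/0) with the degrees of freedom reduced
    accordingly; tables left with fewer than 2 rows or columns are
    degenerate and score p = 1.
    """
    A = M.M
    A = A[A.sum(axis=1) > 0][:, A.sum(axis=0) > 0]
    if A.shape[0] < 2 or A.shape[1] < 2:
        return FeatureScore.degenerate_score()
    E = expected_frequencies(A)
    ok = E > 0
    chi2 = float((((E - A) ** 2)[ok] / E[ok]).sum())
    df = (A.shape[0] - 1) * (A.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return FeatureScore(chi2=chi2, df=df, p_value=p)


def score_feature(feature: DiscretizedFeature, labels: LabelVector,
                  aggregate: bool = True) -> FeatureScore:
    """Full scoring path for one discretised feature: tabulate, redistribute,
    (optionally) aggregate, score.  Degenerate inputs score p = 1."""
    if feature.degenerate or feature.m < 2:
        return FeatureScore.degenerate_score()
    F = build_frequency_table(feature, labels)
    M = redistribute_missing(F)
    if M is None:
        return FeatureScore.degenerate_score()
    if aggregate:
        M = aggregate_rows(M)
    return chi_square_pvalue(M)


class MCFS:
    """Modified chi-square feature selection model on an incomplete matrix.

    Parameters
    ----------
    X : IncompleteMatrix
        Expression data, samples x features, with missingness mask.
    y : LabelVector or sequence
        Per-sample class labels; missing labels participate through the
        class-missing column of the frequency table.
    alpha : float in (0, 1)
        Significance threshold for selection (default 0.001).
    n_bins : int or "auto"
        Bins for continuous-feature discretisation; "auto" uses
        min(5, floor(sqrt(n_observed))) per feature.
    strategy : {"equal_frequency", "equal_width", "distinct"}
        Discretisation strategy.
    aggregate : bool
        Apply the small-sample row aggregation (default True).
    """

    def __init__(self, X: IncompleteMatrix, y, alpha: float = 0.001,
                 n_bins="auto", strategy: str = "equal_frequency",
                 aggregate: bool = True):
        if not isinstance(X, IncompleteMatrix):
            X = IncompleteMatrix.from_values(np.asarray(X, dtype=float))
        if not isinstance(y, LabelVector):
            y = LabelVector(np.asarray(y, dtype=object))
        if not 0 < alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1); got {alpha}")
        if len(y) != X.n_samples:
            raise ConfigError("label vector length must equal n_samples")
        if y.n_classes < 2:
            raise UnsupervisedInputError("need >= 2 observed classes")
        self.X = X
        self.y = y
        self.alpha = float(alpha)
        self.n_bins = n_bins
        self.strategy = strategy
        self.aggregate = aggregate

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "class", **kwargs):
        """Build from a samples x features DataFrame with a label column."""
        y = LabelVector(df[label].to_numpy(dtype=object))
        data = df.drop(columns=[label])
        X = IncompleteMatrix.from_values(
            data.to_numpy(dtype=float), list(data.columns),
            [str(i) for i in data.index])
        return cls(X, y, **kwargs)

    def fit(self) -> "MCFSResults":
        scores = []
        for j in range(self.X.n_features):
            x, mask = self.X.column(j)
            feat = discretize_feature(x, mask, n_bins=self.n_bins,
                                      strategy=self.strategy)
            scores.append(score_feature(feat, self.y, aggregate=self.aggregate))
        return MCFSResults(self, scores)


class MCFSResults:
    """Per-feature chi-square scores, ranking and selection.

    ``order`` ranks features by ascending p-value (ties: larger chi2 first,
    then original index); ``selected`` holds indices with p < alpha in rank
    order.
    """

    def __init__(self, model: MCFS, scores: list[FeatureScore]):
        self.model = model
        self.scores = scores
        p = np.array([s.p_value for s in scores])
        chi2 = np.array([s.chi2 for s in scores])
        idx = np.arange(len(scores))
        self.order = np.array(sorted(idx, key=lambda j: (p[j], -chi2[j], j)),
                              dtype=int)
        self.p_values = p
        self.chi2 = chi2
        self.selected = self.order[p[self.order] < model.alpha]

    @property
    def alpha(self) -> float:
        return self.model.alpha

    def selection_at(self, alpha: float) -> np.ndarray:
        """Rank-ordered indices selected at an alternative threshold."""
        return self.order[self.p_values[self.order] < alpha]

    def to_frame(self) -> pd.DataFrame:
        ranks = np.empty(len(self.order), dtype=int)
        ranks[self.order] = np.arange(1, len(self.order) + 1)
        return pd.DataFrame({
            "feature": self.model.X.feature_names,
            "chi2": self.chi2,
            "df": [s.df for s in self.scores],
            "p_value": self.p_values,
            "rank": ranks,
            "selected": self.p_values < self.alpha,
            "degenerate": [s.degenerate for s in self.scores],
        }).sort_values("rank").reset_index(drop=True)

    def summary(self, top: int = 20) -> str:
        df = self.to_frame().head(top)
        lines = [
            "Modified chi-square feature selection (MCFS)",
            f"  samples: {self.model.X.n_samples}   features: "
            f"{self.model.X.n_features}   classes: {self.model.y.n_classes}",
            f"  alpha: {self.alpha:g}   selected: {len(self.selected)}",
            "",
            df.to_string(index=False,
                         formatters={"chi2": "{:.4f}".format,
                                     "p_value": "{:.3e}".format}),
        ]
        return "\n".join(lines)
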