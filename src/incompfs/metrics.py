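"""Confusion-matrix metrics, one-vs-rest aggregation and seeded CV.

Metrics come in two modes.  ``standard`` uses the textbook formulas
(recall = TP/(TP+FN), balanced accuracy = (recall+specificity)/2, G-mean =
sqrt(recall * specificity)).  ``as_printed`` differs in one place only:
balanced accuracy = (precision + recall)/2, the headline quantity some
microarray studies report.  Undefined ratios (0/0) are returned as None and
excluded from macro averages with a log line.

Cross-validation is stratified and seeded; the pipeline under evaluation
(impute -> train -> predict) is fitted on training folds only, so imputation
statistics never leak from test folds.  A ``fold_safe=False`` switch imputes
the full matrix once up front, mirroring the older impute-before-CV
protocol, and is retained for comparability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .containers import IncompleteMatrix, LabelVector
from .exceptions import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Binary (one-vs-rest) confusion counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise DataError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=object)
        y_pred = np.asarray(y_pred, dtype=object)
        t = y_true == positive
        p = y_pred == positive
        return cls(TP=int((t & p).sum()), TN=int((~t & ~p).sum()),
                   FP=int((~t & p).sum()), FN=int((t & ~p).sum()))


@dataclass
class MetricsReport:
    """Per-class (or binary) metrics; None marks an undefined 0/0 ratio."""

    accuracy: float | None
    recall: float | None
    specificity: float | None
    precision: float | None
    balanced_accuracy: float | None
    f1: float | None
    g_mean: float | None
    auc: float | None = None
    mode: str = "standard"

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("accuracy", "recall", "specificity", "precision",
                 "balanced_accuracy", "f1", "g_mean", "auc")}


def _ratio(num, den, name):
    if den == 0:
        logger.info("metric %s undefined (0/0); excluded from averages", name)
        return None
    return num / den


def compute_metrics(C: ConfusionCounts, mode: str = "standard",
                    auc: float | None = None) -> MetricsReport:
    """All confusion metrics for one binary table.

    ``as_printed`` mode swaps balanced accuracy to (precision + recall)/2;
    everything else is identical between modes.
    """
    if mode not in ("standard", "as_printed"):
        raise ConfigError(f"unknown metrics mode {mode!r}")
    acc = _ratio(C.TP + C.TN, C.total, "accuracy")
    rec = _ratio(C.TP, C.TP + C.FN, "recall")
    spe = _ratio(C.TN, C.TN + C.FP, "specificity")
    pre = _ratio(C.TP, C.TP + C.FP, "precision")
    if mode == "as_printed":
        bal = (pre + rec) / 2 if pre is not None and rec is not None else None
    else:
        bal = (rec + spe) / 2 if rec is not None and spe is not None else None
    f1 = (None if rec is None or pre is None or (rec + pre) == 0
          else 2 * rec * pre / (rec + pre))
    gm = (None if rec is None or spe is None
          else float(np.sqrt(rec * spe)))
    return MetricsReport(acc, rec, spe, pre, bal, f1, gm, auc, mode)


def auc_score(y_true_binary, scores) -> float | None:
    """AUC by the Mann-Whitney rank statistic (midranks under ties).

    Returns None when either class is absent (single-class fold).
    """
    y = np.asarray(y_true_binary, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        logger.info("AUC undefined: one class absent from the fold")
        return None
    r = rankdata(s)
    u = r[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def one_vs_rest(y_true, y_pred, scores=None, mode: str = "standard"):
    """Per-class one-vs-rest metrics plus their macro average.

    ``scores`` (n_samples x n_classes, columns in sorted class order) feeds
    the per-class AUC; omit it to skip AUC.  Returns
    ``(dict class -> MetricsReport, MetricsReport macro)``.
    """
    y_true = np.asarray(y_true, dtype=object)
    classes = sorted(set(y_true))
    if len(classes) < 2:
        raise DataError("one_vs_rest needs >= 2 classes")
    reports = {}
    for ci, c in enumerate(classes):
        auc = None
        if scores is not None:
            auc = auc_score(y_true == c, np.asarray(scores)[:, ci])
        reports[c] = compute_metrics(
            ConfusionCounts.from_predictions(y_true, y_pred, c),
            mode=mode, auc=auc)
    macro_vals = {}
    for k in ("accuracy", "recall", "specificity", "precision",
              "balanced_accuracy", "f1", "g_mean", "auc"):
        vals = [getattr(r, k) for r in reports.values()
                if getattr(r, k) is not None]
        macro_vals[k] = float(np.mean(vals)) if vals else None
    macro = MetricsReport(mode=mode, **macro_vals)
    return reports, macro


def accuracy_score(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    return float((y_true == y_pred).mean())


def _label_array(y) -> np.ndarray:
    if isinstance(y, LabelVector):
        return y.labels
    return LabelVector(np.asarray(y, dtype=object)).labels


def stratified_folds(y, folds: int, seed: int):
    """Seeded stratified fold assignment over samples with observed labels.

    Folds are reduced (with a log line) when the rarest class has fewer
    members than requested folds; singleton classes always stay in training.
    """
    y = _label_array(y)
    keep = np.array([v is not None for v in y])
    idx = np.where(keep)[0]
    y_obs = y[idx]
    counts = {c: int((y_obs == c).sum()) for c in set(y_obs)}
    min_count = min(counts.values())
    eff = folds
    if min_count < folds:
        eff = max(2, min_count)
        logger.info("reducing folds from %d to %d (rarest class has %d members)",
                    folds, eff, min_count)
    if eff < 2:
        raise DataError("cannot stratify: a class has < 2 members")
    singleton = np.array([counts[v] < 2 for v in y_obs])
    cv_idx = idx[~singleton]
    if singleton.any():
        logger.warning("%d singleton-class samples kept in every training fold",
                       int(singleton.sum()))
    skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=seed % (2**32))
    y_cv = y[cv_idx].astype(str)
    for tr, te in skf.split(np.zeros(len(cv_idx)), y_cv):
        train = np.concatenate([cv_idx[tr], idx[singleton]])
        yield np.sort(train), cv_idx[te]


def cross_validate(X, y, pipeline_factory, folds: int = 10, trials: int = 1,
                   seed: int = 0, scorer=None, fold_safe: bool = True):
    """Mean CV score per trial for a fit/predict pipeline.

    ``pipeline_factory(trial_seed)`` must return an object with
    ``fit(X_train, y_train)`` and ``predict(X_test)``; X may be an
    :class:`IncompleteMatrix` (the pipeline imputes) or a complete array.
    Returns an ndarray of per-trial mean scores (default scorer: accuracy).
    """
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    if scorer is None:
        scorer = accuracy_score
    y = _label_array(y)
    if not fold_safe and isinstance(X, IncompleteMatrix):
        from .imputation import mean_impute
        X = mean_impute(X).values

    def take(X, rows):
        if isinstance(X, IncompleteMatrix):
            return X.subset_samples(rows)
        return np.asarray(X, dtype=float)[rows]

    out = []
    root = np.random.SeedSequence(seed)
    trial_seeds = root.generate_state(trials)
    for t in range(trials):
        tseed = int(trial_seeds[t])
        scores = []
        for tr, te in stratified_folds(y, folds, seed=tseed):
            pipe = pipeline_factory(tseed)
            pipe.fit(take(X, tr), y[tr])
            scores.append(scorer(y[te], pipe.predict(take(X, te))))
        out.append(float(np.mean(scores)))
    return np.asarray(out)


class VELMPipeline:
    """Impute -> V-ELM pipeline usable inside :func:`cross_validate`."""

    def __init__(self, imputer=None, n_hidden=None, n_estimators: int = 30,
                 seed: int = 0):
        from .imputation import MeanImputer
        self.imputer = imputer if imputer is not None else MeanImputer()
        self.n_hidden = n_hidden
        self.n_estimators = n_estimators
        self.seed = seed

    def _complete(self, X, fit: bool):
        if isinstance(X, IncompleteMatrix):
            if fit:
                self.imputer.fit(X)
            return self.imputer.transform(X).values
        return np.asarray(X, dtype=float)

    def fit(self, X, y):
        from .velm import VELMClassifier
        Xc = self._complete(X, fit=True)
        self.model_ = VELMClassifier(self.n_hidden, self.n_estimators,
                                     seed=self.seed).fit(Xc, y)
        return self

    def predict(self, X):
        return self.model_.predict(self._complete(X, fit=False))

    def decision_function(self, X):
        return self.model_.decision_function(self._complete(X, fit=False))
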