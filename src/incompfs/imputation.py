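"""Missing-value imputation for the wrapper stage.

Imputation happens *after* feature selection, on the selected columns only.
Both imputers follow a fit/transform protocol so that cross-validation can
learn imputation statistics on training folds alone:

* :class:`MeanImputer` — each missing cell gets its feature's observed mean.
* :class:`KNNImputer` — each missing cell gets the distance-weighted average
  of that feature over the k nearest donor samples that observe it, with
  Euclidean distance computed on the features both samples observe
  (normalised internally so features are commensurate).  Weights are
  1/(d + 1e-8); when no donor observes the feature, the feature mean is the
  fallback.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CompleteMatrix, IncompleteMatrix
from .exceptions import ConfigError, DegenerateFeatureError

logger = logging.getLogger(__name__)

_EPS = 1e-8


def _as_incomplete(X) -> IncompleteMatrix:
    if isinstance(X, IncompleteMatrix):
        return X
    return IncompleteMatrix.from_values(np.asarray(X, dtype=float))


class MeanImputer:
    """Per-feature observed-mean imputation."""

    def __init__(self):
        self.means_ = None

    def fit(self, X) -> "MeanImputer":
        X = _as_incomplete(X)
        dead = [X.feature_names[j] for j in range(X.n_features)
                if not X.mask[:, j].any()]
        if dead:
            raise DegenerateFeatureError(
                dead, f"cannot mean-impute features with no observed value: {dead}")
        self.means_ = np.nanmean(X.values, axis=0)
        return self

    def transform(self, X) -> CompleteMatrix:
        if self.means_ is None:
            raise ConfigError("imputer is not fitted")
        X = _as_incomplete(X)
        values = np.where(X.mask, X.values, self.means_[None, :])
        return CompleteMatrix(values, list(X.feature_names),
                              list(X.sample_ids),
                              {"imputer": "mean"})

    def fit_transform(self, X) -> CompleteMatrix:
        return self.fit(X).transform(X)


class KNNImputer:
    """Nearest-donor imputation in the style of expression-array KNN filling.

    Parameters
    ----------
    k : int
        Number of donor samples (default 10).  If fewer donors observe the
        target feature, all of them are used (logged).
    """

    def __init__(self, k: int = 10):
        if k < 1:
            raise ConfigError("k must be >= 1")
        self.k = int(k)
        self._train = None
        self.means_ = None

    def fit(self, X) -> "KNNImputer":
        X = _as_incomplete(X)
        dead = [X.feature_names[j] for j in range(X.n_features)
                if not X.mask[:, j].any()]
        if dead:
            raise DegenerateFeatureError(
                dead, f"cannot knn-impute features with no observed value: {dead}")
        self.means_ = np.nanmean(X.values, axis=0)
        # distances run on a per-feature min-max rescaled copy so that
        # features with large raw ranges do not dominate
        lo = np.nanmin(X.values, axis=0)
        hi = np.nanmax(X.values, axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        self._scale = (lo, span)
        self._train = X
        return self

    def _scaled(self, values):
        lo, span = self._scale
        return (values - lo) / span

    def transform(self, X) -> CompleteMatrix:
        if self._train is None:
            raise ConfigError("imputer is not fitted")
        X = _as_incomplete(X)
        train = self._train
        out = X.values.copy()
        q_scaled = self._scaled(X.values)
        t_scaled = self._scaled(train.values)
        for s in range(X.n_samples):
            miss = np.where(~X.mask[s])[0]
            if miss.size == 0:
                continue
            # pairwise distances to all training samples over commonly
            # observed features
            common = X.mask[s][None, :] & train.mask
            diff = np.where(common, t_scaled - q_scaled[s][None, :], 0.0)
            n_common = common.sum(axis=1)
            with np.errstate(invalid="ignore"):
                dist = np.sqrt((diff ** 2).sum(axis=1))
            dist = np.where(n_common > 0, dist, np.inf)
            for f in miss:
                donors = np.where(train.mask[:, f] & np.isfinite(dist))[0]
                if donors.size == 0:
                    out[s, f] = self.means_[f]
                    continue
                if donors.size < self.k:
                    logger.debug("feature %s: only %d donors available (k=%d)",
                                 train.feature_names[f], donors.size, self.k)
                    chosen = donors
                else:
                    order = donors[np.argsort(dist[donors], kind="stable")]
                    chosen = order[: self.k]
                w = 1.0 / (dist[chosen] + _EPS)
                out[s, f] = float(np.average(train.values[chosen, f], weights=w))
        return CompleteMatrix(out, list(X.feature_names), list(X.sample_ids),
                              {"imputer": "knn", "k": self.k})

    def fit_transform(self, X) -> CompleteMatrix:
        return self.fit(X).transform(X)


def mean_impute(X) -> CompleteMatrix:
    """One-shot mean imputation of a matrix against itself."""
    return MeanImputer().fit_transform(X)


def knn_impute(X, k: int = 10) -> CompleteMatrix:
    """One-shot KNN imputation of a matrix against itself."""
    return KNNImputer(k=k).fit_transform(X)


def get_imputer(name: str, **params):
    """Imputer factory: ``mean`` or ``knn`` (plug-in point for others)."""
    if name == "mean":
        return MeanImputer()
    if name == "knn":
        return KNNImputer(**params)
    raise ConfigError(f"unknown imputer {name!r}")
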