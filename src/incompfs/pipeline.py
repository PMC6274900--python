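"""End-to-end FB-MCFS model: rank on incomplete data, impute the selected
columns, forward best-first search with a cross-validated V-ELM.

The deliberate ordering — selection *before* any imputation — is the point
of the method: filling values first would let the imputer's assumptions leak
into which genes look informative.  The pipeline therefore never imputes
before the chi-square ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IncompleteMatrix, LabelVector
from .exceptions import ConfigError
from .fbfs import FBFSResult, forward_best_first, make_velm_evaluator
from .imputation import get_imputer
from .mcfs import MCFS, MCFSResults
from .metrics import VELMPipeline, cross_validate, one_vs_rest


@dataclass
class PipelineConfig:
    """Resolved configuration of one FB-MCFS run."""

    alpha: float = 0.001
    n_bins: object = "auto"
    strategy: str = "equal_frequency"
    imputer: str = "mean"
    knn_k: int = 10
    n_hidden: int | None = None
    ensemble: int = 30
    pof: float = 5.0
    patience: int = 5
    folds: int = 10
    trials: int = 20
    metric_mode: str = "standard"
    fold_safe: bool = True
    impute_per_prefix: bool = True
    seed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class FBMCFS:
    """Feature selection + wrapper classification model for incomplete data.

    Parameters mirror :class:`PipelineConfig`; ``fit()`` executes
    rank -> (impute) -> forward search -> evaluation and returns a
    :class:`FBMCFSResults`.
    """

    def __init__(self, X: IncompleteMatrix, y, config: PipelineConfig | None = None,
                 **overrides):
        if not isinstance(X, IncompleteMatrix):
            X = IncompleteMatrix.from_values(np.asarray(X, dtype=float))
        if not isinstance(y, LabelVector):
            y = LabelVector(np.asarray(y, dtype=object))
        self.X = X
        self.y = y
        cfg = config or PipelineConfig()
        for k, v in overrides.items():
            if not hasattr(cfg, k):
                raise ConfigError(f"unknown pipeline parameter {k!r}")
            setattr(cfg, k, v)
        self.config = cfg

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "class", **kwargs):
        y = LabelVector(df[label].to_numpy(dtype=object))
        data = df.drop(columns=[label])
        X = IncompleteMatrix.from_values(data.to_numpy(dtype=float),
                                         list(data.columns),
                                         [str(i) for i in data.index])
        return cls(X, y, **kwargs)

    def _imputer(self):
        cfg = self.config
        if cfg.imputer == "knn":
            return get_imputer("knn", k=cfg.knn_k)
        return get_imputer(cfg.imputer)

    def fit(self) -> "FBMCFSResults":
        cfg = self.config
        ranking = MCFS(self.X, self.y, alpha=cfg.alpha, n_bins=cfg.n_bins,
                       strategy=cfg.strategy).fit()
        order = ranking.selected
        if len(order) == 0:
            # nothing passes the threshold: fall back to the full ranking so
            # the wrapper still has something to search
            order = ranking.order
        evaluator = make_velm_evaluator(
            imputer=self._imputer(), n_hidden=cfg.n_hidden,
            n_estimators=cfg.ensemble, folds=cfg.folds,
            fold_safe=cfg.fold_safe)
        search = forward_best_first(
            order, self.X, self.y, evaluator, pof=cfg.pof,
            patience=cfg.patience, imputer=self._imputer(),
            impute_per_prefix=cfg.impute_per_prefix, seed=cfg.seed)
        return FBMCFSResults(self, ranking, search)


class FBMCFSResults:
    """Ranking, search trajectory and final-subset evaluation."""

    def __init__(self, model: FBMCFS, ranking: MCFSResults, search: FBFSResult):
        self.model = model
        self.ranking = ranking
        self.search = search

    @property
    def selected_features(self) -> list[str]:
        names = self.model.X.feature_names
        return [names[j] for j in self.search.best_subset]

    @property
    def best_score(self) -> float:
        return self.search.best_score

    def evaluate(self, trials: int | None = None):
        """Repeated stratified CV of the final subset; returns
        (per-trial scores array, per-class reports, macro report)."""
        cfg = self.model.config
        trials = cfg.trials if trials is None else trials
        subset = self.search.best_subset or list(self.ranking.order)
        X_sub = self.model.X.subset_features(subset)

        def factory(trial_seed):
            return VELMPipeline(imputer=self.model._imputer(),
                                n_hidden=cfg.n_hidden,
                                n_estimators=cfg.ensemble, seed=trial_seed)

        scores = cross_validate(X_sub, self.model.y, factory, folds=cfg.folds,
                                trials=trials, seed=cfg.seed,
                                fold_safe=cfg.fold_safe)
        # one deterministic refit on everything for the per-class breakdown
        pipe = factory(cfg.seed)
        keep = self.model.y.observed
        X_obs = X_sub.subset_samples(np.where(keep)[0])
        y_obs = self.model.y.labels[keep]
        pipe.fit(X_obs, y_obs)
        preds = pipe.predict(X_obs)
        decision = pipe.decision_function(X_obs)
        per_class, macro = one_vs_rest(y_obs, preds, decision,
                                       mode=cfg.metric_mode)
        return scores, per_class, macro

    def as_dict(self) -> dict:
        return {
            "config": self.model.config.as_dict(),
            "n_selected_by_filter": int(len(self.ranking.selected)),
            "fbfs": self.search.as_dict(),
            "selected_features": self.selected_features,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def summary(self) -> str:
        cfg = self.model.config
        traj = ", ".join(f"{n}:{s:.3f}" for n, s in self.search.trajectory)
        return "\n".join([
            "FB-MCFS pipeline",
            f"  samples: {self.model.X.n_samples}   features: "
            f"{self.model.X.n_features}   classes: {self.model.y.n_classes}",
            f"  filter: alpha={cfg.alpha:g} -> {len(self.ranking.selected)} features",
            f"  search: pof={cfg.pof:g}% patience={cfg.patience} "
            f"imputer={cfg.imputer}",
            f"  trajectory (size:score): {traj}",
            f"  best subset ({self.search.best_size} features, "
            f"CV score {self.best_score:.4f}):",
            f"    {', '.join(self.selected_features) or '(none)'}",
        ])
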