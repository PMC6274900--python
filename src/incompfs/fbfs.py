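"""Forward best-first search (FBFS) over a ranked feature list.

The search walks prefixes of the ranking: round t evaluates the top
ceil(t * pof/100 * n_ranked) features, where ``pof`` is the percent-of-
features step (K = 100/pof rounds cover the whole list).  Each prefix is
scored by a cross-validated classifier on the imputed sub-matrix; the search
keeps the incumbent best and stops once ``patience`` consecutive rounds fail
to strictly improve it (or the full list is reached).  The returned subset
is always a prefix of the input ranking.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .containers import IncompleteMatrix
from .exceptions import ConfigError, IncompfsError

logger = logging.getLogger(__name__)


@dataclass
class FBFSResult:
    """Trajectory and outcome of one forward best-first search."""

    trajectory: list = field(default_factory=list)  # (prefix_size, score)
    best_subset: list = field(default_factory=list)
    best_score: float = -math.inf
    rounds_evaluated: int = 0
    pof: float = 5.0
    patience_k: int = 5

    @property
    def best_size(self) -> int:
        return len(self.best_subset)

    def as_dict(self) -> dict:
        return {
            "trajectory": [[int(n), float(s)] for n, s in self.trajectory],
            "best_subset": [int(j) for j in self.best_subset],
            "best_score": float(self.best_score),
            "rounds_evaluated": self.rounds_evaluated,
            "pof": self.pof,
            "patience_k": self.patience_k,
        }


def prefix_sizes(n_ranked: int, pof: float) -> list[int]:
    """Prefix size per round: ceil(t * pof/100 * n_ranked), t = 1..K,
    deduplicated (short rankings make consecutive percent steps land on the
    same prefix, which is only evaluated once)."""
    K = math.ceil(100.0 / pof)
    sizes = []
    for t in range(1, K + 1):
        n = min(n_ranked, math.ceil(t * pof / 100.0 * n_ranked))
        if not sizes or n != sizes[-1]:
            sizes.append(n)
    return sizes


def forward_best_first(order, X: IncompleteMatrix, y, evaluator,
                       pof: float = 5.0, patience: int = 5,
                       imputer=None, impute_per_prefix: bool = True,
                       seed: int = 0) -> FBFSResult:
    """Search the best top-ranked feature prefix.

    Parameters
    ----------
    order : sequence of int
        Feature indices into ``X``, best first (an MCFS ranking or its
        selected subset).
    evaluator : callable(X_sub, y, seed) -> float
        Cross-validated scorer; receives the prefix's columns.  With the
        default per-prefix imputation the evaluator sees the incomplete
        sub-matrix and imputes inside its folds; with
        ``impute_per_prefix=False`` the whole matrix is imputed once up
        front with ``imputer`` and prefixes are already complete.
    pof : float in (0, 100]
        Percent-of-features step; K = 100/pof rounds cover everything.
    patience : int >= 1
        Rounds allowed without strict improvement before stopping.
    """
    order = [int(j) for j in order]
    if not order:
        raise ConfigError("ranked feature list is empty")
    if not 0 < pof <= 100:
        raise ConfigError("pof must lie in (0, 100]")
    if patience < 1:
        raise ConfigError("patience must be >= 1")

    if not impute_per_prefix:
        if imputer is None:
            from .imputation import MeanImputer
            imputer = MeanImputer()
        complete = imputer.fit_transform(X.subset_features(order))
        X = IncompleteMatrix.from_values(complete.values,
                                         complete.feature_names,
                                         complete.sample_ids)
        order_pos = list(range(len(order)))
    else:
        order_pos = None

    result = FBFSResult(pof=float(pof), patience_k=int(patience))
    best_size = 0
    stale = 0
    # one evaluation seed for every round: all prefixes are scored on the
    # same CV folds, so score differences reflect the features, not the folds
    eval_seed = int(np.random.SeedSequence(seed).generate_state(1)[0])
    sizes = prefix_sizes(len(order), pof)
    for t, n_t in enumerate(sizes):
        cols = order_pos[:n_t] if order_pos is not None else order[:n_t]
        X_sub = X.subset_features(cols)
        try:
            score = float(evaluator(X_sub, y, eval_seed))
        except IncompfsError:
            raise
        except Exception as exc:
            logger.error("evaluator failed at prefix size %d: %s", n_t, exc)
            raise
        result.trajectory.append((n_t, score))
        result.rounds_evaluated = t + 1
        if score > result.best_score:
            result.best_score = score
            best_size = n_t
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    result.best_subset = order[:best_size]
    return result


def make_velm_evaluator(imputer=None, n_hidden=None, n_estimators: int = 30,
                        folds: int = 10, trials: int = 1,
                        fold_safe: bool = True, scorer=None):
    """Cross-validated V-ELM scorer for FBFS prefixes.

    Folds drop to 5 automatically when any class has fewer than 10 labelled
    members (the usual small-cohort concession); further reduction for even
    rarer classes is handled inside the CV driver.
    """
    from .containers import LabelVector
    from .imputation import MeanImputer
    from .metrics import VELMPipeline, cross_validate

    def evaluate(X_sub, y, seed) -> float:
        if not isinstance(y, LabelVector):
            y = LabelVector(np.asarray(y, dtype=object))
        obs = [v for v in y.labels if v is not None]
        min_class = min(obs.count(c) for c in set(obs))
        eff_folds = folds if min_class >= 10 else min(folds, 5)

        def factory(trial_seed):
            imp = MeanImputer() if imputer is None else copy.deepcopy(imputer)
            return VELMPipeline(imputer=imp, n_hidden=n_hidden,
                                n_estimators=n_estimators, seed=trial_seed)

        scores = cross_validate(X_sub, y, factory, folds=eff_folds,
                                trials=trials, seed=seed, scorer=scorer,
                                fold_safe=fold_safe)
        return float(scores.mean())

    return evaluate
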