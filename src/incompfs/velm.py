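"""Extreme learning machine (ELM) and its majority-vote ensemble (V-ELM).

An ELM is a single-hidden-layer network whose hidden weights and biases are
drawn once, uniformly from [-1, 1], and never trained; with sigmoid
activations the hidden output matrix is H_ij = g(w_j . x_i + b_j) and the
output weights solve the least-squares system H beta = T in closed form via
the Moore-Penrose pseudoinverse, beta = pinv(H) T, with T the one-hot class
targets.  V-ELM trains several independently seeded ELMs on the same data
and predicts by majority vote, which smooths away the boundary samples a
single random hidden layer misclassifies.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.special import expit

from .exceptions import ConfigError, DataError

#: relative SVD cutoff for the pseudoinverse (times the largest singular value)
PINV_RCOND = 1e-12


def _check_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("X must be 2-D (samples x features)")
    if not np.isfinite(X).all():
        raise DataError("X must be finite (impute before training)")
    return X


def default_hidden(n_train: int, cap: int = 100) -> int:
    """Default hidden-neuron count min(cap, n_train - 1): ELM accuracy
    saturates as the hidden layer approaches the training size."""
    return max(1, min(cap, n_train - 1))


class ELMClassifier:
    """Single ELM with sigmoid hidden units and one-hot least-squares output.

    Parameters
    ----------
    n_hidden : int or None
        Hidden-neuron count M; None picks min(100, n_train - 1) at fit time.
    seed : int
        Seed for the hidden layer.  Parameters are drawn one neuron at a
        time, so models sharing a seed share their first min(M, M') neurons
        (growing the hidden layer only appends columns to H).
    """

    def __init__(self, n_hidden: int | None = None, seed: int = 0):
        if n_hidden is not None and n_hidden < 1:
            raise ConfigError("n_hidden must be >= 1")
        self.n_hidden = n_hidden
        self.seed = seed
        self.classes_ = None

    def _hidden_layer(self, d: int, M: int):
        rng = np.random.default_rng(self.seed)
        # row j = [w_j, b_j]; C-order fill makes neuron j independent of M
        wb = rng.uniform(-1.0, 1.0, size=(M, d + 1))
        return wb[:, :d].T, wb[:, d]

    def fit(self, X, y) -> "ELMClassifier":
        X = _check_X(X)
        y = np.asarray(y, dtype=object).ravel()
        if len(y) != X.shape[0]:
            raise DataError("X and y length mismatch")
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        codes = np.array([list(self.classes_).index(v) for v in y])
        T = np.eye(len(self.classes_))[codes]
        M = self.n_hidden if self.n_hidden is not None else default_hidden(len(y))
        self.W_, self.b_ = self._hidden_layer(X.shape[1], M)
        H = expit(X @ self.W_ + self.b_)
        self.beta_ = np.linalg.pinv(H, rcond=PINV_RCOND) @ T
        return self

    def decision_function(self, X) -> np.ndarray:
        X = _check_X(X)
        if X.shape[1] != self.W_.shape[0]:
            raise DataError(
                f"expected {self.W_.shape[0]} features, got {X.shape[1]}")
        return expit(X @ self.W_ + self.b_) @ self.beta_

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def training_residual(self, X, y) -> float:
        """Frobenius norm of H beta - T on (X, y)."""
        y = np.asarray(y, dtype=object).ravel()
        codes = np.array([list(self.classes_).index(v) for v in y])
        T = np.eye(len(self.classes_))[codes]
        return float(np.linalg.norm(self.decision_function(X) - T))


class VELMClassifier:
    """Majority-vote ensemble of independently seeded ELMs (default 30).

    All members are trained on the identical data; only the hidden layers
    differ.  Ties are broken by the summed continuous outputs, then by class
    index.
    """

    def __init__(self, n_hidden: int | None = None, n_estimators: int = 30,
                 seed: int = 0):
        if n_estimators < 1:
            raise ConfigError("n_estimators must be >= 1")
        self.n_hidden = n_hidden
        self.n_estimators = int(n_estimators)
        self.seed = seed
        self.models_ = None

    def member_seeds(self) -> np.ndarray:
        ss = np.random.SeedSequence(self.seed)
        return ss.generate_state(self.n_estimators)

    def fit(self, X, y) -> "VELMClassifier":
        self.models_ = [ELMClassifier(self.n_hidden, seed=int(s)).fit(X, y)
                        for s in self.member_seeds()]
        self.classes_ = self.models_[0].classes_
        return self

    def predict(self, X) -> np.ndarray:
        if not self.models_:
            raise ConfigError("ensemble is not fitted")
        votes = np.stack([m.predict(X) for m in self.models_])   # (E, n)
        scores = sum(m.decision_function(X) for m in self.models_)
        out = np.empty(votes.shape[1], dtype=object)
        class_list = list(self.classes_)
        for i in range(votes.shape[1]):
            counts = Counter(votes[:, i])
            top = max(counts.values())
            tied = [c for c, v in counts.items() if v == top]
            if len(tied) == 1:
                out[i] = tied[0]
            else:
                tied.sort(key=lambda c: (-scores[i, class_list.index(c)],
                                         class_list.index(c)))
                out[i] = tied[0]
        return out

    def decision_function(self, X) -> np.ndarray:
        """Ensemble-summed continuous outputs (used for AUC scores)."""
        return sum(m.decision_function(X) for m in self.models_)
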