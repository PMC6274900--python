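"""Class-structured synthetic expression matrices with controlled missingness.

The generator emulates the structure the selection method assumes: a handful
of class-discriminative genes among many noise genes, with missing entries.
Informative features get class-dependent Gaussian means spaced
``effect_size`` standard deviations apart; noise features are class-
independent standard normals.  Missingness is either MCAR (every cell masked
independently at ``missing_rate``) or MAR (a fully observed "driver" feature
modulates each sample's masking probability through a logistic link whose
intercept is calibrated so the overall rate matches ``missing_rate``).
Values are finally min-max normalised to [-0.9, 0.9] over observed cells,
matching the preprocessing applied to real expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .containers import IncompleteMatrix, LabelVector
from .exceptions import ConfigError
from .io_preprocess import minmax_normalize


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults describe a small three-class cohort
    typical of the expression studies the method targets."""

    n_samples: int = 60
    n_features: int = 100
    n_informative: int = 5
    n_classes: int = 3
    effect_size: float = 2.0
    missing_rate: float = 0.1
    mechanism: str = "MCAR"
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < self.n_classes:
            raise ConfigError("need at least one sample per class")
        if not 0 <= self.n_informative <= self.n_features:
            raise ConfigError("n_informative must lie in [0, n_features]")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ConfigError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "MAR" and self.n_informative >= self.n_features:
            raise ConfigError("MAR needs at least one non-informative driver feature")


def _calibrate_intercept(z: np.ndarray, rate: float) -> float:
    """Intercept c with mean(sigmoid(z + c)) == rate, by bisection."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if expit(z + mid).mean() < rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_dataset(spec: SyntheticSpec):
    """Draw one dataset; returns (IncompleteMatrix, LabelVector, informative
    feature index array).  Identical seeds give bit-identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, C = spec.n_samples, spec.n_features, spec.n_classes

    labels = np.array([f"c{i % C}" for i in range(n)], dtype=object)
    rng.shuffle(labels)
    class_idx = np.array([int(v[1:]) for v in labels])

    values = rng.standard_normal((n, p))
    informative = np.arange(spec.n_informative)
    # class means centred around zero, consecutive classes effect_size apart
    class_means = (np.arange(C) - (C - 1) / 2.0) * spec.effect_size
    for j in informative:
        values[:, j] += class_means[class_idx]

    mask = np.ones((n, p), dtype=bool)
    if spec.missing_rate > 0:
        if spec.mechanism == "MCAR":
            mask = rng.random((n, p)) >= spec.missing_rate
        else:  # MAR: last feature drives missingness and stays observed
            driver = p - 1
            z = values[:, driver]
            z = (z - z.mean()) / (z.std() or 1.0)
            p_miss = expit(z + _calibrate_intercept(z, spec.missing_rate))
            mask = rng.random((n, p)) >= p_miss[:, None]
            mask[:, driver] = True
        # keep every feature scorable: re-observe one random cell of any
        # feature the mask emptied entirely
        for j in np.where(~mask.any(axis=0))[0]:
            mask[rng.integers(n), j] = True

    X = IncompleteMatrix(np.where(mask, values, np.nan), mask,
                         [f"g{j}" for j in range(p)],
                         [f"s{i}" for i in range(n)])
    return minmax_normalize(X), LabelVector(labels), informative
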