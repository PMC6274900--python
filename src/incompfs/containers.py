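"""In-memory containers for incomplete expression data.

The canonical layout everywhere in the package is samples x features.
Missingness is explicit: an ``IncompleteMatrix`` carries a boolean mask
(True = observed) next to its values, and every downstream statistic ignores
unobserved cells.  Values at unobserved positions are stored as NaN so that
accidental use is loud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError


@dataclass
class IncompleteMatrix:
    """Real-valued samples x features grid with an explicit missingness mask.

    Parameters
    ----------
    values : ndarray of float, shape (n_samples, n_features)
        Expression values; entries at unobserved cells are forced to NaN.
    mask : ndarray of bool, same shape
        True where the cell is observed.
    feature_names, sample_ids : sequences of str
        Unique feature names; sample identifiers.
    """

    values: np.ndarray
    mask: np.ndarray
    feature_names: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).copy()
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape != self.mask.shape:
            raise DataError(
                f"values {self.values.shape} and mask {self.mask.shape} must be "
                "2-D arrays of identical shape"
            )
        n, p = self.values.shape
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(p)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        self.feature_names = [str(f) for f in self.feature_names]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_names) != p:
            raise DataError("feature_names length does not match n_features")
        if len(self.sample_ids) != n:
            raise DataError("sample_ids length does not match n_samples")
        if len(set(self.feature_names)) != p:
            raise DataError("feature_names must be unique")
        self.values[~self.mask] = np.nan

    @classmethod
    def from_values(cls, values, feature_names=None, sample_ids=None):
        """Build from a float array where NaN marks missing cells."""
        values = np.asarray(values, dtype=float)
        return cls(values, ~np.isnan(values), feature_names, sample_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int((~self.mask).sum())

    def column(self, j: int):
        """Return (values, mask) of feature ``j``."""
        return self.values[:, j], self.mask[:, j]

    def subset_features(self, indices) -> "IncompleteMatrix":
        indices = np.asarray(indices, dtype=int)
        return IncompleteMatrix(
            self.values[:, indices],
            self.mask[:, indices],
            [self.feature_names[j] for j in indices],
            list(self.sample_ids),
        )

    def subset_samples(self, indices) -> "IncompleteMatrix":
        indices = np.asarray(indices, dtype=int)
        return IncompleteMatrix(
            self.values[indices],
            self.mask[indices],
            list(self.feature_names),
            [self.sample_ids[i] for i in indices],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_names)


@dataclass
class LabelVector:
    """Per-sample categorical class labels; missing labels are allowed.

    ``labels`` is an object array; missing entries are None.  ``classes``
    enumerates the distinct observed labels in sorted order.
    """

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=object).ravel()
        norm = np.empty(lab.shape, dtype=object)
        for i, v in enumerate(lab):
            missing = v is None or (isinstance(v, float) and np.isnan(v))
            norm[i] = None if missing else str(v)
        self.labels = norm

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def observed(self) -> np.ndarray:
        return np.array([v is not None for v in self.labels])

    @property
    def classes(self) -> list[str]:
        return sorted({v for v in self.labels if v is not None})

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def codes(self) -> np.ndarray:
        """Integer class codes in ``classes`` order; -1 for missing."""
        lookup = {c: i for i, c in enumerate(self.classes)}
        return np.array([lookup.get(v, -1) for v in self.labels], dtype=int)


@dataclass
class DiscretizedFeature:
    """Ordered integer categories for one feature; -1 marks missing.

    Codes are order-preserving in the raw values so that adjacent rows of the
    contingency table correspond to adjacent value ranges (required for the
    row-merging stabilisation).
    """

    codes: np.ndarray
    bin_edges: np.ndarray
    m: int
    degenerate: bool = False

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=int)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        observed = self.codes[self.codes >= 0]
        if not self.degenerate and observed.size:
            if observed.max() >= self.m:
                raise DataError("codes exceed declared category count m")


@dataclass
class CompleteMatrix:
    """Fully observed matrix plus the provenance of its imputation."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    provenance: dict

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise DataError("CompleteMatrix contains NaN entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_names)
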