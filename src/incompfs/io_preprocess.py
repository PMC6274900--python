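"""Reading, writing and preprocessing incomplete expression tables.

Tables are delimited text (TSV/CSV) with a header.  Two orientations are
supported: ``samples_rows`` (rows = samples, one label column) and
``features_rows`` (rows = features, one label row); internally everything is
normalised to samples x features.  Cells equal to a missing token ("?", "NA"
or empty by default) become unobserved; any other non-numeric cell raises a
:class:`~incompfs.exceptions.FormatError` naming the offending row/column.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .containers import DiscretizedFeature, IncompleteMatrix, LabelVector
from .exceptions import ConfigError, DegenerateFeatureError, FormatError

DEFAULT_MISSING_TOKENS = frozenset({"?", "NA", ""})

#: normalisation range used throughout (expression values are mapped here)
NORM_LO, NORM_HI = -0.9, 0.9


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_table(path, orientation: str = "samples_rows",
                          missing_tokens=DEFAULT_MISSING_TOKENS,
                          label_field: str = "class"):
    """Read a delimited expression table with a class-label field.

    Returns ``(IncompleteMatrix, LabelVector)`` in samples x features layout.
    ``orientation`` says whether rows of the file are samples or features; in
    the latter case the label row is named ``label_field`` in the first
    column.  Labels equal to a missing token are recorded as missing.
    """
    if orientation not in ("samples_rows", "features_rows"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    missing_tokens = set(missing_tokens)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                     keep_default_na=False)
    if orientation == "features_rows":
        df = df.T
    if label_field not in df.columns:
        raise ConfigError(
            f"label field {label_field!r} not found among columns "
            f"{list(df.columns)[:10]}..."
        )
    raw_labels = df[label_field]
    labels = LabelVector(np.array(
        [None if str(v).strip() in missing_tokens else str(v).strip()
         for v in raw_labels], dtype=object))
    data = df.drop(columns=[label_field])

    n, p = data.shape
    values = np.full((n, p), np.nan)
    mask = np.zeros((n, p), dtype=bool)
    for j, col in enumerate(data.columns):
        for i, cell in enumerate(data[col]):
            token = str(cell).strip()
            if token in missing_tokens:
                continue
            try:
                values[i, j] = float(token)
            except ValueError:
                raise FormatError(
                    f"unparseable cell {cell!r} at row {data.index[i]!r}, "
                    f"column {col!r}"
                ) from None
            mask[i, j] = True
    X = IncompleteMatrix(values, mask, list(data.columns), list(data.index))
    return X, labels


def write_expression_table(X: IncompleteMatrix, labels: LabelVector | None,
                           path, missing_token: str = "?",
                           label_field: str = "class") -> None:
    """Write the matrix (plus optional labels) in the dialect readers accept."""
    df = X.to_frame().astype(object)
    df = df.where(pd.notna(df), other=missing_token)
    # repr() of float round-trips bit-exactly through float()
    df = df.map(lambda v: repr(v) if isinstance(v, float) else v)
    if labels is not None:
        df[label_field] = [missing_token if v is None else v
                           for v in labels.labels]
    df.to_csv(path, sep=_sep_for(path), index_label="sample")


def minmax_normalize(X: IncompleteMatrix) -> IncompleteMatrix:
    """Min–max normalise each feature to [-0.9, 0.9] over observed values.

    x' = -0.9 + (x - min) / (max - min) * 1.8, with min/max taken per feature
    over observed cells only.  Constant features map to 0 (the range
    midpoint); features with no observed value raise.
    """
    dead = [X.feature_names[j] for j in range(X.n_features)
            if not X.mask[:, j].any()]
    if dead:
        raise DegenerateFeatureError(dead, f"features with no observed value: {dead}")
    with np.errstate(invalid="ignore"):
        lo = np.nanmin(X.values, axis=0)
        hi = np.nanmax(X.values, axis=0)
    span = hi - lo
    out = np.full_like(X.values, np.nan)
    const = span == 0
    safe = np.where(const, 1.0, span)
    out = NORM_LO + (X.values - lo) / safe * (NORM_HI - NORM_LO)
    out[:, const] = 0.0
    out[~X.mask] = np.nan
    return IncompleteMatrix(out, X.mask.copy(), list(X.feature_names),
                            list(X.sample_ids))


def auto_n_bins(n_observed: int, cap: int = 5) -> int:
    """Default bin count: min(cap, floor(sqrt(n_observed))), at least 2."""
    return max(2, min(cap, int(math.floor(math.sqrt(max(n_observed, 0))))))


def discretize_feature(x, mask=None, n_bins: int | str = "auto",
                       strategy: str = "equal_frequency") -> DiscretizedFeature:
    """Discretise one feature column into ordered integer categories.

    Strategies: ``equal_frequency`` (quantile cuts; duplicate edges collapse,
    so the realised category count m may be below ``n_bins``), ``equal_width``
    (uniform cuts over the observed range) and ``distinct`` (every distinct
    observed value is its own ordered category — appropriate for data that is
    already categorical, encoded numerically).

    Missing entries keep code -1.  All-missing or constant features come back
    flagged ``degenerate`` (they receive p-value 1 downstream, never a crash).
    """
    x = np.asarray(x, dtype=float)
    if mask is None:
        mask = ~np.isnan(x)
    mask = np.asarray(mask, dtype=bool) & ~np.isnan(x)
    obs = x[mask]
    uniq = np.unique(obs)

    codes = np.full(x.shape, -1, dtype=int)
    if uniq.size < 2:
        return DiscretizedFeature(codes, np.array([]), 0, degenerate=True)

    if n_bins == "auto":
        n_bins = auto_n_bins(obs.size)
    if not isinstance(n_bins, (int, np.integer)) or n_bins < 2:
        raise ConfigError("n_bins must be an integer >= 2 or 'auto'")

    if strategy == "distinct":
        edges = (uniq[:-1] + uniq[1:]) / 2.0
        raw = np.searchsorted(edges, obs, side="left")
    elif strategy == "equal_frequency":
        qs = np.quantile(obs, np.linspace(0, 1, n_bins + 1)[1:-1])
        edges = np.unique(qs)
        # right-closed bins: a value equal to a quantile edge stays in the
        # lower bin, so heavy ties collapse bins rather than empty them
        raw = np.searchsorted(edges, obs, side="left")
    elif strategy == "equal_width":
        edges = np.linspace(uniq[0], uniq[-1], n_bins + 1)[1:-1]
        raw = np.searchsorted(edges, obs, side="right")
    else:
        raise ConfigError(f"unknown discretization strategy {strategy!r}")

    # relabel to consecutive 0..m-1 over occupied bins, preserving order
    occupied = np.unique(raw)
    remap = {b: i for i, b in enumerate(occupied)}
    codes[mask] = np.array([remap[b] for b in raw], dtype=int)
    return DiscretizedFeature(codes, edges, len(occupied))
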