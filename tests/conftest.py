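"""Shared fixtures: the published worked example and small helpers.

The worked example is an 8-record table with three ordinal features (wind,
humidity, temperature), a yes/no class label and four missing cells; ordinal
levels are coded low=0, medium=1, high=2.
"""

import numpy as np
import pytest

from incompfs import IncompleteMatrix, LabelVector

NAN = np.nan

# rows u1..u8, columns a1 (wind), a2 (humidity), a3 (temperature)
TABLE9_VALUES = np.array([
    [0, 0, 2],
    [1, 1, 1],
    [2, 2, NAN],
    [0, 1, 2],
    [NAN, NAN, 2],
    [1, 2, 0],
    [NAN, 0, 0],
    [2, 2, 2],
])
TABLE9_LABELS = ["yes", "yes", "yes", "no", "no", "yes", "yes", "no"]
LEVELS = {0: "low", 1: "medium", 2: "high"}


@pytest.fixture
def table9():
    X = IncompleteMatrix.from_values(
        TABLE9_VALUES, feature_names=["a1", "a2", "a3"],
        sample_ids=[f"u{i}" for i in range(1, 9)])
    return X, LabelVector(np.array(TABLE9_LABELS, dtype=object))


@pytest.fixture
def table9_tsv(tmp_path):
    path = tmp_path / "table9.tsv"
    rows = ["sample\ta1\ta2\ta3\tclass"]
    for i, (vals, lab) in enumerate(zip(TABLE9_VALUES, TABLE9_LABELS), 1):
        cells = ["?" if np.isnan(v) else str(int(v)) for v in vals]
        rows.append(f"u{i}\t" + "\t".join(cells) + f"\t{lab}")
    path.write_text("\n".join(rows) + "\n")
    return path


def make_blobs(seed, n=40, d=2, sep=2.0, sd=0.5):
    """Two well-separated Gaussian blobs with string labels."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([rng.normal(-sep, sd, (half, d)),
                   rng.normal(sep, sd, (n - half, d))])
    y = np.array(["A"] * half + ["B"] * (n - half), dtype=object)
    idx = rng.permutation(n)
    return X[idx], y[idx]
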