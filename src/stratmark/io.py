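"""Readers and writers for expression matrices, labels and result tables.

Matrices are plain TSV/CSV: first column = sample ID, header = feature
IDs (or the transpose, with ``orientation="features_by_samples"``).
Labels are a two-column table (sample ID, 0/1 outcome). Delimiters are
auto-detected between tab and comma. Malformed numeric cells raise with
row/column context rather than being coerced.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import DatasetError, ExpressionDataset

__all__ = ["read_dataset", "write_dataset", "read_matrix", "read_labels"]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(path, orientation: str = "samples_by_features") -> pd.DataFrame:
    """Read a numeric matrix, normalizing to samples x features.

    ``orientation`` is the on-disk layout; ``"features_by_samples"``
    inputs are transposed after reading.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"matrix file not found: {path}")
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise DatasetError(f"unknown orientation: {orientation!r}")
    sep = _sniff_delimiter(path)
    try:
        # round_trip parsing keeps float64 values bit-exact
        numeric = pd.read_csv(path, sep=sep, index_col=0,
                              float_precision="round_trip")
        numeric = numeric.astype(float)
    except (TypeError, ValueError):
        # re-read as text purely to name the offending cell
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        r, c = np.argwhere((bad | df.isna()).to_numpy())[0]
        raise DatasetError(
            f"non-numeric cell {df.iloc[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        ) from None
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DatasetError(
            f"missing value at row {numeric.index[r]!r}, "
            f"column {numeric.columns[c]!r} in {path}"
        )
    if orientation == "features_by_samples":
        numeric = numeric.T
    return numeric


def read_labels(path) -> pd.Series:
    """Read a two-column (sample ID, 0/1 label) table."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"label file not found: {path}")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise DatasetError(f"label file needs two columns (sample ID, label): {path}")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise DatasetError(f"duplicate sample IDs in label file: "
                           f"{ids[ids.duplicated()].tolist()[:5]}")
    try:
        lab = pd.to_numeric(df.iloc[:, 1])
    except (TypeError, ValueError) as exc:
        raise DatasetError(f"non-numeric label in {path}: {exc}") from exc
    return pd.Series(lab.to_numpy(), index=pd.Index(ids, name="sample_id"))


def read_dataset(matrix_path, labels_path,
                 orientation: str = "samples_by_features") -> ExpressionDataset:
    """Load and match a matrix and its labels into an :class:`ExpressionDataset`.

    Samples are matched to labels by ID, order-independently. Samples in
    the matrix without a label, or labelled samples absent from the
    matrix, raise an error naming the offending IDs.
    """
    values = read_matrix(matrix_path, orientation=orientation)
    labels = read_labels(labels_path)
    unknown = labels.index.difference(values.index)
    if len(unknown) > 0:
        raise DatasetError(
            f"label file mentions unknown sample IDs: {unknown.tolist()[:5]}"
        )
    return ExpressionDataset(values, labels)


def write_dataset(dataset: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write matrix and label TSVs that :func:`read_dataset` round-trips."""
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    out = dataset.values.copy()
    out.index.name = "sample_id"
    # %.17g keeps float64 values bit-exact across a write/read cycle
    out.to_csv(matrix_path, sep="\t", float_format="%.17g")
    lab = dataset.labels.rename("label")
    lab.index.name = "sample_id"
    lab.to_csv(labels_path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
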