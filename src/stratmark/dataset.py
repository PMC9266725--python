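"""Sample-by-feature expression matrix with a binary per-sample outcome.

The container is a thin, validated wrapper around a pandas DataFrame
(rows = samples, columns = features) and an aligned 0/1 label Series.
All downstream stages (relevance filtering, clustering, cross-validated
protocols, evaluation) consume this one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "DatasetError"]


class DatasetError(ValueError):
    """Raised for malformed or inconsistent dataset inputs."""


@dataclass
class ExpressionDataset:
    """Expression values for a cohort with a binary outcome.

    Parameters
    ----------
    values
        DataFrame of shape (n_samples, n_features); index = sample IDs,
        columns = feature IDs. All entries must be finite numbers.
    labels
        Series of 0/1 outcome labels indexed by sample ID. Reordered to
        match ``values.index`` on construction; every sample must have a
        label.
    """

    values: pd.DataFrame
    labels: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate sample IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate feature IDs: {dups[:5]}")
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"non-numeric expression values: {exc}") from exc
        if not np.isfinite(self.values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.values.to_numpy()))[0]
            raise DatasetError(
                f"non-finite value at sample {self.values.index[bad[0]]!r}, "
                f"feature {self.values.columns[bad[1]]!r}"
            )
        missing = self.values.index.difference(self.labels.index)
        if len(missing) > 0:
            raise DatasetError(f"samples without labels: {missing.tolist()[:5]}")
        self.labels = self.labels.reindex(self.values.index)
        lab = self.labels.to_numpy()
        if not np.isin(lab, [0, 1]).all():
            raise DatasetError("labels must be binary 0/1")
        self.labels = self.labels.astype(int)

    # -- basic views ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def y(self) -> np.ndarray:
        """Outcome labels as an int array aligned with ``values`` rows."""
        return self.labels.to_numpy()

    @property
    def X(self) -> np.ndarray:
        """Expression values as a float array (n_samples, n_features)."""
        return self.values.to_numpy()

    # -- subsetting -----------------------------------------------------
    def subset_samples(self, idx) -> "ExpressionDataset":
        """Row subset by positional indices (e.g. a CV fold)."""
        return ExpressionDataset(self.values.iloc[idx], self.labels.iloc[idx])

    def subset_features(self, feature_ids) -> "ExpressionDataset":
        feature_ids = list(feature_ids)
        missing = [f for f in feature_ids if f not in self.values.columns]
        if missing:
            raise DatasetError(f"unknown feature IDs: {missing[:5]}")
        return ExpressionDataset(self.values[feature_ids], self.labels)

    def zero_variance_features(self) -> list[str]:
        """Feature IDs constant across all samples (sample variance exactly 0)."""
        arr = self.X
        const = (arr == arr[0]).all(axis=0)
        return [f for f, c in zip(self.feature_ids, const) if c]

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        y = self.y
        return int((y == 0).sum()), int((y == 1).sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return self.values.equals(other.values) and self.labels.equals(other.labels)
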