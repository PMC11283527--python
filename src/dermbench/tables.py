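"""Labeled feature tables: the in-memory currency between pipeline stages.

A :class:`LabeledFeatureTable` holds a samples x features matrix of deep
embeddings (or any numeric features) together with per-sample class labels.
Synthetic tables additionally carry a ground-truth mask of informative
columns so selector recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DataFormatError",
    "LabeledFeatureTable",
    "read_feature_table",
    "write_feature_table",
]

LABEL_COLUMN = "label"


class DataFormatError(ValueError):
    """A feature-table file violates the expected delimited-text layout."""


@dataclass
class LabeledFeatureTable:
    """Samples x features matrix with class labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Feature matrix; must be finite.
    labels : ndarray of shape (n_samples,)
        Class label per row, stored as strings.
    feature_ids : list of str
        Unique, ordered column identifiers.
    informative_mask : ndarray of bool, optional
        Ground-truth indicator of class-separating columns; present only on
        synthetic tables.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    informative_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=str)
        self.feature_ids = list(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("number of labels must equal number of rows")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length must equal number of columns")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite (no missing values)")
        if self.informative_mask is not None:
            self.informative_mask = np.asarray(self.informative_mask, dtype=bool)
            if self.informative_mask.shape != (self.values.shape[1],):
                raise ValueError("informative_mask length must equal number of columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_ids(self) -> list[str]:
        """Sorted distinct labels."""
        return sorted(set(self.labels.tolist()))

    def subset_rows(self, index: np.ndarray) -> "LabeledFeatureTable":
        return LabeledFeatureTable(
            values=self.values[index],
            labels=self.labels[index],
            feature_ids=self.feature_ids,
            informative_mask=self.informative_mask,
        )

    def subset_columns(self, mask: np.ndarray) -> "LabeledFeatureTable":
        mask = np.asarray(mask, dtype=bool)
        ids = [f for f, m in zip(self.feature_ids, mask) if m]
        informative = (
            self.informative_mask[mask] if self.informative_mask is not None else None
        )
        return LabeledFeatureTable(
            values=self.values[:, mask],
            labels=self.labels,
            feature_ids=ids,
            informative_mask=informative,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df[LABEL_COLUMN] = self.labels
        return df


def write_feature_table(table: LabeledFeatureTable, path) -> None:
    """Write a table as CSV: header of feature ids plus a ``label`` column."""
    # Default float formatting is the shortest round-trip repr.
    table.to_dataframe().to_csv(path, index=False)


def read_feature_table(path) -> LabeledFeatureTable:
    """Read a delimited-text feature table written by :func:`write_feature_table`.

    Raises
    ------
    DataFormatError
        If the label column is missing, rows are ragged, or feature cells are
        non-numeric.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows
        raise DataFormatError(f"malformed feature table {path!s}: {exc}") from exc
    if LABEL_COLUMN not in df.columns:
        raise DataFormatError(f"{path!s}: missing required '{LABEL_COLUMN}' column")
    labels = df[LABEL_COLUMN].astype(str).to_numpy()
    features = df.drop(columns=[LABEL_COLUMN])
    try:
        values = features.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"{path!s}: non-numeric feature cell: {exc}") from exc
    if np.isnan(values).any():
        raise DataFormatError(f"{path!s}: missing values in feature columns")
    return LabeledFeatureTable(
        values=values,
        labels=labels,
        feature_ids=[str(c) for c in features.columns],
    )
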