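"""Sample-by-feature tables: the currency every pipeline stage trades in.

A :class:`FeatureTable` is a thin immutable wrapper around a numeric
``(n_samples, n_features)`` matrix plus feature names, per-sample class
labels and sample identifiers. Loading is strict: missing or non-numeric
cells are rejected rather than imputed — imputation is preprocessing that
belongs upstream of feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = ["FeatureTable", "load_feature_table", "save_feature_table", "subset_features"]


@dataclass(frozen=True)
class FeatureTable:
    """Numeric matrix with named feature columns and categorical labels.

    Parameters
    ----------
    values
        Float matrix of shape ``(n_samples, n_features)``; no NaN/inf.
    feature_names
        Unique column names, one per matrix column.
    labels
        Class label per row; at least two distinct classes unless
        ``allow_single_class`` paths construct it internally.
    sample_ids
        Unique row identifiers.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise DataError(f"feature matrix must be 2-D, got shape {values.shape}")
        n, p = values.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise DataError(
                f"row count {n} does not match labels ({len(self.labels)}) "
                f"or sample_ids ({len(self.sample_ids)})"
            )
        if len(self.feature_names) != p:
            raise DataError(
                f"column count {p} does not match feature_names ({len(self.feature_names)})"
            )
        if len(set(self.feature_names)) != p:
            raise DataError("feature names must be unique")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise DataError(
                f"missing value at row {self.sample_ids[r]!r}, "
                f"column {self.feature_names[c]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct labels in first-appearance order (stable encoding)."""
        seen: dict[str, None] = {}
        for l in self.labels:
            seen.setdefault(l, None)
        return tuple(seen)

    def encoded_labels(self) -> np.ndarray:
        """Integer labels, encoded by first appearance order."""
        index = {c: i for i, c in enumerate(self.classes)}
        return np.array([index[l] for l in self.labels], dtype=int)

    def take_rows(self, indices: Sequence[int], sample_ids: Sequence[str] | None = None) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        ids = tuple(sample_ids) if sample_ids is not None else tuple(
            self.sample_ids[i] for i in idx
        )
        return FeatureTable(
            values=self.values[idx],
            feature_names=self.feature_names,
            labels=tuple(self.labels[i] for i in idx),
            sample_ids=ids,
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names),
                          index=list(self.sample_ids))
        df.index.name = "sample_id"
        df[label_column] = list(self.labels)
        return df

    def __eq__(self, other: object) -> bool:  # value equality, for round-trip tests
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and self.labels == other.labels
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


def load_feature_table(
    path: str | Path,
    label_column: str,
    delimiter: str = ",",
    sample_id_column: str | None = None,
) -> FeatureTable:
    """Read a delimited sample-by-feature file into a :class:`FeatureTable`.

    The header row is required. ``label_column`` is removed from the matrix
    and used as class labels; every remaining cell must parse as a number.
    When ``sample_id_column`` is None, row numbers become sample ids.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not in header {list(df.columns)}"
        )
    labels = df.pop(label_column)
    if labels.isna().any():
        row = labels.index[labels.isna()][0]
        raise DataError(f"missing class label at row {row}")
    if sample_id_column is not None:
        if sample_id_column not in df.columns:
            raise ConfigurationError(
                f"sample-id column {sample_id_column!r} not in header"
            )
        sample_ids = [str(s) for s in df.pop(sample_id_column)]
    else:
        sample_ids = [f"s{i}" for i in range(len(df))]

    # exact parse: numpy's str->float conversion round-trips full precision,
    # unlike pandas' fast to_numeric path
    try:
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError):
        values = None
    if values is None or np.isnan(values).any():
        for i, (_, row) in enumerate(df.iterrows()):
            for c, cell in row.items():
                if pd.isna(cell):
                    raise DataError(
                        f"missing value at row {sample_ids[i]!r}, column {c!r}"
                    )
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise DataError(
                        f"non-numeric ({cell!r}) value at row "
                        f"{sample_ids[i]!r}, column {c!r}"
                    ) from None
        raise DataError("feature matrix failed to parse as numeric")
    numeric = pd.DataFrame(values, columns=df.columns)
    if labels.nunique() < 2:
        raise DataError(f"need at least 2 label classes, found {labels.nunique()}")
    return FeatureTable(
        values=numeric.to_numpy(dtype=float),
        feature_names=tuple(str(c) for c in df.columns),
        labels=tuple(str(l) for l in labels),
        sample_ids=tuple(sample_ids),
    )


def save_feature_table(
    table: FeatureTable,
    path: str | Path,
    label_column: str = "label",
    delimiter: str = ",",
    write_sample_ids: bool = False,
) -> None:
    """Write a table as delimited text with a trailing label column."""
    df = table.to_frame(label_column)
    df.to_csv(path, sep=delimiter, index=write_sample_ids,
              float_format="%.17g")


def subset_features(table: FeatureTable, keep: Sequence[str]) -> FeatureTable:
    """Return a table with exactly the columns in ``keep``, in that order."""
    index = {name: i for i, name in enumerate(table.feature_names)}
    missing = [k for k in keep if k not in index]
    if missing:
        raise KeyError(f"unknown feature name(s): {missing}")
    cols = [index[k] for k in keep]
    values = table.values[:, cols] if cols else np.empty((table.n_samples, 0))
    return FeatureTable(
        values=values,
        feature_names=tuple(keep),
        labels=table.labels,
        sample_ids=table.sample_ids,
    )
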