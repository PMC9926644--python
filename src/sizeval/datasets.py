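"""Two-class labelled feature tables.

:class:`LabeledDataset` is the in-memory container shared by every module:
a numeric sample-by-variable matrix plus one binary class label per row.
CSV round-tripping goes through pandas; a header row is required and the
label column is configurable by name.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TwoClassViolationError

__all__ = ["LabeledDataset", "load_csv"]


@dataclass
class LabeledDataset:
    """Numeric feature matrix with a class label per sample.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_variables)
        Real-valued measurements; rows are samples, columns are variables.
    labels : ndarray of shape (n_samples,)
        Class identifier per row. Effect sizes and evaluation require
        exactly two distinct values with at least two samples each.
    variable_names : list of str, optional
        Per-column identifiers; defaults to ``var_0 .. var_{v-1}``.
    """

    values: np.ndarray
    labels: np.ndarray
    variable_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x variables matrix")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"{self.values.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.unique(np.nonzero(~np.isfinite(self.values))[1])
            names = [self._names()[j] for j in bad]
            raise ValueError(f"missing or non-finite values in columns: {names}")
        if self.variable_names is not None and len(self.variable_names) != self.n_variables:
            raise ValueError("variable_names length does not match column count")

    def _names(self) -> list[str]:
        if self.variable_names is not None:
            return list(self.variable_names)
        return [f"var_{j}" for j in range(self.values.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Distinct label values in sorted order (defines class 1 vs class 2)."""
        return np.unique(self.labels)

    def class_counts(self) -> dict:
        classes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))

    def require_two_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """Validate the two-class invariant and return the two class masks."""
        classes = self.classes
        if len(classes) != 2:
            raise TwoClassViolationError(
                f"expected exactly 2 classes, found {len(classes)}: {classes.tolist()}"
            )
        m1 = self.labels == classes[0]
        m2 = self.labels == classes[1]
        if m1.sum() < 2 or m2.sum() < 2:
            raise TwoClassViolationError(
                "each class needs >= 2 samples for an SD estimate; "
                f"counts are {self.class_counts()}"
            )
        return m1, m2

    def split_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the value matrices of class 1 and class 2 (sorted label order)."""
        m1, m2 = self.require_two_classes()
        return self.values[m1], self.values[m2]

    def take(self, indices: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.values[indices], self.labels[indices], self.variable_names)

    def fingerprint(self) -> str:
        """Short content hash used to assert dataset lineage across artifacts."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.values).tobytes())
        h.update(np.asarray(self.labels, dtype="U32").tobytes())
        return h.hexdigest()[:16]

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self._names())
        df[label_column] = self.labels
        return df

    def to_csv(self, path, label_column: str = "label") -> None:
        self.to_dataframe(label_column).to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label") -> "LabeledDataset":
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {list(df.columns)}")
        features = df.drop(columns=[label_column])
        non_numeric = [
            c for c in features.columns
            if not pd.api.types.is_numeric_dtype(features[c])
        ]
        if non_numeric:
            raise ValueError(f"non-numeric feature columns: {non_numeric}")
        if features.isna().any().any():
            bad = features.columns[features.isna().any()].tolist()
            raise ValueError(f"missing values in columns: {bad}; clean or drop them first")
        return cls(
            features.to_numpy(dtype=float),
            df[label_column].to_numpy(),
            [str(c) for c in features.columns],
        )

    @classmethod
    def from_csv(cls, path, label_column: str = "label") -> "LabeledDataset":
        return cls.from_dataframe(pd.read_csv(path), label_column)


def load_csv(path, label_column: str = "label") -> LabeledDataset:
    """Read a header-ed CSV of numeric features plus one label column."""
    return LabeledDataset.from_csv(path, label_column)
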