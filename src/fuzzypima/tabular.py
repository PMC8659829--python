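"""Tabular input/output for two-class clinical datasets.

Reads Pima-format CSV files (numeric feature columns plus a binary outcome
column), rescales every feature to the unit interval by dividing by the
column maximum, partitions records by class, and performs the deterministic
"linear" train/test split (first-N rows per class, in file order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PIMA_FEATURES",
    "DEFAULT_OUTCOME",
    "TableError",
    "LabelledTable",
    "ClassPartition",
    "SplitSpec",
    "read_pima_csv",
    "normalize_features",
    "partition_by_class",
    "linear_split",
    "split_indices",
    "write_split_manifest",
]

#: Canonical Pima-Indians header (eight clinical features; outcome excluded).
PIMA_FEATURES = (
    "Pregnancies",
    "Glucose",
    "BloodPressure",
    "SkinThickness",
    "Insulin",
    "BMI",
    "DiabetesPedigreeFunction",
    "Age",
)

DEFAULT_OUTCOME = "Outcome"

_LABEL_ALIASES = {"yes": 1, "no": 0, "1": 1, "0": 0, "1.0": 1, "0.0": 0}


class TableError(ValueError):
    """Raised for malformed tabular input (missing columns, bad cells, bad labels)."""


@dataclass(frozen=True)
class LabelledTable:
    """A two-class dataset: a records-by-features matrix plus 0/1 labels.

    Class 0 is the healthy/negative class ("No"), class 1 the sick/positive
    class ("Yes").  All features must be finite and non-negative.
    """

    features: np.ndarray
    labels: np.ndarray
    attribute_names: tuple[str, ...]

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labs = np.asarray(self.labels)
        if feats.ndim != 2:
            raise TableError("features must be a 2-D records-by-attributes matrix")
        if labs.ndim != 1 or labs.shape[0] != feats.shape[0]:
            raise TableError("labels must be one value per record")
        if not np.isin(labs, (0, 1)).all():
            bad = np.flatnonzero(~np.isin(labs, (0, 1)))[0]
            raise TableError(f"label at row {bad} is not 0/1")
        if not np.isfinite(feats).all():
            r, c = np.argwhere(~np.isfinite(feats))[0]
            raise TableError(
                f"non-finite feature value at row {r}, column "
                f"{self.attribute_names[c]!r}"
            )
        if (feats < 0).any():
            r, c = np.argwhere(feats < 0)[0]
            raise TableError(
                f"negative feature value at row {r}, column "
                f"{self.attribute_names[c]!r}"
            )
        names = tuple(str(n) for n in self.attribute_names)
        if len(names) != feats.shape[1]:
            raise TableError("attribute_names length must match feature columns")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labs.astype(np.int64))
        object.__setattr__(self, "attribute_names", names)

    @property
    def n_records(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_frame(self, outcome_column: str = DEFAULT_OUTCOME) -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=list(self.attribute_names))
        frame[outcome_column] = self.labels
        return frame

    def to_csv(self, path: str | Path, outcome_column: str = DEFAULT_OUTCOME) -> None:
        self.to_frame(outcome_column).to_csv(path, index=False)


@dataclass(frozen=True)
class ClassPartition:
    """The dataset split into the class-0 matrix A0 (n x k) and class-1 A1 (m x k).

    ``feature_max`` carries the per-attribute maxima that produced the
    normalized values, so test records can be mapped onto the same scale.
    """

    a0: np.ndarray
    a1: np.ndarray
    feature_max: np.ndarray | None = None
    attribute_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a0 = np.atleast_2d(np.asarray(self.a0, dtype=float))
        a1 = np.atleast_2d(np.asarray(self.a1, dtype=float))
        if a0.size and a1.size and a0.shape[1] != a1.shape[1]:
            raise TableError("class matrices must share the feature dimension")
        object.__setattr__(self, "a0", a0)
        object.__setattr__(self, "a1", a1)
        if self.feature_max is not None:
            object.__setattr__(
                self, "feature_max", np.asarray(self.feature_max, dtype=float)
            )

    @property
    def n(self) -> int:
        return self.a0.shape[0]

    @property
    def m(self) -> int:
        return self.a1.shape[0]

    @property
    def k(self) -> int:
        return self.a0.shape[1] if self.a0.size else self.a1.shape[1]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All records (class 0 rows first) with their labels."""
        feats = np.vstack([self.a0, self.a1])
        labels = np.concatenate([np.zeros(self.n, int), np.ones(self.m, int)])
        return feats, labels


@dataclass(frozen=True)
class SplitSpec:
    """Per-class training-row counts for the linear split (study defaults 250/150)."""

    train_count_class0: int = 250
    train_count_class1: int = 150

    def __post_init__(self) -> None:
        if self.train_count_class0 < 0 or self.train_count_class1 < 0:
            raise TableError("training counts must be non-negative")


def read_pima_csv(
    path: str | Path, outcome_column: str = DEFAULT_OUTCOME
) -> LabelledTable:
    """Load a Pima-format CSV into a :class:`LabelledTable`.

    The outcome column is matched case-insensitively; its values may be 0/1
    or Yes/No (Yes maps to 1).  Every other column must be fully numeric,
    finite and non-negative; violations raise :class:`TableError` naming the
    offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise TableError(f"input file not found: {path}")
    frame = pd.read_csv(path)
    if frame.shape[0] == 0:
        raise TableError(f"{path}: no data rows")

    matches = [c for c in frame.columns if c.lower() == outcome_column.lower()]
    if not matches:
        raise TableError(
            f"{path}: outcome column {outcome_column!r} not found "
            f"(columns: {list(frame.columns)})"
        )
    outcome = matches[0]

    labels = np.empty(frame.shape[0], dtype=np.int64)
    for i, value in enumerate(frame[outcome]):
        key = str(value).strip().lower()
        if key not in _LABEL_ALIASES:
            raise TableError(
                f"{path}: unknown label {value!r} at row {i} in column {outcome!r}"
            )
        labels[i] = _LABEL_ALIASES[key]

    feature_cols = [c for c in frame.columns if c != outcome]
    if not feature_cols:
        raise TableError(f"{path}: no feature columns besides the outcome")
    columns = []
    for col in feature_cols:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise TableError(
                f"{path}: non-numeric or missing value at row {row}, column {col!r}"
            )
        columns.append(numeric.to_numpy(dtype=float))
    features = np.column_stack(columns)
    return LabelledTable(features, labels, tuple(feature_cols))


def normalize_features(
    table: LabelledTable, maxima: Sequence[float] | np.ndarray | None = None
) -> tuple[LabelledTable, np.ndarray]:
    """Divide each feature column by its maximum, mapping features into [0, 1].

    When ``maxima`` is omitted the per-column maxima of ``table`` are used
    and returned, so a test table can be rescaled onto the training axis by
    passing them back in.  A zero column maximum is an error (division
    undefined).  Normalizing an already-normalized table with its own maxima
    is the identity.
    """
    if maxima is None:
        maxima = table.features.max(axis=0)
    maxima = np.asarray(maxima, dtype=float)
    if maxima.shape != (table.n_features,):
        raise TableError(
            f"maxima has length {maxima.size}, expected {table.n_features}"
        )
    if (maxima <= 0).any():
        col = int(np.argmax(maxima <= 0))
        raise TableError(
            f"column {table.attribute_names[col]!r} has non-positive maximum; "
            "cannot normalize"
        )
    scaled = table.features / maxima
    return LabelledTable(scaled, table.labels, table.attribute_names), maxima


def partition_by_class(
    table: LabelledTable, feature_max: np.ndarray | None = None
) -> ClassPartition:
    """Split the table into the class-0 and class-1 matrices, preserving row order."""
    mask0 = table.labels == 0
    n, m = int(mask0.sum()), int((~mask0).sum())
    if n == 0 or m == 0:
        raise TableError(
            f"both classes must be represented (got {n} class-0 and {m} class-1 rows)"
        )
    return ClassPartition(
        table.features[mask0],
        table.features[~mask0],
        feature_max=feature_max,
        attribute_names=table.attribute_names,
    )


def linear_split(
    partition: ClassPartition, spec: SplitSpec = SplitSpec()
) -> tuple[ClassPartition, ClassPartition]:
    """Deterministic linear sampling: first-N rows per class train, rest test."""
    if spec.train_count_class0 > partition.n:
        raise TableError(
            f"requested {spec.train_count_class0} class-0 training rows, "
            f"only {partition.n} available"
        )
    if spec.train_count_class1 > partition.m:
        raise TableError(
            f"requested {spec.train_count_class1} class-1 training rows, "
            f"only {partition.m} available"
        )
    c0, c1 = spec.train_count_class0, spec.train_count_class1
    train = ClassPartition(
        partition.a0[:c0],
        partition.a1[:c1],
        feature_max=partition.feature_max,
        attribute_names=partition.attribute_names,
    )
    test = ClassPartition(
        partition.a0[c0:],
        partition.a1[c1:],
        feature_max=partition.feature_max,
        attribute_names=partition.attribute_names,
    )
    return train, test


def split_indices(labels: np.ndarray, spec: SplitSpec = SplitSpec()) -> dict[str, list[int]]:
    """Original row indices of each split block, for reproducibility manifests."""
    labels = np.asarray(labels)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    if spec.train_count_class0 > idx0.size or spec.train_count_class1 > idx1.size:
        raise TableError("split spec exceeds class sizes")
    return {
        "train_class0": idx0[: spec.train_count_class0].tolist(),
        "train_class1": idx1[: spec.train_count_class1].tolist(),
        "test_class0": idx0[spec.train_count_class0 :].tolist(),
        "test_class1": idx1[spec.train_count_class1 :].tolist(),
    }


def write_split_manifest(path: str | Path, indices: dict[str, list[int]]) -> None:
    """Write the split as plain text: one ``block: i1 i2 ...`` line per block."""
    lines = [
        f"{block}: {' '.join(str(i) for i in indices[block])}"
        for block in ("train_class0", "train_class1", "test_class0", "test_class1")
    ]
    Path(path).write_text("\n".join(lines) + "\n")
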