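"""Raw-table preprocessing for the n-SBC pipeline.

Turns a mixed-type table (numeric and categorical cells, missing values
allowed) into a matrix of nonnegative integers ready for reflected-binary
encoding.  All statistics — imputation values, category tables, per-feature
minimum shifts and training maxima — are fitted on the training rows only
and reapplied verbatim to query rows, so no information leaks from a test
fold into the fitted model.

The integerization of a numeric feature is: subtract the training minimum,
truncate toward minus infinity at two decimal places, multiply by 100.  All
of this is done in exact decimal arithmetic (`decimal.Decimal`) so that a
value such as 1.24 maps to 124 and never to 123 via a binary-float artifact.
Categorical features are label-encoded to consecutive codes 0..c-1 in sorted
token order and used directly as nonnegative integers (no decimal scaling is
needed for values that are already integers).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation, ROUND_FLOOR
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MISSING_MARKERS",
    "SCALE",
    "RawTable",
    "ColumnModel",
    "PreprocessModel",
    "is_missing",
    "fit_preprocessor",
    "integerize_column",
    "transform",
]

#: Cell tokens recognised as missing (case-insensitive, surrounding
#: whitespace ignored).  "?" is the WEKA/ARFF convention.
DEFAULT_MISSING_MARKERS: tuple[str, ...] = ("", "na", "?", "nan")

#: Fixed decimal scale: two decimal places are kept, so integers are value*100.
SCALE: int = 100

_CENT = Decimal("0.01")

NUMERIC = "numeric"
CATEGORICAL = "categorical"


def is_missing(cell: object, markers: Sequence[str] = DEFAULT_MISSING_MARKERS) -> bool:
    """True if a raw cell should be treated as a missing value."""
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    if isinstance(cell, str) and cell.strip().lower() in markers:
        return True
    return False


def _as_decimal(cell: object) -> Decimal | None:
    """Parse a cell as an exact decimal number, or None if non-numeric.

    String tokens are parsed directly (keeping their printed decimal
    digits); floats go through ``repr`` which yields the shortest
    round-tripping decimal literal.
    """
    if isinstance(cell, Decimal):
        return cell if cell.is_finite() else None
    if isinstance(cell, bool):
        return None
    if isinstance(cell, (int, np.integer)):
        return Decimal(int(cell))
    if isinstance(cell, (float, np.floating)):
        f = float(cell)
        if not math.isfinite(f):
            return None
        return Decimal(repr(f))
    if isinstance(cell, str):
        tok = cell.strip()
        try:
            d = Decimal(tok)
        except InvalidOperation:
            return None
        return d if d.is_finite() else None
    return None


@dataclass
class RawTable:
    """A labelled table of raw feature cells.

    ``features`` holds object-dtype cells: numbers, category tokens, or
    ``None`` for missing.  ``labels`` holds one class token per row; the
    label column may not contain missing values.
    """

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree on row count")

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        label_column: str | None = None,
        missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
    ) -> "RawTable":
        """Split a DataFrame into features and labels, normalising missing cells.

        ``label_column`` defaults to the last column.  Recognised missing
        markers become ``None`` in the feature block; a missing label is an
        error.
        """
        if frame.shape[1] < 2:
            raise ValueError("table needs at least one feature column and a label column")
        if label_column is None:
            label_column = frame.columns[-1]
        if label_column not in frame.columns:
            raise ValueError(f"label column {label_column!r} not found")
        feats = frame.drop(columns=[label_column]).copy()
        markers = tuple(m.lower() for m in missing_markers)
        feats = feats.map(lambda c: None if is_missing(c, markers) else c)
        labels = frame[label_column]
        if any(is_missing(v, markers) for v in labels):
            raise ValueError(f"label column {label_column!r} contains missing values")
        labels = labels.map(lambda v: str(v).strip()).rename(label_column)
        return cls(features=feats.reset_index(drop=True), labels=labels.reset_index(drop=True))

    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def column_names(self) -> list[str]:
        return [str(c) for c in self.features.columns]

    def take(self, indices: Iterable[int]) -> "RawTable":
        """Row subset (used by cross-validation splits)."""
        idx = list(indices)
        return RawTable(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels.iloc[idx].reset_index(drop=True),
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = self.features.copy()
        out[self.labels.name or "class"] = self.labels.values
        return out


@dataclass
class ColumnModel:
    """Fitted per-feature state: kind, imputation value, codes and shifts."""

    name: str
    kind: str  # NUMERIC or CATEGORICAL
    impute: str  # decimal literal (numeric) or category token (categorical)
    categories: dict[str, int] | None
    min_shift: str | None  # decimal literal, numeric columns only
    train_max_int: int

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "impute": self.impute,
            "categories": self.categories,
            "min_shift": self.min_shift,
            "train_max_int": self.train_max_int,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnModel":
        return cls(**d)


@dataclass
class PreprocessModel:
    """The full fitted preprocessor: one ColumnModel per feature column."""

    columns: list[ColumnModel]
    scale: int = SCALE
    missing_markers: tuple[str, ...] = DEFAULT_MISSING_MARKERS

    def to_dict(self) -> dict:
        return {
            "columns": [c.to_dict() for c in self.columns],
            "scale": self.scale,
            "missing_markers": list(self.missing_markers),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessModel":
        return cls(
            columns=[ColumnModel.from_dict(c) for c in d["columns"]],
            scale=int(d.get("scale", SCALE)),
            missing_markers=tuple(d.get("missing_markers", DEFAULT_MISSING_MARKERS)),
        )


def _truncate_2dp(d: Decimal) -> Decimal:
    """Truncate toward minus infinity at two decimal places."""
    return d.quantize(_CENT, rounding=ROUND_FLOOR)


def integerize_column(
    values: Iterable[object], min_shift: object
) -> np.ndarray:
    """Map imputed numeric values to nonnegative integers.

    Each value v becomes ``trunc2(v - min_shift) * 100`` where ``trunc2``
    truncates toward minus infinity at two decimal places; results below
    zero (possible only for query values under the training minimum) clip
    to 0.  Arithmetic is exact decimal throughout.
    """
    shift = _as_decimal(min_shift)
    if shift is None:
        raise ValueError(f"min_shift {min_shift!r} is not a finite number")
    out = []
    for v in values:
        d = _as_decimal(v)
        if d is None:
            raise ValueError(f"non-finite or non-numeric value {v!r} in numeric column")
        i = int(_truncate_2dp(d - shift).scaleb(2))
        out.append(max(0, i))
    return np.asarray(out, dtype=np.int64)


def _fit_numeric(name: str, observed: list[Decimal], n_rows: int) -> ColumnModel:
    mean = sum(observed, Decimal(0)) / Decimal(len(observed))
    # imputed training column = observed values plus `mean` for each missing row
    col = observed + [mean] * (n_rows - len(observed))
    min_shift = min(col)
    ints = integerize_column(col, min_shift)
    return ColumnModel(
        name=name,
        kind=NUMERIC,
        impute=str(mean),
        categories=None,
        min_shift=str(min_shift),
        train_max_int=int(ints.max()),
    )


def _fit_categorical(name: str, observed: list[str]) -> ColumnModel:
    counts = Counter(observed)
    top = max(counts.values())
    mode = min(tok for tok, c in counts.items() if c == top)  # deterministic tie-break
    cats = {tok: i for i, tok in enumerate(sorted(counts))}
    return ColumnModel(
        name=name,
        kind=CATEGORICAL,
        impute=mode,
        categories=cats,
        min_shift=None,
        train_max_int=len(cats) - 1,
    )


def fit_preprocessor(
    train: RawTable,
    missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
) -> PreprocessModel:
    """Fit imputation, category tables and integerization on training rows.

    A column whose non-missing cells all parse as numbers is numeric
    (imputed with the mean); a column with no numeric cell is categorical
    (imputed with the mode, ties to the lexicographically smallest token).
    A column mixing both kinds, or entirely missing, is an error.
    """
    if train.n_rows < 1 or train.features.shape[1] < 1:
        raise ValueError("training table needs at least one row and one feature column")
    markers = tuple(m.lower() for m in missing_markers)
    cols: list[ColumnModel] = []
    for name in train.features.columns:
        cells = [c for c in train.features[name] if not is_missing(c, markers)]
        if not cells:
            raise ValueError(f"column {name!r} is entirely missing")
        decimals = [_as_decimal(c) for c in cells]
        n_num = sum(d is not None for d in decimals)
        if n_num == len(cells):
            cols.append(_fit_numeric(str(name), decimals, train.n_rows))
        elif n_num == 0:
            cols.append(_fit_categorical(str(name), [str(c).strip() for c in cells]))
        else:
            raise ValueError(
                f"column {name!r} mixes numeric and categorical cells "
                f"({n_num} of {len(cells)} parse as numbers)"
            )
    return PreprocessModel(columns=cols, missing_markers=tuple(missing_markers))


def _transform_numeric(cells: Iterable[object], cm: ColumnModel, markers) -> np.ndarray:
    impute = Decimal(cm.impute)
    vals = []
    for c in cells:
        d = None if is_missing(c, markers) else _as_decimal(c)
        vals.append(impute if d is None else d)
    ints = integerize_column(vals, Decimal(cm.min_shift))
    return np.minimum(ints, cm.train_max_int)


def _transform_categorical(cells: Iterable[object], cm: ColumnModel, markers) -> np.ndarray:
    assert cm.categories is not None
    fallback = cm.categories[cm.impute]
    out = []
    for c in cells:
        if is_missing(c, markers):
            out.append(fallback)
        else:
            out.append(cm.categories.get(str(c).strip(), fallback))
    return np.asarray(out, dtype=np.int64)


def transform(table: RawTable, model: PreprocessModel) -> tuple[np.ndarray, np.ndarray]:
    """Apply a fitted preprocessor to a table.

    Returns ``(X, labels)`` where X is a nonnegative integer matrix with one
    row per record and columns in model order.  Query cells outside the
    fitted ranges are made representable: numerics clip to
    [0, train_max_int], unseen category tokens fall back to the imputation
    value's code.
    """
    if table.features.shape[1] != len(model.columns):
        raise ValueError(
            f"column count mismatch: table has {table.features.shape[1]}, "
            f"model expects {len(model.columns)}"
        )
    names = [str(c) for c in table.features.columns]
    expected = [c.name for c in model.columns]
    if names != expected:
        raise ValueError(f"column names {names} do not match fitted schema {expected}")
    markers = tuple(m.lower() for m in model.missing_markers)
    mat = np.empty((table.n_rows, len(model.columns)), dtype=np.int64)
    for j, cm in enumerate(model.columns):
        cells = table.features.iloc[:, j]
        if cm.kind == NUMERIC:
            mat[:, j] = _transform_numeric(cells, cm, markers)
        else:
            mat[:, j] = _transform_categorical(cells, cm, markers)
    return mat, table.labels.to_numpy(dtype=object)
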