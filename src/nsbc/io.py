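"""Reading and writing labelled tables: CSV and a minimal ARFF subset.

CSV files need a header row; the label column is named explicitly or
defaults to the last column.  Cells are kept as their original string
tokens so numeric values retain their printed decimal digits exactly (the
integerization step works in decimal arithmetic).

The ARFF reader covers the common WEKA layout: ``@relation``,
``@attribute name numeric|real|integer|{a,b,c}`` and a dense ``@data``
block with "?" for missing.  Sparse data blocks, date/string attributes
and quoted multi-word tokens are out of scope.
"""

from __future__ import annotations

import csv
import os
import tempfile
from typing import Sequence

import pandas as pd

from .preprocessing import DEFAULT_MISSING_MARKERS, RawTable

__all__ = ["read_csv", "read_arff", "write_csv", "write_text_atomic"]


def read_csv(
    path: str,
    label: str | None = None,
    delimiter: str = ",",
    missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
) -> RawTable:
    """Load a header-ed delimited file into a RawTable (label defaults to last column)."""
    frame = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return RawTable.from_dataframe(frame, label_column=label, missing_markers=missing_markers)


def _parse_arff_attribute(line: str) -> tuple[str, list[str] | None]:
    body = line.split(None, 1)[1].strip()
    if body.startswith(("'", '"')):
        quote = body[0]
        end = body.index(quote, 1)
        name, rest = body[1:end], body[end + 1:].strip()
    else:
        parts = body.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"malformed @attribute line: {line!r}")
        name, rest = parts
    rest = rest.strip()
    if rest.startswith("{"):
        inner = rest.rstrip().rstrip("}").lstrip("{")
        values = [v.strip().strip("'\"") for v in inner.split(",")]
        return name, values
    if rest.lower() in ("numeric", "real", "integer"):
        return name, None
    raise ValueError(f"unsupported attribute type {rest!r} for {name!r}")


def read_arff(path: str, label: str | None = None) -> RawTable:
    """Load a dense ARFF file; nominal attributes become categorical columns."""
    names: list[str] = []
    nominal: dict[str, list[str]] = {}
    rows: list[list[str]] = []
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if in_data:
                rows.append(next(csv.reader([line])))
            elif low.startswith("@attribute"):
                name, values = _parse_arff_attribute(line)
                names.append(name)
                if values is not None:
                    nominal[name] = values
            elif low.startswith("@data"):
                in_data = True
            elif low.startswith("@relation"):
                continue
            else:
                raise ValueError(f"unrecognised ARFF line: {line!r}")
    if not names or not rows:
        raise ValueError(f"{path}: no attributes or no data rows")
    for r in rows:
        if len(r) != len(names):
            raise ValueError(f"{path}: data row has {len(r)} cells, expected {len(names)}")
    frame = pd.DataFrame(rows, columns=names, dtype=str)
    frame = frame.map(lambda c: c.strip().strip("'\""))
    # a nominal attribute whose tokens are all numbers must stay categorical:
    # tag its cells so the preprocessor cannot mistake the column for numeric
    for name, values in nominal.items():
        if name == (label if label is not None else names[-1]):
            continue
        if all(_is_number(v) for v in values):
            frame[name] = frame[name].map(lambda c: c if c == "?" else f"cat:{c}")
    return RawTable.from_dataframe(frame, label_column=label)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_csv(table: RawTable, path: str) -> None:
    """Write a RawTable back to CSV (missing cells as empty), atomically."""
    frame = table.to_dataframe()
    frame = frame.map(lambda c: "" if c is None else c)
    write_text_atomic(path, frame.to_csv(index=False))


def write_text_atomic(path: str, text: str) -> None:
    """Write text to a temp file in the target directory, then rename over."""
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
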