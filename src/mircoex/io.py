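"""Readers and writers for the plain-text formats used by the pipeline.

Count matrices are represented as :class:`pandas.DataFrame` with feature IDs
on the index and sample IDs on the columns; counts are non-negative integers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

#: Annotation columns emitted by featureCounts between the feature ID and the
#: per-sample count columns.
FEATURECOUNTS_META = ("Chr", "Start", "End", "Strand", "Length")


class ParseError(ValueError):
    """Raised when an input file violates the expected schema."""


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample count TSV into an integer DataFrame.

    Accepts the plain dialect (first column = feature ID, remaining columns =
    samples) and the featureCounts dialect (annotation columns
    Chr/Start/End/Strand/Length are dropped when all present).  Lines starting
    with ``#`` are ignored.

    Raises
    ------
    ParseError
        On duplicate feature or sample IDs, ragged rows, negative or
        non-integer cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a feature column plus at least one sample column")
    feature_col = df.columns[0]
    sample_cols = [c for c in df.columns[1:] if c not in FEATURECOUNTS_META]
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns after dropping annotation columns")
    feats = df[feature_col].astype(str)
    if feats.duplicated().any():
        dup = feats[feats.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate feature ID {dup!r}")
    if pd.Index(sample_cols).duplicated().any():
        raise ParseError(f"{path}: duplicate sample IDs in header")
    counts = df[sample_cols]
    if counts.isna().any().any():
        row = int(counts.isna().any(axis=1).idxmax()) + 2
        raise ParseError(f"{path}: missing value near line {row}")
    try:
        values = counts.astype(np.float64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric count cell: {exc}") from None
    arr = values.to_numpy()
    if (arr < 0).any():
        i = int(np.argwhere(arr < 0)[0, 0]) + 2
        raise ParseError(f"{path}: negative count near line {i}")
    if not np.allclose(arr, np.round(arr)):
        i = int(np.argwhere(~np.isclose(arr, np.round(arr)))[0, 0]) + 2
        raise ParseError(f"{path}: non-integer count near line {i}")
    out = pd.DataFrame(arr.astype(np.int64), index=pd.Index(feats, name="feature_id"),
                       columns=sample_cols)
    return out


def write_counts(cm: pd.DataFrame, path: str | Path) -> Path:
    """Write a count matrix as plain TSV (first column ``feature_id``)."""
    path = Path(path)
    cm.to_csv(path, sep="\t", index_label="feature_id")
    return path


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the ``sample_id,group,tissue`` CSV.

    Sample IDs may repeat across tissues (the same animal profiled in several
    tissues) but each (sample_id, tissue) pair must be unique and each
    sample_id must map to a single group.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "group", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df.duplicated(subset=["sample_id", "tissue"]).any():
        raise ParseError(f"{path}: duplicate (sample_id, tissue) rows")
    groups_per_sample = df.groupby("sample_id")["group"].nunique()
    bad = groups_per_sample[groups_per_sample > 1]
    if len(bad):
        raise ParseError(f"{path}: sample(s) assigned to multiple groups: {list(bad.index)}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> Path:
    sheet.to_csv(path, index=False)
    return Path(path)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a transformed expression TSV (floats, same layout as counts)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature_id"
    return df.astype(np.float64)


def write_expression(em: pd.DataFrame, path: str | Path) -> Path:
    """Write an expression matrix at 6 significant digits."""
    em.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")
    return Path(path)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
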