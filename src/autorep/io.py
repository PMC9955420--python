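"""Readers and writers for the pipeline's delimited-text formats.

Matrices travel as TSV with the feature ID in the first column and sample
IDs in the header; AIRR rearrangements as standard tab-separated
Rearrangement files; localization annotations as two-column TSV with
pipe-separated categories.  All writers emit deterministic output
(fixed float format, fixed column order) so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ValidationError
from .repertoire import REQUIRED_AIRR_COLUMNS

FLOAT_FORMAT = "%.8g"


def read_matrix(path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated feature IDs: {dups[:5]}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            feat = df.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric value at feature {feat!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing values in matrix")
    return df


def write_matrix(df: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing metadata column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated sample IDs")
    return df.set_index("sample_id")


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_airr(path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV.

    Requires the standard columns ``sequence_id``, ``v_call``,
    ``junction_aa`` and ``duplicate_count``; any other columns are
    preserved as passthrough.  An empty data section yields an empty
    table, not an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required AIRR columns: {missing}")
    counts = pd.to_numeric(df["duplicate_count"], errors="coerce")
    bad = counts.isna() & df["duplicate_count"].notna()
    if bad.any():
        # +2 for the header line and 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValidationError(f"{path}: malformed duplicate_count at line {line}")
    df["duplicate_count"] = counts.astype("Int64")
    for col in df.columns:
        if col.startswith("mu_count_"):
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_airr(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> dict[str, set[str]]:
    from .expression import read_gmt

    return read_gmt(path)


def file_digest(path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def ensure_exists(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"input file not found: {p}")
    return p
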