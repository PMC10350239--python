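"""Readers and writers for the plain-text interchange formats.

Beta matrix: TSV (or CSV), probes as rows, first column probe IDs,
header row of sample IDs. Sample sheet: CSV with columns sample_id,
subject_id, replicate and optional plate. Annotation: CSV keyed by
probe_id. Reliability table: TSV with a fixed column order, floats at 6
significant digits, missing written as "NA". On input "NA", "NaN" and
the empty string all parse as missing; only "NA" is ever emitted.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    RELIABILITY_COLUMNS,
    REQUIRED_SHEET_COLUMNS,
    BetaMatrix,
    DataError,
)

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "read_annotation",
    "read_reliability_table",
    "write_reliability_table",
]

NA_VALUES = ["NA", "NaN", "nan", ""]

_FLOAT_COLUMNS = ("icc", "sigma_b2", "sigma_w2", "sd_diff", "hola", "micc", "mean_beta", "sd_beta")


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_beta_matrix(path, range_check: bool = True) -> BetaMatrix:
    """Read a probes x samples beta matrix from TSV/CSV.

    Empty cells, "NA" and "NaN" become missing. With ``range_check``
    (beta mode) any value outside [0, 1] is rejected with the offending
    probe and sample named; disable it for M-values or other scales.
    """
    try:
        df = pd.read_csv(
            path,
            sep=_sep_for(path),
            index_col=0,
            na_values=NA_VALUES,
            keep_default_na=False,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"could not parse beta matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise DataError(
                f"non-numeric beta value {bad.iloc[0]!r} for probe {bad.index[0]!r}, "
                f"sample {col!r}"
            ) from None
    if range_check:
        arr = df.to_numpy(dtype=float)
        bad = np.argwhere((arr < 0) | (arr > 1))
        if len(bad):
            i, j = bad[0]
            raise DataError(
                f"beta value {arr[i, j]!r} out of [0, 1] for probe {df.index[i]!r}, "
                f"sample {df.columns[j]!r} (use range_check=False for M-values)"
            )
    return BetaMatrix(df)


def write_beta_matrix(m: BetaMatrix, path) -> None:
    m.data.to_csv(path, sep=_sep_for(path), na_rep="NA", index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate the replicate sample sheet (CSV)."""
    sheet = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False)
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise DataError(f"sample sheet {path} is missing required columns: {missing}")
    return sheet


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation table (CSV keyed by probe_id)."""
    ann = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False)
    if "probe_id" not in ann.columns:
        raise DataError(f"annotation {path} must have a 'probe_id' column")
    if ann["probe_id"].duplicated().any():
        raise DataError(f"annotation {path} has duplicate probe IDs")
    return ann


def _format_float(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return f"{v:.6g}"


def write_reliability_table(table: pd.DataFrame, path) -> None:
    """Write a reliability table as TSV with the fixed column contract.

    Columns: probe_id, n_pairs, icc, sigma_b2, sigma_w2, sd_diff, hola,
    micc, class_icc, class_micc, mean_beta, sd_beta. Floats carry 6
    significant digits; missing values are written as "NA". The file
    round-trips losslessly at that precision.
    """
    missing = [c for c in RELIABILITY_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"reliability table is missing columns: {missing}")
    out = table.loc[:, list(RELIABILITY_COLUMNS)].copy()
    for col in _FLOAT_COLUMNS:
        out[col] = out[col].map(_format_float)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_reliability_table(path) -> pd.DataFrame:
    """Read a reliability table written by :func:`write_reliability_table`.

    Also accepts any TSV/CSV with at least ``probe_id`` plus a subset of
    the contract columns (e.g. an external study's probe -> ICC table).
    """
    df = pd.read_csv(path, sep=_sep_for(path), na_values=NA_VALUES, keep_default_na=False)
    if "probe_id" not in df.columns:
        raise DataError(f"reliability table {path} must have a 'probe_id' column")
    if df["probe_id"].duplicated().any():
        raise DataError(f"reliability table {path} has duplicate probe IDs")
    for col in _FLOAT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "n_pairs" in df.columns:
        df["n_pairs"] = pd.to_numeric(df["n_pairs"], errors="coerce").astype("Int64")
    return df


def ensure_parent(path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
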