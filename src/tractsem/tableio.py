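"""Reading and validating subject tables.

The expected layout mirrors the study dataset: one row per subject with 10
mean tract-based FA columns (ATR, CGC, CGH, CST, Fmj, Fmn, IFO, ILF, SLF,
UNC), age in years, and the four WAIS-III index scores (PO, PS, VC, WM).
Column matching is case-sensitive; deposits with different headers can be
mapped through an alias dictionary.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import INDICATORS, TRACTS

__all__ = ["REQUIRED_COLUMNS", "read_study_table", "validate_study_table"]

log = logging.getLogger("tractsem")

REQUIRED_COLUMNS = TRACTS + ("age",) + INDICATORS


def validate_study_table(
    df: pd.DataFrame,
    *,
    fa_range=(0.0, 1.0),
    age_range=(0.0, 120.0),
    id_column: str | None = None,
) -> pd.DataFrame:
    """Schema checks + listwise deletion; returns the cleaned table.

    Raises on a missing required column, a non-numeric cell, FA outside
    ``fa_range`` or age outside ``age_range`` (errors name the offending
    row and column).  Rows with missing values are dropped (listwise
    deletion) and the count is logged and stored as ``attrs['n_dropped']``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if id_column is not None and id_column in df.columns:
        dup = df[id_column][df[id_column].duplicated()]
        if len(dup):
            raise ValueError(f"duplicated subject id(s): {dup.tolist()}")
    out = df.copy()
    for col in REQUIRED_COLUMNS:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric value in column {col!r}, row {row}")
        out[col] = converted
    for col in TRACTS:
        v = out[col]
        viol = v.notna() & ((v < fa_range[0]) | (v > fa_range[1]))
        if viol.any():
            row = int(np.flatnonzero(viol)[0])
            raise ValueError(
                f"FA out of range [{fa_range[0]}, {fa_range[1]}] in column "
                f"{col!r}, row {row} (value {v.iloc[row]})"
            )
    v = out["age"]
    viol = v.notna() & ((v < age_range[0]) | (v > age_range[1]))
    if viol.any():
        row = int(np.flatnonzero(viol)[0])
        raise ValueError(f"age out of range in row {row} (value {v.iloc[row]})")
    before = len(out)
    cleaned = out.dropna(subset=list(REQUIRED_COLUMNS))
    n_dropped = before - len(cleaned)
    if n_dropped:
        log.info("listwise deletion removed %d of %d rows", n_dropped, before)
    cleaned = cleaned.reset_index(drop=True)
    cleaned.attrs["n_dropped"] = n_dropped
    return cleaned


def read_study_table(path, *, aliases: dict[str, str] | None = None,
                     fa_range=(0.0, 1.0), id_column: str | None = "subject") -> pd.DataFrame:
    """Read a subject CSV, apply the alias map, validate, listwise-delete.

    ``aliases`` maps column names as found in the file to the canonical
    names (e.g. ``{"Age_years": "age"}``).
    """
    df = pd.read_csv(path)
    if aliases:
        df = df.rename(columns=aliases)
    return validate_study_table(df, fa_range=fa_range, id_column=id_column)
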