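"""Reading and writing visit tables.

The on-disk format is a plain UTF-8 CSV with the exact header
``visit_id, T_a_C, T_hd_C, T_th_C, T_ab_C, G_Wm2`` plus optional
``M_mW`` and ``condition`` columns. Units are embedded in the column
names because the W/mW boundary is the most dangerous unit mix-up in
this model. Missing measured M is an empty cell, never a sentinel
number. The derived ``is_sun`` column (G strictly above 100 W m-2) is
recomputed on read and never stored.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .constants import CELSIUS_ZERO, SUN_THRESHOLD
from .exceptions import ValidationError

REQUIRED_COLUMNS = ("visit_id", "T_a_C", "T_hd_C", "T_th_C", "T_ab_C", "G_Wm2")
OPTIONAL_COLUMNS = ("M_mW", "condition")
_TEMPERATURE_COLUMNS = ("T_a_C", "T_hd_C", "T_th_C", "T_ab_C")


def _numeric(frame: pd.DataFrame, column: str, required: bool) -> pd.Series:
    raw = frame[column]
    values = pd.to_numeric(raw, errors="coerce")
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = values.isna() & ~blank
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based plus header line
        raise ValidationError(
            f"unparseable number in column {column!r}, file row {row}: {raw[bad.idxmax()]!r}"
        )
    if required and blank.any():
        row = int(blank.idxmax()) + 2
        raise ValidationError(f"missing value in required column {column!r}, file row {row}")
    return values


def read_visits(path) -> pd.DataFrame:
    """Read and validate a visit CSV; adds the derived ``is_sun`` column."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing required column(s) {missing}")
    out = pd.DataFrame()
    out["visit_id"] = _numeric(frame, "visit_id", required=True).astype(int)
    for col in _TEMPERATURE_COLUMNS:
        values = _numeric(frame, col, required=True)
        below = values <= -CELSIUS_ZERO
        if below.any():
            row = int(below.idxmax()) + 2
            raise ValidationError(
                f"temperature at or below absolute zero in column {col!r}, file row {row}"
            )
        out[col] = values.astype(float)
    g = _numeric(frame, "G_Wm2", required=True)
    negative = g < 0
    if negative.any():
        row = int(negative.idxmax()) + 2
        raise ValidationError(f"negative global radiation in column 'G_Wm2', file row {row}")
    out["G_Wm2"] = g.astype(float)
    if "M_mW" in frame.columns:
        out["M_mW"] = _numeric(frame, "M_mW", required=False).astype(float)
    if "condition" in frame.columns:
        out["condition"] = frame["condition"]
    out["is_sun"] = out["G_Wm2"] > SUN_THRESHOLD
    return out


def write_visits(frame: pd.DataFrame, path) -> None:
    """Write a visit table in the canonical column order (derived
    columns dropped); value-identical under a read/write round trip."""
    path = Path(path)
    columns = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in frame.columns]
    frame.loc[:, columns].to_csv(path, index=False)
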