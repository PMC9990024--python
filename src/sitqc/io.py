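"""Tidy CSV schemas for the three experiment tables, with validation.

Schemas (exact headers):

* lifespans:   ``treatment,replicate,time_days,event``
* flight:      ``treatment,replicate,second_chill_min,n_loaded,n_escaped``
* competition: ``arm,replicate,n_fertile_males,n_sterile_males,n_females,eggs_total,eggs_hatched``

Readers validate every row and report 1-based data-row numbers for each
violation. Writers round-trip exactly through the readers. For foreign
spreadsheets (e.g. supplementary datasets with their own column layout)
every reader accepts a ``column_map`` of ``{source_column: schema_column}``
applied before validation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "LIFESPAN_COLUMNS",
    "FLIGHT_COLUMNS",
    "COMPETITION_COLUMNS",
    "validate_lifespans",
    "validate_flight",
    "validate_competition",
    "read_lifespans",
    "read_flight",
    "read_competition",
    "write_lifespans",
    "write_flight",
    "write_competition",
]

LIFESPAN_COLUMNS = ["treatment", "replicate", "time_days", "event"]
FLIGHT_COLUMNS = ["treatment", "replicate", "second_chill_min", "n_loaded", "n_escaped"]
COMPETITION_COLUMNS = [
    "arm",
    "replicate",
    "n_fertile_males",
    "n_sterile_males",
    "n_females",
    "eggs_total",
    "eggs_hatched",
]

SURVIVAL_TREATMENTS = {"control", "1_25", "2_25", "2_50", "2_100"}
FLIGHT_TREATMENT_LABELS = {
    "1_25", "2_25", "2_50", "2_100", "C_1_25", "C_2_25", "C_2_50", "C_2_100",
}
ARM_LABELS = {"Hn", "Hs", "Ho", "Ho_1_25", "Ho_2_25"}


class SchemaError(ValueError):
    """A table violates its schema; the message lists offending rows."""


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _rows(mask: pd.Series) -> str:
    """1-based data-row numbers of True entries, for error messages."""
    idx = np.flatnonzero(np.asarray(mask)) + 1
    shown = ", ".join(map(str, idx[:10]))
    return shown + (", ..." if len(idx) > 10 else "")


def _check(mask: pd.Series, message: str, problems: list[str]) -> None:
    if mask.any():
        problems.append(f"{message} (row {_rows(mask)})")


def _raise_if(problems: list[str], what: str) -> None:
    if problems:
        raise SchemaError(f"invalid {what} table: " + "; ".join(problems))


def validate_lifespans(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, LIFESPAN_COLUMNS, "lifespan")
    out = df[LIFESPAN_COLUMNS].copy()
    out["time_days"] = pd.to_numeric(out["time_days"], errors="coerce")
    if out["event"].dtype != bool:
        out["event"] = (
            out["event"].astype(str).str.strip().str.lower()
            .map({"true": True, "false": False, "1": True, "0": False})
        )
    problems: list[str] = []
    _check(out["time_days"].isna() | (out["time_days"] <= 0),
           "time_days must be a positive number", problems)
    _check(out["event"].isna(), "event must be boolean", problems)
    _check(~out["treatment"].isin(SURVIVAL_TREATMENTS),
           f"unknown treatment label (expected {sorted(SURVIVAL_TREATMENTS)})",
           problems)
    _raise_if(problems, "lifespan")
    out["event"] = out["event"].astype(bool)
    return out.reset_index(drop=True)


def validate_flight(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, FLIGHT_COLUMNS, "flight")
    out = df[FLIGHT_COLUMNS].copy()
    for col in ("second_chill_min", "n_loaded", "n_escaped"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    problems: list[str] = []
    _check(~out["treatment"].isin(FLIGHT_TREATMENT_LABELS),
           f"unknown treatment label (expected {sorted(FLIGHT_TREATMENT_LABELS)})",
           problems)
    _check(out["n_loaded"].isna() | (out["n_loaded"] < 1),
           "n_loaded must be a positive count", problems)
    _check(out["n_escaped"].isna() | (out["n_escaped"] < 0),
           "n_escaped must be a non-negative count", problems)
    _check(out["n_escaped"] > out["n_loaded"],
           "n_escaped exceeds n_loaded", problems)
    is_control = out["treatment"].astype(str).str.startswith("C_")
    _check(~is_control & ~out["second_chill_min"].isin([0, 25, 50, 100]),
           "second_chill_min must be one of 0, 25, 50, 100 for treatments",
           problems)
    _raise_if(problems, "flight")
    out["n_loaded"] = out["n_loaded"].astype(int)
    out["n_escaped"] = out["n_escaped"].astype(int)
    return out.reset_index(drop=True)


def validate_competition(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, COMPETITION_COLUMNS, "competition")
    out = df[COMPETITION_COLUMNS].copy()
    count_cols = COMPETITION_COLUMNS[2:]
    for col in count_cols:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    problems: list[str] = []
    _check(~out["arm"].isin(ARM_LABELS),
           f"unknown arm label (expected {sorted(ARM_LABELS)})", problems)
    for col in count_cols:
        _check(out[col].isna() | (out[col] < 0),
               f"{col} must be a non-negative count", problems)
    _check(out["eggs_hatched"] > out["eggs_total"],
           "eggs_hatched exceeds eggs_total", problems)
    _check((out["arm"] == "Hn") & (out["n_sterile_males"] > 0),
           "Hn control must have no sterile males", problems)
    _check((out["arm"] == "Hs") & (out["n_fertile_males"] > 0),
           "Hs control must have no fertile males", problems)
    _raise_if(problems, "competition")
    for col in count_cols:
        out[col] = out[col].astype(int)
    return out.reset_index(drop=True)


def _read(
    path: str | Path,
    validator,
    column_map: Mapping[str, str] | None,
) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    try:
        return validator(df)
    except SchemaError as err:
        raise SchemaError(f"{path}: {err}") from None


def read_lifespans(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a lifespan CSV (one row per male)."""
    return _read(path, validate_lifespans, column_map)


def read_flight(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a flight-trial CSV (one row per device run)."""
    return _read(path, validate_flight, column_map)


def read_competition(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a competition-cage CSV (one row per cage)."""
    return _read(path, validate_competition, column_map)


def write_lifespans(df: pd.DataFrame, path) -> None:
    validate_lifespans(df).to_csv(path, index=False)


def write_flight(df: pd.DataFrame, path) -> None:
    validate_flight(df).to_csv(path, index=False)


def write_competition(df: pd.DataFrame, path) -> None:
    validate_competition(df).to_csv(path, index=False)
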