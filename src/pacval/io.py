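"""Reading and writing the three linked input tables.

All inputs are delimited text (CSV) with ISO-8601 dates:

* maternities: ``woman_id, maternity_id, delivery_date, gestation_weeks``
* hospital:    ``woman_id, record_id, admission_date, diag1 .. diag22``
  (diagnosis fields blank-padded on the right)
* registry:    ``woman_id, registry_id, diagnosis_date, group,
  first_notification_date``

Readers fail fast with the file and first offending row named in the error.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .codes import ClinicalGroup

__all__ = ["read_maternities", "read_hospital", "read_registry", "InputFormatError"]


class InputFormatError(ValueError):
    """An input file violates the expected schema."""


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap with filename
        raise InputFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def _parse_dates(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    parsed = pd.to_datetime(df[column], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & (df[column].astype(str).str.strip() != "")
    if bad.any() or parsed.isna().any():
        row = int(df.index[parsed.isna()][0]) + 2  # header + 1-based
        raise InputFormatError(
            f"{path}, line {row}: unparseable {column} "
            f"{df.loc[parsed.isna(), column].iloc[0]!r} (expected YYYY-MM-DD)"
        )
    return parsed


def read_maternities(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(
        path, {"woman_id", "maternity_id", "delivery_date", "gestation_weeks"}
    )
    df["delivery_date"] = _parse_dates(df, "delivery_date", path)
    try:
        df["gestation_weeks"] = df["gestation_weeks"].astype(int)
    except ValueError as exc:
        raise InputFormatError(
            f"{path}: non-integer gestation_weeks ({exc})"
        ) from exc
    return df


def read_hospital(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(path, {"woman_id", "record_id", "admission_date"})
    diag_cols = [c for c in df.columns if c.startswith("diag")]
    if not (1 <= len(diag_cols) <= 22):
        raise InputFormatError(
            f"{path}: expected 1–22 diagnosis columns, found {len(diag_cols)}"
        )
    df["admission_date"] = _parse_dates(df, "admission_date", path)
    return df


def read_registry(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(
        path,
        {"woman_id", "registry_id", "diagnosis_date", "group",
         "first_notification_date"},
    )
    df["diagnosis_date"] = _parse_dates(df, "diagnosis_date", path)
    df["first_notification_date"] = _parse_dates(
        df, "first_notification_date", path
    )
    valid = {g.value for g in ClinicalGroup}
    bad = ~df["group"].isin(valid)
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise InputFormatError(
            f"{path}, line {row}: unknown group label "
            f"{df.loc[bad, 'group'].iloc[0]!r}"
        )
    return df
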