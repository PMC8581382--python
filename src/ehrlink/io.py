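"""Readers for the delimited-text input tables.

All inputs are plain CSV with one header row and ISO-8601 dates:

* patients: ``patient_id, year_of_birth, sex, ethnicity16, lsoa,
  lambeth_resident, death_date``
* events: ``patient_id, source, terminology, code, event_date``
* consultations: ``patient_id, date, mode, care_home``
* prescriptions: ``patient_id, date, drug_class``
* IMD lookup: ``lsoa, quintile``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "True": True, "False": False}


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def _parse_dates(df: pd.DataFrame, col: str, path) -> pd.DataFrame:
    try:
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: malformed date in column {col!r}: {err}") from None
    return df


def _parse_bool(s: pd.Series) -> pd.Series:
    return s.map(lambda v: _BOOL_MAP.get(str(v).strip(), bool(v) if isinstance(v, bool) else None)).astype(bool)


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "ethnicity16": str, "lsoa": str})
    _require(df, ["patient_id", "year_of_birth"], path)
    if "lambeth_resident" in df:
        df["lambeth_resident"] = _parse_bool(df["lambeth_resident"])
    if "death_date" in df:
        dd = df["death_date"].astype("string").replace("", pd.NA)
        df["death_date"] = pd.to_datetime(dd, format="%Y-%m-%d")
    return df


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "code": str})
    _require(df, ["patient_id", "source", "terminology", "code", "event_date"], path)
    df = _parse_dates(df, "event_date", path)
    prim = df["source"] == "PRIMARY"
    bad = (prim & ~df["terminology"].isin(["READ", "SNOMED"])) | (~prim & (df["terminology"] != "ICD10"))
    if bad.any():
        raise ValueError(f"{path}: row {int(bad.idxmax()) + 2}: terminology inconsistent with source")
    return df


def read_consultations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require(df, ["patient_id", "date", "mode", "care_home"], path)
    df = _parse_dates(df, "date", path)
    df["care_home"] = _parse_bool(df["care_home"])
    return df


def read_prescriptions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require(df, ["patient_id", "date", "drug_class"], path)
    return _parse_dates(df, "date", path)


def read_imd_lookup(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, dtype={"lsoa": str})
    _require(df, ["lsoa", "quintile"], path)
    q = df["quintile"].astype(int)
    if ((q < 1) | (q > 5)).any():
        raise ValueError(f"{path}: IMD quintile outside 1-5")
    return dict(zip(df["lsoa"], q))
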