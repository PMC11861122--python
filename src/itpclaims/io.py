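"""Claims table schemas, readers/writers, and validation.

The claims dialect is four delimited text files, one per entity:

``patients.csv``
    patient_id, gender ({female, male}), birth_year,
    observation_start (YYYY-MM), observation_end (YYYY-MM)
``diagnoses.csv``
    patient_id, date (YYYY-MM-DD), code, suspected (0/1), inpatient (0/1)
``prescriptions.csv``
    patient_id, date, drug_class ({CS, EPAG, ROMI, RTX, OTHER_IS}),
    drug_name, route ({oral, injection}), daily_dose_mg, days_supplied
``procedures.csv``
    patient_id, date, procedure ({splenectomy})

Doses are native compound mg/day (prednisolone conversion happens in
:mod:`itpclaims.exposure`); ``days_supplied`` is the number of covered
days starting at ``date``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from itpclaims.config import DRUG_CLASSES

log = logging.getLogger(__name__)

PATIENT_COLUMNS = ["patient_id", "gender", "birth_year",
                   "observation_start", "observation_end"]
DIAGNOSIS_COLUMNS = ["patient_id", "date", "code", "suspected", "inpatient"]
PRESCRIPTION_COLUMNS = ["patient_id", "date", "drug_class", "drug_name",
                        "route", "daily_dose_mg", "days_supplied"]
PROCEDURE_COLUMNS = ["patient_id", "date", "procedure"]

FILE_SCHEMAS = {
    "patients": PATIENT_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "prescriptions": PRESCRIPTION_COLUMNS,
    "procedures": PROCEDURE_COLUMNS,
}


class SchemaError(ValueError):
    """A mandatory column is missing or mistyped."""


class ValidationError(ValueError):
    """Rows violate a stated invariant; offending row indices are listed."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(f"{message} (rows: {rows})")
        self.rows = rows


class ClaimsTables(NamedTuple):
    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    procedures: pd.DataFrame


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing mandatory column(s) "
                          f"{', '.join(missing)}")


def _parse_dates(df: pd.DataFrame, column: str, name: str) -> pd.Series:
    parsed = pd.to_datetime(df[column], format="%Y-%m-%d", errors="coerce")
    bad = df.index[parsed.isna() & df[column].notna()].tolist()
    if bad:
        raise ValidationError(f"{name}: unparseable {column}", bad)
    if parsed.isna().any():
        raise ValidationError(f"{name}: missing {column}",
                              df.index[parsed.isna()].tolist())
    return parsed


def _parse_months(df: pd.DataFrame, column: str, name: str) -> pd.PeriodIndex:
    parsed = pd.PeriodIndex(
        pd.to_datetime(df[column], format="%Y-%m", errors="coerce"), freq="M")
    bad = df.index[parsed.isna()].tolist()
    if bad:
        raise ValidationError(f"{name}: unparseable {column}", bad)
    return parsed


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, PATIENT_COLUMNS, "patients")
    df["observation_start"] = _parse_months(df, "observation_start",
                                            "patients")
    df["observation_end"] = _parse_months(df, "observation_end", "patients")
    df["birth_year"] = df["birth_year"].astype(int)
    bad = df.index[df["observation_start"] > df["observation_end"]].tolist()
    if bad:
        raise ValidationError(
            "patients: observation_start after observation_end", bad)
    bad = df.index[df["observation_start"].dt.year < df["birth_year"]].tolist()
    if bad:
        raise ValidationError("patients: negative age at observation_start",
                              bad)
    bad = df.index[~df["gender"].isin(["female", "male"])].tolist()
    if bad:
        raise ValidationError("patients: gender must be female or male", bad)
    if df["patient_id"].duplicated().any():
        raise ValidationError(
            "patients: duplicated patient_id",
            df.index[df["patient_id"].duplicated()].tolist())
    return df[PATIENT_COLUMNS]


def read_diagnoses(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "code": str})
    _require_columns(df, DIAGNOSIS_COLUMNS, "diagnoses")
    df["date"] = _parse_dates(df, "date", "diagnoses")
    df["suspected"] = df["suspected"].astype(int).astype(bool)
    df["inpatient"] = df["inpatient"].astype(int).astype(bool)
    return df[DIAGNOSIS_COLUMNS]


def read_prescriptions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "drug_name": str})
    _require_columns(df, PRESCRIPTION_COLUMNS, "prescriptions")
    df["date"] = _parse_dates(df, "date", "prescriptions")
    df["daily_dose_mg"] = df["daily_dose_mg"].astype(float)
    df["days_supplied"] = df["days_supplied"].astype(int)
    bad = df.index[df["daily_dose_mg"] < 0].tolist()
    if bad:
        raise ValidationError("prescriptions: negative daily_dose_mg", bad)
    bad = df.index[df["days_supplied"] < 1].tolist()
    if bad:
        raise ValidationError("prescriptions: days_supplied must be >= 1",
                              bad)
    bad = df.index[~df["route"].isin(["oral", "injection"])].tolist()
    if bad:
        raise ValidationError("prescriptions: route must be oral or "
                              "injection", bad)
    unknown = ~df["drug_class"].isin(DRUG_CLASSES)
    if unknown.any():
        names = sorted(df.loc[unknown, "drug_class"].unique())
        log.warning("prescriptions: %d rows with unknown drug_class %s "
                    "mapped to OTHER_IS", int(unknown.sum()), names)
        df.loc[unknown, "drug_class"] = "OTHER_IS"
    return df[PRESCRIPTION_COLUMNS]


def read_procedures(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "procedure": str})
    _require_columns(df, PROCEDURE_COLUMNS, "procedures")
    df["date"] = _parse_dates(df, "date", "procedures")
    return df[PROCEDURE_COLUMNS]


def read_claims(directory) -> ClaimsTables:
    """Read the four claims tables from ``directory``."""
    directory = Path(directory)
    return ClaimsTables(
        patients=read_patients(directory / "patients.csv"),
        diagnoses=read_diagnoses(directory / "diagnoses.csv"),
        prescriptions=read_prescriptions(directory / "prescriptions.csv"),
        procedures=read_procedures(directory / "procedures.csv"),
    )


def write_claims(tables: ClaimsTables, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables._asdict().items():
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
            elif isinstance(out[col].dtype, pd.PeriodDtype):
                out[col] = out[col].astype(str)
            elif pd.api.types.is_bool_dtype(out[col]):
                out[col] = out[col].astype(int)
        out.to_csv(directory / f"{name}.csv", index=False)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a stage output as delimited text (NaN -> empty string)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, na_rep="")


def read_results(path) -> pd.DataFrame:
    """Read back a stage output written by :func:`write_results`."""
    return pd.read_csv(path)


def roundtrips(table: pd.DataFrame, path) -> bool:
    """True when write/read reproduces values (the round-trip invariant)."""
    write_results(table, path)
    back = read_results(path)
    if list(back.columns) != list(table.columns):
        return False
    for col in table.columns:
        a, b = table[col], back[col]
        if pd.api.types.is_float_dtype(a):
            if not np.allclose(a.fillna(np.inf), b.fillna(np.inf)):
                return False
        elif not (a.astype(str).where(a.notna(), "")
                  == b.astype(str).where(b.notna(), "")).all():
            return False
    return True
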