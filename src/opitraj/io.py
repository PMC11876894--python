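"""Readers/writers for the four delimited claims tables and the ground-truth sidecar.

Layout (CSV, header row, UTF-8; dates are integer day offsets from an arbitrary
epoch, which keeps 30-day window arithmetic exact across claims dialects):

* ``patients.csv``      — patient_id, birth_offset_days, sex, region
* ``enrollment.csv``    — patient_id, start_day, end_day (inclusive span)
* ``prescriptions.csv`` — patient_id, day, drug_id, drug_class, route,
  strength_mg, quantity, days_supply
* ``diagnoses.csv``     — patient_id, day, code, category
* ``ground_truth.json`` — generator sidecar (absent for external data)
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

PATIENT_SCHEMA = {
    "patient_id": "string",
    "birth_offset_days": "int64",
    "sex": "string",
    "region": "string",
}
ENROLLMENT_SCHEMA = {"patient_id": "string", "start_day": "int64", "end_day": "int64"}
PRESCRIPTION_SCHEMA = {
    "patient_id": "string",
    "day": "int64",
    "drug_id": "string",
    "drug_class": "string",
    "route": "string",
    "strength_mg": "float64",
    "quantity": "float64",
    "days_supply": "int64",
}
DIAGNOSIS_SCHEMA = {"patient_id": "string", "day": "int64", "code": "string", "category": "string"}

TABLE_SCHEMAS = {
    "patients": PATIENT_SCHEMA,
    "enrollment": ENROLLMENT_SCHEMA,
    "prescriptions": PRESCRIPTION_SCHEMA,
    "diagnoses": DIAGNOSIS_SCHEMA,
}


def empty_table(name: str) -> pd.DataFrame:
    schema = TABLE_SCHEMAS[name]
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in schema.items()})


def coerce_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    """Reorder/retype columns to the canonical schema (idempotent)."""
    schema = TABLE_SCHEMAS[name]
    missing = set(schema) - set(df.columns)
    if missing:
        raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    return df[list(schema)].astype(schema).reset_index(drop=True)


def write_tables(tables: dict[str, pd.DataFrame], directory: str | Path) -> dict[str, int]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name in TABLE_SCHEMAS:
        df = coerce_table(name, tables[name])
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest[f"{name}.csv"] = len(df)
    return manifest


def read_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    tables = {}
    for name, schema in TABLE_SCHEMAS.items():
        path = directory / f"{name}.csv"
        df = pd.read_csv(path, dtype=schema)
        tables[name] = coerce_table(name, df)
    return tables


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
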