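"""Tables, configuration and report files.

Conventions: CSV with '.' decimal, UTF-8, units encoded in column names
(``counter_kBq``, ``specific_activity_kBq_per_1e6``) so unit drift is
visible at the schema level; JSON reports carry a ``schema_version``;
study configuration read from YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .phantom import WELL_TABLE_COLUMNS, StudyConfig

__all__ = [
    "read_well_table",
    "write_well_table",
    "read_study_config",
    "write_json_report",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"

_REQUIRED_WELL_COLUMNS = WELL_TABLE_COLUMNS


def write_well_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in _REQUIRED_WELL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"well table missing columns: {missing}")
    table.to_csv(path, index=False, encoding="utf-8")


def read_well_table(path) -> pd.DataFrame:
    """Read a well-record CSV with the fixed pipeline header.

    QC-excluded rows are retained (flagged, not dropped) so downstream
    stages decide inclusion themselves.  Basic validation: required
    columns present, cell numbers and activities non-negative.
    """
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:
        raise SchemaError(f"cannot read well table {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_WELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"well table {path} missing columns: {missing}")
    if (df["cell_number"] < 0).any():
        raise ValidationError("negative cell_number in well table")
    if (df["specific_activity_kBq_per_1e6"] < 0).any():
        raise ValidationError("negative specific activity in well table")
    df["qc_excluded"] = df["qc_excluded"].astype(bool)
    return df


def read_study_config(path) -> StudyConfig:
    """Load a :class:`StudyConfig` from YAML; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError("study config must be a YAML mapping")
    valid = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    for key in ("cell_level_medians", "sa_range", "cubic_loading"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in raw[key]
            )
    cfg = StudyConfig(**raw)
    cfg.validate()
    return cfg


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_json_report(payload: dict, path) -> None:
    """Write a JSON report with the pipeline schema version stamped in."""
    body = {"schema_version": SCHEMA_VERSION}
    body.update(_jsonable(payload))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(body, fh, indent=2, sort_keys=True)
        fh.write("\n")
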