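"""Data contracts: long-format monitoring CSV and solid-profile CSV.

Monitoring tables are long-format UTF-8 CSV with one row per (column, day,
port, analyte) observation:

    column_id,treatment,day,distance_m,analyte,value,censored,detection_limit

Units are fixed per analyte (toluene µg/L, fe2_dissolved mg/L) and declared
in '#'-prefixed header metadata lines, which also carry the configuration
hash and seed of the run that produced the file.  Validation collects *all*
violations and reports them together with row numbers, rather than stopping
at the first.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "MONITORING_COLUMNS",
    "ANALYTE_UNITS",
    "SCHEMA_VERSION",
    "MonitoringSchemaError",
    "validate_monitoring",
    "read_monitoring_csv",
    "write_monitoring_csv",
    "read_solid_profile_csv",
    "write_solid_profile_csv",
    "config_hash",
]

SCHEMA_VERSION = "1"
MONITORING_COLUMNS = [
    "column_id", "treatment", "day", "distance_m",
    "analyte", "value", "censored", "detection_limit",
]
ANALYTE_UNITS = {"toluene": "ug/L", "fe2_dissolved": "mg/L"}
_TREATMENTS = {"biotic", "sterile"}

PROFILE_COLUMNS = ["distance_m", "fe2_mg_per_kg"]
PROFILE_UNITS_LINE = "units: distance_m=m, fe2_mg_per_kg=mg/kg dry medium"


class MonitoringSchemaError(ValueError):
    """All schema violations of a monitoring table, collected together."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__(
            f"{len(errors)} monitoring-table violation(s):\n  " + "\n  ".join(errors)
        )


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping (for output headers)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def validate_monitoring(df: pd.DataFrame, column_length: Optional[float] = None) -> list[str]:
    """Return a list of violation messages (empty if the table is valid)."""
    errors: list[str] = []
    missing = [c for c in MONITORING_COLUMNS if c not in df.columns]
    if missing:
        errors.append(f"missing column(s): {missing}")
        return errors  # cannot check rows without the columns

    def rows(mask) -> str:
        idx = list(df.index[mask][:8])
        more = "" if mask.sum() <= 8 else f" (+{int(mask.sum()) - 8} more)"
        return f"rows {idx}{more}"

    bad = ~df["analyte"].isin(ANALYTE_UNITS)
    if bad.any():
        errors.append(
            f"unknown analyte(s) {sorted(df.loc[bad, 'analyte'].unique())}: {rows(bad)}"
        )
    bad = ~df["treatment"].isin(_TREATMENTS)
    if bad.any():
        errors.append(f"treatment must be one of {sorted(_TREATMENTS)}: {rows(bad)}")
    bad = pd.to_numeric(df["day"], errors="coerce") < 0
    if bad.any():
        errors.append(f"negative day: {rows(bad)}")
    dist = pd.to_numeric(df["distance_m"], errors="coerce")
    bad = ~(dist > 0)
    if column_length is not None:
        bad |= dist > column_length + 1e-9
    if bad.any():
        errors.append(f"distance_m out of (0, length]: {rows(bad)}")
    val = pd.to_numeric(df["value"], errors="coerce")
    bad = val.isna() | (val < 0)
    if bad.any():
        errors.append(f"negative or non-numeric value: {rows(bad)}")
    cens = df["censored"].astype(bool)
    dl = pd.to_numeric(df["detection_limit"], errors="coerce")
    bad = cens & ~np.isclose(val, dl, rtol=1e-9, atol=0)
    if bad.any():
        errors.append(f"censored rows must report value = detection_limit: {rows(bad)}")
    dup = df.duplicated(subset=["column_id", "day", "distance_m", "analyte"], keep=False)
    if dup.any():
        errors.append(f"duplicate (column_id, day, distance_m, analyte) key: {rows(dup)}")
    return errors


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_monitoring_csv(
    path: Union[str, Path], column_length: Optional[float] = None
) -> pd.DataFrame:
    """Read and validate a long-format monitoring CSV.

    Raises :class:`MonitoringSchemaError` listing every violation at once.
    The '#' metadata header is returned on the frame as ``df.attrs['metadata']``.
    """
    path = Path(path)
    meta = _read_metadata(path)
    if "schema" in meta and meta["schema"] != SCHEMA_VERSION:
        raise MonitoringSchemaError(
            [f"schema version {meta['schema']!r} != supported {SCHEMA_VERSION!r}"]
        )
    df = pd.read_csv(path, comment="#")
    errors = validate_monitoring(df, column_length=column_length)
    if errors:
        raise MonitoringSchemaError(errors)
    df["censored"] = df["censored"].astype(bool)
    df.attrs["metadata"] = meta
    return df


def write_monitoring_csv(
    df: pd.DataFrame, path: Union[str, Path], metadata: Optional[Mapping] = None
) -> Path:
    """Write a monitoring table with schema/units metadata header lines."""
    path = Path(path)
    errors = validate_monitoring(df)
    if errors:
        raise MonitoringSchemaError(errors)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        units = ", ".join(f"{a}={u}" for a, u in sorted(ANALYTE_UNITS.items()))
        fh.write(f"# units: {units}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, columns=MONITORING_COLUMNS, lineterminator="\n")
    return path


def read_solid_profile_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a solid-phase Fe(II) profile CSV; the units header is mandatory."""
    path = Path(path)
    meta = _read_metadata(path)
    if "units" not in meta:
        raise ValueError(
            f"{path}: solid-profile CSV must declare its units in a "
            f"'# {PROFILE_UNITS_LINE}' header line"
        )
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df.attrs["metadata"] = meta
    return df


def write_solid_profile_csv(
    df: pd.DataFrame, path: Union[str, Path], metadata: Optional[Mapping] = None
) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {PROFILE_UNITS_LINE}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        cols = [c for c in df.columns if c in PROFILE_COLUMNS + ["column_id", "day"]]
        df.to_csv(fh, index=False, columns=cols, lineterminator="\n")
    return path
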