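"""Cohort table I/O: CSV schema, validation and JSON run metadata.

Files use RFC-4180 CSV with a header row, UTF-8, ISO-8601 dates, 0/1 integers
for binary flags and the strings ``show_up`` / ``no_show`` for the outcome
(show-up is the positive class throughout the package).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from noshowpricing.cohort import BINARY_COVARIATES, COVARIATES, DEPARTMENTS

__all__ = [
    "CohortSchema",
    "SchemaError",
    "write_cohort",
    "read_cohort",
    "outcome_to_binary",
    "write_run_metadata",
    "read_run_metadata",
]

logger = logging.getLogger(__name__)

OUTCOME_LEVELS = ("no_show", "show_up")
GENDER_LEVELS = ("female", "male")


class SchemaError(ValueError):
    """A table does not conform to the cohort CSV schema."""


@dataclass(frozen=True)
class CohortSchema:
    """Ordered column names of the cohort table plus the outcome label."""

    columns: tuple[str, ...] = COVARIATES
    outcome_column: str = "outcome"

    def __post_init__(self) -> None:
        all_cols = self.all_columns
        if len(set(all_cols)) != len(all_cols):
            raise SchemaError("duplicate column names in schema")

    @property
    def all_columns(self) -> tuple[str, ...]:
        return self.columns + (self.outcome_column,)


DEFAULT_SCHEMA = CohortSchema()


def _validate(table: pd.DataFrame, schema: CohortSchema) -> pd.DataFrame:
    missing = [c for c in schema.all_columns if c not in table.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in table.columns if c not in schema.all_columns]
    if extra:
        raise SchemaError(f"unexpected column(s): {', '.join(extra)}")
    table = table[list(schema.all_columns)].copy()

    if table.isna().any().any():
        col = table.columns[table.isna().any().to_numpy()][0]
        row = int(table.index[table[col].isna()][0])
        raise SchemaError(f"missing value in column {col!r} at row {row}")

    def check_levels(col: str, levels: tuple[str, ...]) -> None:
        bad = ~table[col].isin(levels)
        if bad.any():
            row = int(table.index[bad][0])
            raise SchemaError(
                f"unknown level {table[col].iloc[int(np.flatnonzero(bad)[0])]!r} "
                f"in column {col!r} at row {row}"
            )

    check_levels(schema.outcome_column, OUTCOME_LEVELS)
    check_levels("gender", GENDER_LEVELS)
    check_levels("department", DEPARTMENTS)

    table["date"] = pd.to_datetime(table["date"], format="ISO8601", errors="coerce")
    if table["date"].isna().any():
        row = int(table.index[table["date"].isna()][0])
        raise SchemaError(f"unparseable ISO date in column 'date' at row {row}")

    for col in BINARY_COVARIATES + ("weekend_flag",):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any() or not vals.isin((0, 1)).all():
            bad = ~vals.isin((0, 1)) | vals.isna()
            row = int(table.index[bad][0])
            raise SchemaError(f"non-binary value in column {col!r} at row {row}")
        table[col] = vals.astype(int)

    derived_weekend = (pd.DatetimeIndex(table["date"]).dayofweek >= 5).astype(int)
    if (table["weekend_flag"].to_numpy() != derived_weekend).any():
        row = int(np.flatnonzero(table["weekend_flag"].to_numpy() != derived_weekend)[0])
        raise SchemaError(f"weekend_flag inconsistent with date at row {row}")

    ages = pd.to_numeric(table["age"], errors="coerce")
    if ages.isna().any() or (ages < 0).any():
        bad = ages.isna() | (ages < 0)
        row = int(table.index[bad][0])
        raise SchemaError(f"invalid age at row {row}")
    table["age"] = ages.astype(int)

    locs = pd.to_numeric(table["location_id"], errors="coerce")
    if locs.isna().any() or (locs < 0).any() or (locs != locs.astype(int)).any():
        raise SchemaError("location_id must be a non-negative integer zone code")
    table["location_id"] = locs.astype(int)
    return table


def write_cohort(table: pd.DataFrame, path: str | Path, schema: CohortSchema = DEFAULT_SCHEMA) -> Path:
    """Validate *table* against the schema and write it as CSV. Returns the path."""
    path = Path(path)
    out = _validate(table, schema)
    out = out.assign(date=pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    logger.info("wrote cohort with %d rows to %s", len(out), path)
    return path


def read_cohort(path: str | Path, schema: CohortSchema = DEFAULT_SCHEMA) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises :class:`SchemaError` on violations."""
    path = Path(path)
    raw = pd.read_csv(path, dtype={"location_id": "Int64"})
    table = _validate(raw, schema)
    logger.info("read cohort with %d rows from %s", len(table), path)
    return table


def outcome_to_binary(outcome: pd.Series) -> np.ndarray:
    """Map outcome strings to 0/1 with show-up as the positive class."""
    bad = ~outcome.isin(OUTCOME_LEVELS)
    if bad.any():
        raise SchemaError(f"non-binary outcome value {outcome[bad].iloc[0]!r}")
    return (outcome == "show_up").to_numpy(dtype=int)


def config_digest(config: object) -> str:
    """Stable SHA-256 digest of a configuration object's repr."""
    return hashlib.sha256(repr(config).encode()).hexdigest()


def write_run_metadata(
    path: str | Path, *, seed: int, config: object, timestamp: str | None = None
) -> Path:
    """JSON sidecar recording the seed and a digest of the generating config.

    *timestamp* is optional so that fully deterministic pipelines can produce
    byte-identical sidecars across reruns.
    """
    path = Path(path)
    meta = {"seed": seed, "config": repr(config), "config_sha256": config_digest(config)}
    if timestamp is not None:
        meta["timestamp"] = timestamp
    path.write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    return path


def read_run_metadata(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
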