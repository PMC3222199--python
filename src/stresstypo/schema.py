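"""Cohort data model: variable schemas, CSV ingestion, cleaning and standardization.

A cohort is a flat table of per-respondent records in which every column has a
declared measurement level -- ``nominal``, ``ordinal`` or ``numeric``.  The
level drives everything downstream: how a column is optimally scaled, whether
it can be z-scored, and how it is validated on input.  Schemas are plain
YAML/JSON documents so an analysis is reproducible from two text files
(data CSV + schema).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

LEVELS = ("nominal", "ordinal", "numeric")

#: Default plausibility bounds used to flag "unrealistic" numeric entries.
#: Units follow the conventional clinical ones (mg/dL, mmHg, cm, kg).
DEFAULT_PLAUSIBLE_RANGES: dict[str, tuple[float, float]] = {
    "glucose": (40.0, 500.0),
    "sbp": (70.0, 250.0),
    "dbp": (40.0, 150.0),
    "height": (120.0, 220.0),
    "weight": (35.0, 250.0),
    "waist": (40.0, 200.0),
    "total_chol": (50.0, 500.0),
    "hdl": (10.0, 150.0),
    "triglycerides": (20.0, 1000.0),
}


class SchemaError(ValueError):
    """Raised when a schema file or a record violates the declared schema."""


@dataclass(frozen=True)
class VariableSpec:
    """Declared measurement properties of one cohort variable.

    Parameters
    ----------
    name : str
        Column name, unique within a schema.
    level : {"nominal", "ordinal", "numeric"}
        Measurement level.  Ordinal categories are listed in their declared
        order; that order is the monotonicity constraint used by optimal
        scaling.
    categories : tuple of str
        Category labels (empty for numeric variables).
    units : str
        Free-text unit annotation.
    plausible_range : (float, float), optional
        Inclusive bounds outside which a numeric value is treated as
        unrealistic by :func:`apply_exclusions`.
    """

    name: str
    level: str
    categories: tuple[str, ...] = ()
    units: str = ""
    plausible_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise SchemaError(
                f"variable {self.name!r}: level must be one of {LEVELS}, got {self.level!r}"
            )
        object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        if self.level == "numeric":
            if self.categories:
                raise SchemaError(f"numeric variable {self.name!r} must not declare categories")
        else:
            if self.level == "ordinal" and len(self.categories) < 2:
                raise SchemaError(
                    f"ordinal variable {self.name!r} needs >=2 categories in declared order"
                )
            if self.level == "nominal" and len(self.categories) < 1:
                raise SchemaError(f"nominal variable {self.name!r} needs >=1 category")
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"variable {self.name!r}: duplicate category labels")
        if self.plausible_range is not None:
            lo, hi = self.plausible_range
            if not (lo < hi):
                raise SchemaError(f"variable {self.name!r}: plausible_range must satisfy lo < hi")
            object.__setattr__(self, "plausible_range", (float(lo), float(hi)))

    @property
    def is_categorical(self) -> bool:
        return self.level in ("nominal", "ordinal")


@dataclass
class CohortTable:
    """A schema-validated cohort: one row per respondent.

    ``data`` holds categorical columns as strings and numeric columns as
    floats; the index is the stable respondent identifier.
    """

    schema: list[VariableSpec]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        names = [v.name for v in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("schema has duplicate variable names")
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise SchemaError(f"data is missing schema columns: {missing}")
        self.data = self.data[names]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> dict[str, VariableSpec]:
        return {v.name: v for v in self.schema}

    def levels(self) -> dict[str, str]:
        return {v.name: v.level for v in self.schema}

    def validate(self) -> None:
        """Check every non-missing categorical value against its category list."""
        if len(self.data) == 0:
            raise SchemaError("no records")
        for spec in self.schema:
            col = self.data[spec.name]
            if spec.is_categorical:
                observed = col.dropna()
                bad = ~observed.isin(spec.categories)
                if bad.any():
                    row = observed.index[bad][0]
                    raise SchemaError(
                        f"unknown category {observed[bad].iloc[0]!r} for variable "
                        f"{spec.name!r} at row {row!r}"
                    )
            else:
                if not pd.api.types.is_numeric_dtype(col):
                    raise SchemaError(f"numeric variable {spec.name!r} has non-numeric dtype")

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="row_id")


@dataclass(frozen=True)
class CleaningReport:
    """Outcome of listwise exclusion: every dropped row carries a reason."""

    n_input: int
    n_retained: int
    exclusions: tuple[tuple[object, str], ...]

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + len(self.exclusions):
            raise ValueError("inconsistent cleaning report counts")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "exclusions": [{"row_id": r, "reason": why} for r, why in self.exclusions],
        }


# ---------------------------------------------------------------------------
# schema / cohort IO


def load_schema(path: str | Path) -> list[VariableSpec]:
    """Read a schema from YAML or JSON (a mapping with a ``variables`` list)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise SchemaError(f"{path}: expected a mapping with a 'variables' list")
    specs = []
    for entry in doc["variables"]:
        entry = dict(entry)
        if "plausible_range" in entry and entry["plausible_range"] is not None:
            entry["plausible_range"] = tuple(entry["plausible_range"])
        specs.append(VariableSpec(**entry))
    return specs


def save_schema(schema: Sequence[VariableSpec], path: str | Path) -> None:
    doc = {
        "variables": [
            {
                "name": v.name,
                "level": v.level,
                **({"categories": list(v.categories)} if v.categories else {}),
                **({"units": v.units} if v.units else {}),
                **(
                    {"plausible_range": list(v.plausible_range)}
                    if v.plausible_range is not None
                    else {}
                ),
            }
            for v in schema
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_cohort(path: str | Path, schema_path: str | Path) -> CohortTable:
    """Read a cohort CSV against a schema, coercing values to declared levels.

    Categorical values are whitespace-trimmed and matched case-sensitively;
    empty cells become missing.  Unparsable numeric cells and unknown category
    labels raise :class:`SchemaError` naming the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = load_schema(schema_path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "row_id" in raw.columns:
        raw = raw.set_index("row_id")
    if len(raw) == 0:
        raise SchemaError("no records")
    header = set(raw.columns)
    missing = [v.name for v in schema if v.name not in header]
    if missing:
        raise SchemaError(f"CSV header is missing schema columns: {missing}")

    cols: dict[str, pd.Series] = {}
    for spec in schema:
        col = raw[spec.name].str.strip()
        blank = col == ""
        if spec.level == "numeric":
            parsed = pd.to_numeric(col.mask(blank), errors="coerce")
            bad = parsed.isna() & ~blank
            if bad.any():
                row = col.index[bad][0]
                raise SchemaError(
                    f"numeric field {spec.name!r} unparsable at row {row!r}: {col[bad].iloc[0]!r}"
                )
            cols[spec.name] = parsed
        else:
            values = col.mask(blank)
            cols[spec.name] = values
    table = CohortTable(schema=schema, data=pd.DataFrame(cols, index=raw.index))
    table.validate()
    return table


# ---------------------------------------------------------------------------
# cleaning and standardization


def apply_exclusions(table: CohortTable) -> tuple[CohortTable, CleaningReport]:
    """Listwise exclusion of incomplete or unrealistic records.

    A record is dropped, with reason ``"incomplete"``, if any schema field is
    missing, and with reason ``"unrealistic"`` if any numeric value falls
    outside the variable's ``plausible_range``.  Always returns a report; the
    retained set does not depend on row order.
    """
    data = table.data
    reasons: list[tuple[object, str]] = []
    drop: set = set()
    missing_mask = data.isna().any(axis=1)
    for row_id in data.index[missing_mask]:
        reasons.append((row_id, "incomplete"))
        drop.add(row_id)
    for spec in table.schema:
        if spec.level != "numeric" or spec.plausible_range is None:
            continue
        lo, hi = spec.plausible_range
        col = data[spec.name]
        bad = (col < lo) | (col > hi)
        for row_id in data.index[bad.fillna(False)]:
            if row_id not in drop:
                reasons.append((row_id, f"unrealistic: {spec.name}"))
                drop.add(row_id)
    kept = data.loc[~data.index.isin(drop)]
    report = CleaningReport(
        n_input=len(data), n_retained=len(kept), exclusions=tuple(reasons)
    )
    return CohortTable(schema=list(table.schema), data=kept.copy()), report


def zscore_columns(
    table: CohortTable | pd.DataFrame,
    names: Iterable[str] | None = None,
    *,
    ddof: int = 1,
) -> pd.DataFrame:
    """Standardize named numeric columns to mean 0, SD 1.

    The SD denominator is the sample convention (``ddof=1``) by default, the
    same convention as conventional descriptive tables; pass ``ddof=0`` for
    the population convention.  A constant column raises ``ValueError``.
    """
    data = table.data if isinstance(table, CohortTable) else table
    if names is None:
        names = list(data.columns)
    names = list(names)
    out = {}
    for name in names:
        col = pd.to_numeric(data[name], errors="raise").astype(float)
        sd = col.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero variance in column {name!r}")
        out[name] = (col - col.mean()) / sd
    return pd.DataFrame(out, index=data.index)
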