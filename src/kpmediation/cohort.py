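"""Long-format cohort table: schema, I/O, validation, inclusion filter.

A cohort is one record per participant-visit. Visits are the three
posttreatment measurement rounds (T1 = 6 weeks, T2 = 6 months, T3 = 12
months). Each column carries a role (exposure, mediator, outcome,
covariate, id, time) declared in a :class:`VariableSchema`, which is what
the validation and the downstream model builders key off.

Missing values are empty CSV fields; complete-case handling is done per
model downstream, never at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError, IntegrityError, SchemaError, ValidationError

#: Ordered visit labels and their nominal weeks posttreatment.
VISITS = ("T1", "T2", "T3")
VISIT_WEEKS = {"T1": 6, "T2": 26, "T3": 52}

ROLES = ("exposure", "mediator", "outcome", "covariate", "id", "time")


@dataclass(frozen=True)
class ColumnDef:
    """Role, unit, measurement level and value bounds of one column.

    ``bounds`` is an inclusive (low, high) pair, either end open when
    None. Observed-data schemas declare (0, 100) for HRQoL scales and
    (0, None) for metabolite concentrations; schemas for untransformed
    Gaussian synthetic outcomes omit them.
    """

    role: str
    unit: str = ""
    kind: str = "continuous"  # continuous | categorical
    levels: tuple[str, ...] | None = None
    bounds: tuple[float | None, float | None] | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r}")
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"unknown kind {self.kind!r}")
        if self.kind == "categorical" and not self.levels:
            raise SchemaError("categorical column needs explicit levels")


class VariableSchema:
    """Mapping of column name -> :class:`ColumnDef` with YAML round-trip."""

    def __init__(self, columns: Mapping[str, ColumnDef]):
        self.columns = dict(columns)

    def __contains__(self, name: str) -> bool:
        return name in self.columns

    def __getitem__(self, name: str) -> ColumnDef:
        return self.columns[name]

    def names(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.columns)
        return [n for n, c in self.columns.items() if c.role == role]

    def categorical(self) -> list[str]:
        return [n for n, c in self.columns.items() if c.kind == "categorical"]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "columns": {
                n: {
                    "role": c.role,
                    "unit": c.unit,
                    "kind": c.kind,
                    **({"levels": list(c.levels)} if c.levels else {}),
                    **({"bounds": list(c.bounds)} if c.bounds else {}),
                }
                for n, c in self.columns.items()
            }
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableSchema":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict) or "columns" not in payload:
            raise SchemaError(f"{path}: not a schema file (missing 'columns')")
        cols = {}
        for name, raw in payload["columns"].items():
            levels = raw.get("levels")
            bounds = raw.get("bounds")
            cols[name] = ColumnDef(
                role=raw.get("role", "covariate"),
                unit=raw.get("unit", ""),
                kind=raw.get("kind", "continuous"),
                levels=tuple(levels) if levels else None,
                bounds=tuple(bounds) if bounds else None,
            )
        return cls(cols)


@dataclass
class LongCohortTable:
    """Validated participant-visit table plus its schema.

    ``data`` holds one row per (subject, visit); validation enforces
    uniqueness of that key, the fixed visit label set, categorical levels,
    the 0-100 range of HRQoL outcome columns, and non-negativity of
    metabolite (mediator) concentrations.
    """

    data: pd.DataFrame
    schema: VariableSchema
    id_col: str = "subject_id"
    visit_col: str = "visit"

    def __post_init__(self):
        self.validate()

    # -- structure -----------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data[self.id_col].nunique()

    def validate(self) -> None:
        df = self.data
        for col in (self.id_col, self.visit_col):
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        dup = df.duplicated(subset=[self.id_col, self.visit_col])
        if dup.any():
            first = df.loc[dup, [self.id_col, self.visit_col]].iloc[0]
            raise IntegrityError(
                f"duplicate record for subject {first[self.id_col]!r} "
                f"visit {first[self.visit_col]!r}"
            )
        bad_visit = ~df[self.visit_col].isin(VISITS)
        if bad_visit.any():
            raise ValidationError(
                f"visit label {df.loc[bad_visit, self.visit_col].iloc[0]!r} "
                f"not in {VISITS}",
                row=int(np.flatnonzero(bad_visit)[0]),
            )
        for name, cdef in self.schema.columns.items():
            if name not in df.columns:
                continue
            col = df[name]
            if cdef.kind == "categorical":
                bad = col.notna() & ~col.isin(cdef.levels)
                if bad.any():
                    i = int(np.flatnonzero(bad)[0])
                    raise ValidationError(
                        f"column {name!r}: value {col.iloc[i]!r} not among "
                        f"levels {cdef.levels}",
                        row=i,
                    )
            elif cdef.bounds is not None:
                lo, hi = cdef.bounds
                vals = pd.to_numeric(col, errors="coerce")
                bad = vals.notna() & (
                    (vals < (lo if lo is not None else -np.inf))
                    | (vals > (hi if hi is not None else np.inf))
                )
                if bad.any():
                    i = int(np.flatnonzero(bad)[0])
                    raise ValidationError(
                        f"column {name!r}: value {vals.iloc[i]} outside "
                        f"[{lo}, {hi}]",
                        row=i,
                    )


@dataclass
class InclusionResult:
    """Filtered table plus the identities of the subjects removed."""

    table: LongCohortTable
    dropped_subjects: list = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_subjects)


def load_cohort(path: str | Path, schema: VariableSchema) -> LongCohortTable:
    """Read a cohort CSV, coerce types against ``schema`` and validate.

    Raises :class:`SchemaError` if a schema column is absent from the
    file, :class:`ValidationError` (with row index) for out-of-level
    categorical values or out-of-range outcomes, :class:`IntegrityError`
    for duplicated (subject, visit) keys.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in schema.names() if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for name, cdef in schema.columns.items():
        if cdef.kind == "continuous" and name not in ("subject_id", "visit"):
            df[name] = pd.to_numeric(df[name], errors="coerce")
    return LongCohortTable(df, schema)


def write_cohort(table: LongCohortTable, path: str | Path) -> None:
    """Write the cohort as RFC-4180-style CSV (UTF-8, empty = missing)."""
    table.data.to_csv(path, index=False, encoding="utf-8")


def inclusion_filter(
    table: LongCohortTable, required: Iterable[str]
) -> InclusionResult:
    """Keep subjects with >= 1 visit complete on all ``required`` columns.

    Mirrors the study's inclusion rule: a participant enters the analysis
    set if at least one posttreatment measurement has dietary intake,
    metabolites, HRQoL and the relevant covariates all observed. All
    records of a retained subject are kept, including incomplete ones.
    """
    required = list(required)
    if not required:
        raise ContractError("required column list must be non-empty")
    missing = [c for c in required if c not in table.data.columns]
    if missing:
        raise SchemaError(f"required column(s) not in table: {missing}")
    df = table.data
    complete = df[required].notna().all(axis=1)
    keep_ids = set(df.loc[complete, table.id_col])
    dropped = sorted(set(df[table.id_col]) - keep_ids)
    kept = df[df[table.id_col].isin(keep_ids)].reset_index(drop=True)
    return InclusionResult(
        LongCohortTable(kept, table.schema, table.id_col, table.visit_col),
        dropped_subjects=dropped,
    )
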