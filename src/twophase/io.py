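"""CSV schemas and validation for the pipeline's tabular artifacts.

All artifacts are plain RFC-4180 CSV with a header row; booleans are written
as 0/1.  :func:`validate_schema` checks column presence, types and ranges and
returns a report with the first violations rather than raising, so callers
can surface row/column context to the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import COHORT_COLUMNS
from .population import PATIENT_COLUMNS

#: Known schemas: {name: {column: (dtype kind, check)}}.  ``check`` is a
#: vectorized predicate returning a boolean "valid" mask, or None.
SCHEMAS: dict[str, dict] = {
    "patients": {
        "patient_id": ("i", None),
        "clinic_id": ("O", None),
        "clinic_type": ("O", lambda s: s.isin(["public", "private"])),
        "region": ("O", lambda s: s.isin(["South", "Central/North"])),
        "year": ("i", lambda s: s.isin([2005, 2006, 2007])),
        "quarter": ("i", lambda s: s.between(1, 4)),
        "cohort_id": ("O", None),
        "age": ("i", lambda s: s >= 16),
        "female": ("i", lambda s: s.isin([0, 1])),
        "who34": ("i", lambda s: s.isin([0, 1])),
        "outcome": ("i", lambda s: s.isin([0, 1])),
    },
    "cohorts": {
        "cohort_id": ("O", None),
        "clinic_id": ("O", None),
        "clinic_type": ("O", lambda s: s.isin(["public", "private"])),
        "region": ("O", lambda s: s.isin(["South", "Central/North"])),
        "year": ("i", lambda s: s.isin([2005, 2006, 2007])),
        "n_total": ("i", lambda s: s >= 1),
        "n_negative": ("i", lambda s: s >= 0),
        "mean_age": ("f", lambda s: s >= 16),
        "pct_female": ("f", lambda s: s.between(0, 1)),
        "pct_who34": ("f", lambda s: s.between(0, 1)),
    },
    "phase1": {
        "stratum": ("O", None),
        "N0": ("i", lambda s: s >= 0),
        "N1": ("i", lambda s: s >= 0),
    },
    "allocation": {
        "outcome": ("i", lambda s: s.isin([0, 1])),
        "stratum": ("O", None),
        "N": ("i", lambda s: s >= 0),
        "n": ("i", lambda s: s >= 0),
    },
    "power": {
        "design": ("O", None),
        "n": ("O", None),
        "estimator": ("O", None),
        "replicates": ("i", lambda s: s >= 1),
        "power": ("f", lambda s: s.between(0, 1)),
        "mc_se": ("f", lambda s: s >= 0),
        "n_converged": ("i", lambda s: s >= 0),
    },
}

#: Cross-column invariants per schema.
_TABLE_CHECKS = {
    "cohorts": [
        ("n_negative<=n_total", lambda df: df["n_negative"] <= df["n_total"]),
    ],
    "allocation": [
        ("n<=N", lambda df: df["n"] <= df["N"]),
    ],
}


@dataclass
class ValidationReport:
    schema: str
    ok: bool
    n_rows: int
    violations: list = field(default_factory=list)  # (row, column, message)

    def __str__(self):
        head = f"schema={self.schema} rows={self.n_rows} -> {'PASS' if self.ok else 'FAIL'}"
        lines = [f"  row {r}, column {c}: {m}" for r, c, m in self.violations]
        return "\n".join([head, *lines])


def validate_schema(source, schema_name: str, max_violations: int = 10) -> ValidationReport:
    """Validate a CSV file (or DataFrame) against a named schema."""
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}")
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    spec = SCHEMAS[schema_name]
    violations: list[tuple] = []

    for col, (kind, check) in spec.items():
        if col not in df.columns:
            violations.append(("-", col, "missing column"))
            continue
        s = df[col]
        if kind in ("i", "f"):
            coerced = pd.to_numeric(s, errors="coerce")
            bad = coerced.isna() & s.notna()
            for r in np.flatnonzero(bad)[: max_violations]:
                violations.append((int(r), col, f"not numeric: {s.iloc[r]!r}"))
            s = coerced
            if kind == "i" and not bad.any():
                frac = s.dropna() % 1
                for r in np.flatnonzero((frac != 0).reindex(s.index, fill_value=False))[:max_violations]:
                    violations.append((int(r), col, "not an integer"))
        if check is not None:
            valid = check(s) | s.isna()
            for r in np.flatnonzero(~valid.to_numpy())[: max_violations]:
                violations.append((int(r), col, f"out of range: {df[col].iloc[r]!r}"))

    for name, check in _TABLE_CHECKS.get(schema_name, []):
        try:
            valid = check(df)
        except (KeyError, TypeError):
            continue  # already reported as missing/mistyped columns
        for r in np.flatnonzero(~valid.to_numpy())[: max_violations]:
            violations.append((int(r), name, "invariant violated"))

    violations = violations[:max_violations]
    return ValidationReport(
        schema=schema_name, ok=not violations, n_rows=len(df), violations=violations
    )


def write_patients(patients: pd.DataFrame, path: str | Path) -> None:
    patients[PATIENT_COLUMNS].to_csv(path, index=False)


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("female", "who34", "outcome"):
        df[col] = df[col].astype(np.int8)
    return df


def write_cohorts(cohorts: pd.DataFrame, path: str | Path) -> None:
    cohorts[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohorts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sample(sample, path: str | Path) -> None:
    """Write a two-phase sample: patient schema plus stratum and weight columns."""
    sample.data.to_csv(path, index=False)


def write_phase1(phase1, path: str | Path) -> None:
    phase1.counts.reset_index().to_csv(path, index=False)


def write_allocation(allocation, path: str | Path) -> None:
    allocation.table.to_csv(path, index=False)
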