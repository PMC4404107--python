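"""Collapse patient records into quarterly-clinic cohort aggregates.

This mimics the routinely collected facility-level record: one row per
quarterly-clinic cohort carrying only marginal summaries (counts, mean age,
percent female, percent WHO stage 3/4, negative-outcome count) and no
cross-classified information.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Column order of the cohort table (the package's cohort CSV schema).
COHORT_COLUMNS = [
    "cohort_id",
    "clinic_id",
    "clinic_type",
    "region",
    "year",
    "n_total",
    "n_negative",
    "mean_age",
    "pct_female",
    "pct_who34",
]


def aggregate_cohorts(patients: pd.DataFrame) -> pd.DataFrame:
    """One aggregate record per distinct cohort_id.

    Summaries are exact sample statistics of the cohort's patients; cohorts
    with zero registrants never appear (the routine system only creates a
    record when patients register).  Raises if patients within a cohort
    disagree on clinic-level attributes, which would indicate a corrupted
    table.
    """
    if np.any(patients["outcome"].to_numpy() < 0):
        raise ValueError("outcomes must be assigned before aggregation")
    g = patients.groupby("cohort_id", sort=True)
    attrs = g[["clinic_id", "clinic_type", "region", "year"]].nunique()
    bad = attrs[(attrs > 1).any(axis=1)]
    if len(bad):
        raise ValueError(
            f"cohorts with inconsistent clinic attributes: {list(bad.index[:5])}"
        )
    out = pd.DataFrame(
        {
            "clinic_id": g["clinic_id"].first(),
            "clinic_type": g["clinic_type"].first(),
            "region": g["region"].first(),
            "year": g["year"].first(),
            "n_total": g.size(),
            "n_negative": g["outcome"].sum().astype(np.int64),
            "mean_age": g["age"].mean(),
            "pct_female": g["female"].mean(),
            "pct_who34": g["who34"].mean(),
        }
    ).reset_index()
    return out[COHORT_COLUMNS]


def check_consistency(patients: pd.DataFrame, cohorts: pd.DataFrame) -> pd.DataFrame:
    """Compare patient-level and cohort-level margins; report, never raise.

    Returns one row per checked margin with the two totals and an equality
    flag.  On an untampered pair every flag is True.
    """
    rows = []

    def add(margin, patient_value, cohort_value):
        rows.append(
            {
                "margin": margin,
                "patients": int(patient_value),
                "cohorts": int(cohort_value),
                "equal": int(patient_value) == int(cohort_value),
            }
        )

    add("total_patients", len(patients), cohorts["n_total"].sum())
    add("total_negative", patients["outcome"].sum(), cohorts["n_negative"].sum())
    for ctype, n in patients.groupby("clinic_type").size().items():
        add(
            f"clinic_type={ctype}",
            n,
            cohorts.loc[cohorts["clinic_type"] == ctype, "n_total"].sum(),
        )
    for year, n in patients.groupby("year").size().items():
        add(f"year={year}", n, cohorts.loc[cohorts["year"] == year, "n_total"].sum())
    for region, n in patients.groupby("region").size().items():
        add(
            f"region={region}",
            n,
            cohorts.loc[cohorts["region"] == region, "n_total"].sum(),
        )
    return pd.DataFrame(rows)
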