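"""Phase-I stratification and phase-II sampling for two-phase designs.

A two-phase design stratifies the *entire* registrant population (phase I)
on outcome status crossed with information that is already available in the
aggregated quarterly-clinic cohort records, then draws a without-replacement
subsample within each (outcome, stratum) cell (phase II) on which detailed
patient data are collected.

Six stratification schemes are supported, all computable from cohort-level
data alone:

=========  ==========================================================
design1    clinic type (public / private)
design2    clinic type x registration year
design3    cohort percent WHO stage 1/2 (<=5% vs >5%)
design4    cohort average age (<=35 / 36-40 / >40 years)
design5    cohort percent female (0 / 1-40 / 41-50 / 51-60 / 60-99 / 100%)
design6    WHO band x clinic type
case_control  the single-stratum special case (outcome only)
=========  ==========================================================

Allocation follows the balanced rule: an equal target per (outcome, stratum)
cell, with cells smaller than their target exhausted and the shortfall
redistributed equally among the unexhausted cells of the same outcome
level (crossing outcome levels only as a last resort).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import aggregate_cohorts

DESIGN_NAMES = (
    "design1",
    "design2",
    "design3",
    "design4",
    "design5",
    "design6",
    "case_control",
)


class AllocationError(ValueError):
    """Raised when a phase-II allocation is infeasible."""


def _labels_design5(pf: np.ndarray) -> np.ndarray:
    out = np.empty(len(pf), dtype=object)
    out[pf == 0.0] = "pf=0%"
    out[(pf > 0.0) & (pf <= 0.405)] = "pf1-40%"
    out[(pf > 0.405) & (pf <= 0.505)] = "pf41-50%"
    out[(pf > 0.505) & (pf <= 0.605)] = "pf51-60%"
    out[(pf > 0.605) & (pf < 1.0)] = "pf60-99%"
    out[pf == 1.0] = "pf=100%"
    return out


def cohort_strata(cohorts: pd.DataFrame, design: str) -> pd.Series:
    """Stratum label of each cohort under the named design."""
    ctype = cohorts["clinic_type"].astype(str)
    if design == "design1":
        labels = ctype
    elif design == "design2":
        labels = cohorts["year"].astype(str) + "/" + ctype
    elif design == "design3":
        who12 = 1.0 - cohorts["pct_who34"].to_numpy()
        labels = pd.Series(
            np.where(who12 <= 0.05, "who12<=5%", "who12>5%"), index=cohorts.index
        )
    elif design == "design4":
        ma = cohorts["mean_age"].to_numpy()
        labels = pd.Series(
            np.select([ma <= 35.0, ma <= 40.0], ["age<=35", "age36-40"], "age>40"),
            index=cohorts.index,
        )
    elif design == "design5":
        labels = pd.Series(
            _labels_design5(cohorts["pct_female"].to_numpy()), index=cohorts.index
        )
    elif design == "design6":
        who12 = 1.0 - cohorts["pct_who34"].to_numpy()
        who = np.where(who12 <= 0.05, "who12<=5%", "who12>5%")
        labels = pd.Series(who, index=cohorts.index) + "/" + ctype
    elif design == "case_control":
        labels = pd.Series("all", index=cohorts.index)
    else:
        raise KeyError(f"unknown design {design!r}; choose from {DESIGN_NAMES}")
    return labels.rename("stratum")


@dataclass
class PhaseOneTable:
    """Population counts N_ys per (outcome y, phase-I stratum s).

    ``counts`` is indexed by stratum label with integer columns ``N0``
    (non-negative status) and ``N1`` (negative status).  When built from a
    patient table, ``patient_strata`` maps each patient (by table index) to
    its stratum so phase-II draws can locate cell members.
    """

    design: str
    counts: pd.DataFrame
    patient_strata: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self):
        c = self.counts
        if (c < 0).any().any() or not all(col in c.columns for col in ("N0", "N1")):
            raise ValueError("counts must have non-negative N0/N1 columns")
        self.counts = c[["N0", "N1"]].astype(np.int64)

    @classmethod
    def from_counts(cls, design: str, mapping: dict) -> "PhaseOneTable":
        """Build from ``{stratum: (non_negative, negative)}`` count pairs."""
        labels = [
            "/".join(str(p) for p in k) if isinstance(k, tuple) else str(k)
            for k in mapping
        ]
        counts = pd.DataFrame(
            {
                "N0": [v[0] for v in mapping.values()],
                "N1": [v[1] for v in mapping.values()],
            },
            index=pd.Index(labels, name="stratum"),
        )
        return cls(design=design, counts=counts)

    @property
    def strata(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_cases(self) -> int:
        return int(self.counts["N1"].sum())

    @property
    def n_controls(self) -> int:
        return int(self.counts["N0"].sum())

    def cell(self, outcome: int, stratum: str) -> int:
        return int(self.counts.loc[stratum, f"N{outcome}"])


def build_phase1(
    patients: pd.DataFrame, design: str, cohorts: pd.DataFrame | None = None
) -> PhaseOneTable:
    """Cross-classify every patient by outcome and its cohort's stratum.

    ``design1``/``design2``/``case_control`` need only patient columns;
    covariate-based designs need the cohort aggregates, which are computed on
    the fly when not supplied.
    """
    if np.any(patients["outcome"].to_numpy() < 0):
        raise ValueError("outcomes must be assigned before phase-I stratification")
    if design in ("design1", "design2", "case_control"):
        # these strata depend only on columns the patient table carries itself
        strata = cohort_strata(patients, design)
    else:
        if cohorts is None:
            cohorts = aggregate_cohorts(patients)
        cohort_lab = cohort_strata(cohorts, design)
        lookup = pd.Series(cohort_lab.to_numpy(), index=cohorts["cohort_id"])
        missing = set(patients["cohort_id"]) - set(lookup.index)
        if missing:
            raise KeyError(f"patients with no cohort summary: {sorted(missing)[:5]}")
        strata = (
            patients["cohort_id"].map(lookup).rename("stratum")
        )
    tab = (
        pd.crosstab(strata, patients["outcome"].to_numpy())
        .reindex(columns=[0, 1], fill_value=0)
        .rename(columns={0: "N0", 1: "N1"})
        .sort_index()
    )
    tab.index.name = "stratum"
    return PhaseOneTable(design=design, counts=tab, patient_strata=strata)


@dataclass
class Allocation:
    """Phase-II sample-size targets n_ys per (outcome, stratum) cell.

    ``base_target`` is the equal per-cell target ``floor(n / #cells)`` before
    cell exhaustion and redistribution.
    """

    table: pd.DataFrame  # columns: outcome, stratum, N, n
    n: int
    base_target: int | None = None

    def __post_init__(self):
        t = self.table
        if (t["n"] < 0).any() or (t["n"] > t["N"]).any():
            raise AllocationError("allocation must satisfy 0 <= n_ys <= N_ys")
        if int(t["n"].sum()) != self.n:
            raise AllocationError("allocated cells must sum to n")

    def cell(self, outcome: int, stratum: str) -> int:
        t = self.table
        row = t[(t["outcome"] == outcome) & (t["stratum"] == stratum)]
        return int(row["n"].iloc[0]) if len(row) else 0


def allocate_balanced(phase1: PhaseOneTable, n: int) -> Allocation:
    """Balanced allocation of ``n`` phase-II slots across the phase-I cells.

    Base target ``floor(n / #cells)`` per cell with the remainder going one
    apiece to the largest cells (ties broken by lexicographic stratum key);
    cells smaller than their target are exhausted and the shortfall is
    redistributed equally among unexhausted cells of the same outcome level,
    iterating until absorbed.  Any residue that the outcome level cannot
    absorb crosses outcome levels (with a warning).
    """
    cells = [
        {"outcome": y, "stratum": s, "N": phase1.cell(y, s)}
        for y in (0, 1)
        for s in phase1.strata
    ]
    total = sum(c["N"] for c in cells)
    if n > total:
        raise AllocationError(f"n = {n} exceeds the population size {total}")
    if n < 0:
        raise AllocationError("n must be non-negative")
    if total == 0:
        raise AllocationError("phase-I table is empty")

    k = len(cells)
    base, rem = divmod(n, k)
    order = sorted(range(k), key=lambda i: (-cells[i]["N"], str(cells[i]["stratum"]), cells[i]["outcome"]))
    target = [base] * k
    for i in order[:rem]:
        target[i] += 1

    alloc = [min(t, c["N"]) for t, c in zip(target, cells)]
    pool = {y: 0 for y in (0, 1)}
    for i, c in enumerate(cells):
        pool[c["outcome"]] += target[i] - alloc[i]

    def redistribute(pool_amount: int, eligible: list[int]) -> int:
        """Spread pool equally over eligible (unsaturated) cells; return residue."""
        while pool_amount > 0:
            open_cells = [i for i in eligible if alloc[i] < cells[i]["N"]]
            if not open_cells:
                return pool_amount
            share, extra = divmod(pool_amount, len(open_cells))
            open_sorted = sorted(
                open_cells,
                key=lambda i: (-cells[i]["N"], str(cells[i]["stratum"]), cells[i]["outcome"]),
            )
            pool_amount = 0
            for rank, i in enumerate(open_sorted):
                want = share + (1 if rank < extra else 0)
                room = cells[i]["N"] - alloc[i]
                take = min(want, room)
                alloc[i] += take
                pool_amount += want - take
        return 0

    for y in (0, 1):
        pool[y] = redistribute(pool[y], [i for i, c in enumerate(cells) if c["outcome"] == y])
    residue = pool[0] + pool[1]
    if residue > 0:
        warnings.warn(
            f"{residue} phase-II slots crossed outcome levels: a whole outcome "
            "level was exhausted",
            RuntimeWarning,
        )
        residue = redistribute(residue, list(range(k)))
    assert residue == 0 and sum(alloc) == n

    table = pd.DataFrame(cells)
    table["n"] = alloc
    return Allocation(table=table, n=n, base_target=base)


@dataclass
class TwoPhaseSample:
    """Phase-II patient records together with the phase-I table and allocation.

    ``data`` carries the sampled patient rows plus ``stratum`` and ``weight``
    columns, where the design weight is ``N_ys / n_ys`` for the patient's
    (outcome, stratum) cell.
    """

    data: pd.DataFrame
    phase1: PhaseOneTable
    allocation: Allocation

    def __post_init__(self):
        if self.data["patient_id"].duplicated().any():
            raise ValueError("phase-II sample drawn with replacement (duplicate ids)")

    @property
    def n(self) -> int:
        return len(self.data)

    def cell_counts(self) -> pd.DataFrame:
        return (
            self.data.groupby(["outcome", "stratum"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )


def draw_phase2(
    patients: pd.DataFrame,
    phase1: PhaseOneTable,
    allocation: Allocation,
    seed: int,
) -> TwoPhaseSample:
    """Simple random sampling without replacement within each phase-I cell."""
    if phase1.patient_strata is None:
        raise ValueError("phase-I table was not built from a patient table")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 97)))
    strata = phase1.patient_strata.to_numpy()
    outcome = patients["outcome"].to_numpy()
    pieces = []
    for _, row in allocation.table.sort_values(["outcome", "stratum"]).iterrows():
        want = int(row["n"])
        if want == 0:
            continue
        mask = (outcome == row["outcome"]) & (strata == row["stratum"])
        idx = np.flatnonzero(mask)
        if want > len(idx):
            raise AllocationError(
                f"cell ({row['outcome']}, {row['stratum']}) has {len(idx)} patients "
                f"but allocation {want}"
            )
        chosen = np.sort(rng.choice(idx, size=want, replace=False))
        piece = patients.iloc[chosen].copy()
        piece["stratum"] = row["stratum"]
        piece["weight"] = row["N"] / want
        pieces.append(piece)
    data = pd.concat(pieces, ignore_index=True).sort_values("patient_id")
    data = data.reset_index(drop=True)
    return TwoPhaseSample(data=data, phase1=phase1, allocation=allocation)


def draw_case_control(
    patients: pd.DataFrame,
    n: int,
    case_fraction: float = 0.5,
    seed: int = 0,
) -> TwoPhaseSample:
    """Case-control draw: the single-stratum two-phase special case."""
    phase1 = build_phase1(patients, "case_control")
    n_cases = int(round(n * case_fraction))
    n_controls = n - n_cases
    if n_cases > phase1.n_cases:
        raise AllocationError(
            f"requested {n_cases} cases but only {phase1.n_cases} exist"
        )
    if n_controls > phase1.n_controls:
        raise AllocationError(
            f"requested {n_controls} controls but only {phase1.n_controls} exist"
        )
    table = pd.DataFrame(
        {
            "outcome": [0, 1],
            "stratum": ["all", "all"],
            "N": [phase1.n_controls, phase1.n_cases],
            "n": [n_controls, n_cases],
        }
    )
    return draw_phase2(patients, phase1, Allocation(table=table, n=n), seed)
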