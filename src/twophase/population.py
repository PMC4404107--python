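"""Synthetic registrant populations with the structure of the Malawi survey.

The generator produces a patient-level table whose (registration year, clinic
type) cell counts are *exact* (not in expectation), whose patients partition
into quarterly-clinic cohorts, and whose covariates follow the survey's
published marginals.  Cohort-level covariate composition varies between
cohorts (cohort-specific Bernoulli probabilities drawn from Beta
distributions), which is what populates the covariate-based phase-I
stratification schemes.  Outcomes are Bernoulli draws from a logistic model
whose slopes default to the survey's gold-standard adjusted odds ratios and
whose intercept is calibrated to the overall 19.5% negative rate.

All randomness flows from ``PopulationConfig.seed`` through named
deterministic sub-streams, so identical configurations yield byte-identical
tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special

from .config import AGE_BANDS, CLINIC_TYPES, PopulationConfig, TrueModel
from .logistic import age_transform

#: Column order of the patient table (the package's patient CSV schema).
PATIENT_COLUMNS = [
    "patient_id",
    "clinic_id",
    "clinic_type",
    "region",
    "year",
    "quarter",
    "cohort_id",
    "age",
    "female",
    "who34",
    "outcome",
]

_STREAMS = {"clinics": 0, "cohorts": 1, "covariates": 2, "calibrate": 3, "outcomes": 4}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    """Named deterministic sub-stream of the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), _STREAMS[stream], int(extra)))
    )


def _beta_probs(rng, mean: float, kappa: float, size: int) -> np.ndarray:
    """Cohort-specific probabilities ~ Beta with given mean and concentration."""
    if not np.isfinite(kappa):
        return np.full(size, mean)
    return rng.beta(mean * kappa, (1.0 - mean) * kappa, size=size)


def _clinic_table(config: PopulationConfig, rng) -> pd.DataFrame:
    """One row per clinic: id, type, region, and opening quarter.

    Clinics open at a staggered global quarter (uniform over the first
    three-quarters of the observation window), emulating program scale-up;
    this is what keeps the number of nonempty quarterly-clinic cohorts near
    the survey's N* = 1,518 rather than at the 2,268 ceiling.
    """
    n_quarters = len(config.years) * config.quarters_per_year
    rows = []
    for ctype, n_clinics in (
        ("public", config.n_clinics_public),
        ("private", config.n_clinics_private),
    ):
        for k in range(n_clinics):
            rows.append((f"{ctype[:4]}{k + 1:03d}", ctype))
    clinics = pd.DataFrame(rows, columns=["clinic_id", "clinic_type"])
    p_south = config.covariate_marginals.p_south
    clinics["region"] = np.where(
        rng.random(len(clinics)) < p_south, "South", "Central/North"
    )
    max_open = max(1, n_quarters - config.quarters_per_year + 1)
    clinics["opening_quarter"] = rng.integers(1, max_open + 1, size=len(clinics))
    # the program predates the observation window: at least one clinic of
    # each type is active from the first quarter
    for ctype in ("public", "private"):
        idx = clinics.index[clinics["clinic_type"] == ctype]
        if len(idx):
            clinics.loc[idx[0], "opening_quarter"] = 1
    return clinics


def generate_covariates(config: PopulationConfig) -> pd.DataFrame:
    """Generate the patient table with covariates set and outcome unset (-1).

    Every (year, clinic type) stratum receives exactly its configured number
    of patients, split multinomially across the stratum's active
    clinic-quarter cells; each nonempty cell is a quarterly-clinic cohort.
    """
    config.validate()
    clinics = _clinic_table(config, _rng(config.seed, "clinics"))
    qpy = config.quarters_per_year
    years = config.years

    cohort_rng = _rng(config.seed, "cohorts")
    frames = []
    for (year, ctype), n_cell in sorted(config.stratum_sizes.items(), key=str):
        if n_cell == 0:
            continue
        sub = clinics[clinics["clinic_type"] == ctype]
        year_idx = years.index(year)
        # active (clinic, quarter) cells: the clinic has opened by that quarter
        cells = []
        for _, cl in sub.iterrows():
            for q in range(1, qpy + 1):
                global_q = year_idx * qpy + q
                if global_q >= cl["opening_quarter"]:
                    cells.append((cl["clinic_id"], cl["region"], q))
        if not cells:
            raise ValueError(f"no active clinics for stratum ({year}, {ctype})")
        counts = cohort_rng.multinomial(n_cell, np.full(len(cells), 1.0 / len(cells)))
        keep = counts > 0
        cell_ids = np.array([c[0] for c in cells])[keep]
        cell_regions = np.array([c[1] for c in cells])[keep]
        cell_quarters = np.array([c[2] for c in cells], dtype=np.int64)[keep]
        counts = counts[keep]
        frames.append(
            pd.DataFrame(
                {
                    "clinic_id": np.repeat(cell_ids, counts),
                    "clinic_type": ctype,
                    "region": np.repeat(cell_regions, counts),
                    "year": np.int64(year),
                    "quarter": np.repeat(cell_quarters, counts),
                    "_cohort_ord": np.repeat(np.arange(len(counts)), counts),
                    "_cohort_size_key": 0,
                }
            )
        )

    patients = pd.concat(frames, ignore_index=True)
    patients["cohort_id"] = (
        patients["clinic_id"]
        + "-"
        + patients["year"].astype(str)
        + "q"
        + patients["quarter"].astype(str)
    )

    # cohort-specific covariate composition
    cov_rng = _rng(config.seed, "covariates")
    cohort_codes, cohort_index = pd.factorize(patients["cohort_id"], sort=True)
    n_cohorts = len(cohort_index)
    het = config.cohort_heterogeneity
    marg = config.covariate_marginals
    p_female = _beta_probs(cov_rng, marg.p_female, het.get("female", np.inf), n_cohorts)
    p_who34 = _beta_probs(cov_rng, marg.p_who34, het.get("who34", np.inf), n_cohorts)

    n = len(patients)
    patients["female"] = (cov_rng.random(n) < p_female[cohort_codes]).astype(np.int8)
    patients["who34"] = (cov_rng.random(n) < p_who34[cohort_codes]).astype(np.int8)

    band_idx = cov_rng.choice(len(AGE_BANDS), size=n, p=marg.age_band_probs)
    lo = np.array([b[0] for b in AGE_BANDS])[band_idx]
    hi = np.array([b[1] for b in AGE_BANDS])[band_idx]
    patients["age"] = lo + np.floor(cov_rng.random(n) * (hi - lo + 1)).astype(np.int64)

    patients["outcome"] = np.int8(-1)  # unset
    patients = patients.drop(columns=["_cohort_ord", "_cohort_size_key"])
    patients.insert(0, "patient_id", np.arange(n, dtype=np.int64))
    return patients[PATIENT_COLUMNS]


def linear_predictor(
    patients: pd.DataFrame, model: TrueModel, *, include_intercept: bool = True
) -> np.ndarray:
    """Linear predictor of the outcome model for each patient."""
    for col in ("age", "female", "who34", "region", "year", "clinic_type"):
        if col not in patients.columns:
            raise KeyError(f"missing covariate column {col!r}")
    x = age_transform(patients["age"].to_numpy())
    private = (patients["clinic_type"].to_numpy() == "private").astype(float)
    year = patients["year"].to_numpy()
    eta = (
        model.beta_age_linear * x
        + model.beta_age_quadratic * x**2
        + model.beta_female * patients["female"].to_numpy()
        + model.beta_who34 * patients["who34"].to_numpy()
        + model.beta_south * (patients["region"].to_numpy() == "South")
        + model.beta_2006 * (year == 2006)
        + model.beta_2007 * (year == 2007)
        + model.beta_private * private
        + model.beta_private_2006 * (private * (year == 2006))
        + model.beta_private_2007 * (private * (year == 2007))
    )
    if include_intercept:
        if model.intercept is None:
            raise ValueError("model intercept is not set")
        eta = eta + model.intercept
    return eta


def calibrate_intercept(
    config: PopulationConfig,
    target_rate: float | None = None,
    tol: float = 1e-3,
    *,
    patients: pd.DataFrame | None = None,
) -> float:
    """Intercept at which the population-average outcome probability hits
    ``target_rate``.

    Solves ``mean(expit(eta + a)) = target_rate`` by monotone root-finding
    over the covariate population generated from ``config`` (deterministic
    given the config seed).  ``patients`` may be supplied to reuse an already
    generated covariate table.
    """
    target = config.target_outcome_rate if target_rate is None else target_rate
    if not 0.0 < target < 1.0:
        raise ValueError("target_rate must be in (0, 1)")
    if patients is None:
        patients = generate_covariates(config)
    eta0 = linear_predictor(patients, config.coefficients, include_intercept=False)

    def gap(a: float) -> float:
        return float(np.mean(special.expit(eta0 + a))) - target

    try:
        intercept = optimize.brentq(gap, -20.0, 20.0, xtol=1e-10, maxiter=100)
    except (ValueError, RuntimeError) as err:
        raise RuntimeError(f"intercept calibration failed: {err}") from err
    if abs(gap(intercept)) > tol:
        raise RuntimeError("intercept calibration did not reach the target rate")
    return float(intercept)


def assign_outcomes(
    patients: pd.DataFrame, model: TrueModel, seed: int, *, replicate: int = 0
) -> pd.DataFrame:
    """Draw Bernoulli six-month outcomes from the logistic model.

    Returns a copy with ``outcome`` set; requires the column to be unset
    (-1).  ``replicate`` selects an independent outcome sub-stream so power
    simulations can redraw outcomes over a fixed covariate population.
    """
    if np.any(patients["outcome"].to_numpy() != -1):
        raise ValueError("outcomes are already assigned")
    p = special.expit(linear_predictor(patients, model))
    rng = _rng(seed, "outcomes", extra=replicate)
    out = patients.copy()
    out["outcome"] = (rng.random(len(out)) < p).astype(np.int8)
    return out


def simulate_population(
    config: PopulationConfig, *, replicate: int = 0
) -> tuple[pd.DataFrame, TrueModel]:
    """Covariates + calibrated intercept + outcomes, in one call.

    Returns the complete patient table and the fully specified model
    (intercept filled in) that generated its outcomes.
    """
    patients = generate_covariates(config)
    model = config.coefficients
    if model.intercept is None:
        model = model.replace(
            intercept=calibrate_intercept(config, patients=patients)
        )
    return assign_outcomes(patients, model, config.seed, replicate=replicate), model
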