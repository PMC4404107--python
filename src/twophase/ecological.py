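"""Group-level (ecological) binomial regression on cohort aggregates.

Fits a binomial-logit model to the cohort table with the negative-outcome
count of each quarterly-clinic cohort as the outcome, adjusting through the
group-level analogues of the patient covariates: mean age (same centered
decade transform, linear + quadratic), percent female (entered per 20
percentage points), an indicator of the cohort being >90% WHO stage 3/4,
region, year, clinic type, and clinic-by-year interactions.

Estimation is quasi-likelihood: point estimates are the ordinary binomial
MLE; the covariance is inflated by the Pearson dispersion
``phi = X^2 / (N* - p)`` to accommodate the overdispersion that aggregation
induces.  Comparing these fits with the patient-level model is what exposes
ecological bias (attenuated sex/WHO effects, loss of the quadratic age term).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .logistic import LogitResults, age_transform, irls_logit

#: Default term specification for the cohort-level model.
ECO_TERMS = (
    "intercept",
    "age_lin",
    "age_quad",
    "female_20pct",
    "who34_gt90",
    "south",
    "year_2006",
    "year_2007",
    "private",
    "private_2006",
    "private_2007",
)


def build_cohort_design(cohorts: pd.DataFrame, terms=ECO_TERMS) -> np.ndarray:
    """Design matrix of group-level covariates, one row per cohort."""
    n = len(cohorts)
    x_age = age_transform(cohorts["mean_age"].to_numpy())
    private = (cohorts["clinic_type"].to_numpy() == "private").astype(float)
    year = cohorts["year"].to_numpy()
    cols = {
        "intercept": np.ones(n),
        "age_lin": x_age,
        "age_quad": x_age**2,
        # per 20-percentage-point contrast in percent female
        "female_20pct": cohorts["pct_female"].to_numpy() / 0.20,
        "who34_gt90": (cohorts["pct_who34"].to_numpy() > 0.90).astype(float),
        "south": (cohorts["region"].to_numpy() == "South").astype(float),
        "year_2006": (year == 2006).astype(float),
        "year_2007": (year == 2007).astype(float),
        "private": private,
        "private_2006": private * (year == 2006),
        "private_2007": private * (year == 2007),
    }
    return np.column_stack([cols[t] for t in terms])


class EcoResults(LogitResults):
    """Quasi-binomial fit: a LogitResults plus the Pearson dispersion."""

    def __init__(self, *args, dispersion=1.0, model_cov=None, **kwargs):
        super().__init__(*args, **kwargs)
        self.dispersion = float(dispersion)
        #: unscaled (model-based) covariance, before the phi inflation
        self.model_cov = model_cov


class CohortBinomialLogit:
    """Binomial-logit model for cohort aggregates with quasi-likelihood inference."""

    def __init__(self, cohorts: pd.DataFrame, terms=ECO_TERMS):
        if (cohorts["n_total"] < 1).any():
            raise ValueError("every cohort must have n_total >= 1")
        if (cohorts["n_negative"] > cohorts["n_total"]).any() or (
            cohorts["n_negative"] < 0
        ).any():
            raise ValueError("n_negative must lie in [0, n_total]")
        self.cohorts = cohorts
        self.terms = list(terms)
        self.exog = build_cohort_design(cohorts, terms)
        self.trials = cohorts["n_total"].to_numpy(dtype=float)
        self.endog = cohorts["n_negative"].to_numpy(dtype=float) / self.trials
        if len(cohorts) <= len(self.terms):
            raise ValueError("fewer cohorts than model parameters")
        total_neg = cohorts["n_negative"].sum()
        if total_neg == 0 or total_neg == cohorts["n_total"].sum():
            raise ValueError("degenerate outcome: all cohorts all-0 or all-n")

    def fit(self) -> EcoResults:
        fit = irls_logit(
            self.exog, self.endog, trials=self.trials, term_names=self.terms
        )
        mu = 1.0 / (1.0 + np.exp(-(self.exog @ fit.beta)))
        pearson = np.sum(
            (self.trials * (self.endog - mu)) ** 2 / (self.trials * mu * (1.0 - mu))
        )
        dof = len(self.endog) - len(self.terms)
        phi = float(pearson / dof)
        model_cov = np.linalg.inv(fit.info)
        model_cov = (model_cov + model_cov.T) / 2.0
        return EcoResults(
            pd.Series(fit.beta, index=self.terms),
            phi * model_cov,
            method="quasi",
            nobs=len(self.endog),
            converged=fit.converged,
            llf=fit.llf,
            n_iter=fit.n_iter,
            dispersion=phi,
            model_cov=pd.DataFrame(model_cov, index=self.terms, columns=self.terms),
        )


def fit_ecological(cohorts: pd.DataFrame, terms=ECO_TERMS) -> EcoResults:
    """Fit the quasi-binomial group-level model to a cohort table."""
    return CohortBinomialLogit(cohorts, terms).fit()
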