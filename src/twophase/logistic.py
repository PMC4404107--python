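"""Patient-level binary logistic regression: the gold-standard analysis engine.

Implements maximum-likelihood logistic regression by iteratively reweighted
least squares (IRLS) with step-halving, plus the inference utilities every
other fitter in the package reuses: Wald tests on coefficient subsets,
odds-ratio/confidence-interval tables, and delta-method combinations of main
effects with interactions.

The engine supports Bernoulli data, grouped binomial data (``trials``), case
weights, and a fixed offset, which is exactly the generality the ecological
and two-phase fitters need.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

#: Default term specification of the patient-level model: quadratic age trend
#: centered at 45 years, sex, WHO stage 3/4, region, registration-year
#: indicators (2005 reference), clinic type (public reference), and
#: clinic-by-year interactions.
PATIENT_TERMS = (
    "intercept",
    "age_lin",
    "age_quad",
    "female",
    "who34",
    "south",
    "year_2006",
    "year_2007",
    "private",
    "private_2006",
    "private_2007",
)

#: The clinic-by-year interaction terms tested in the power study.
INTERACTION_TERMS = ("private_2006", "private_2007")


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximizer (or outcome is constant)."""


class RankDeficientError(RuntimeError):
    """Raised when the design matrix is rank deficient; names the offending terms."""

    def __init__(self, collinear: list[str]):
        self.collinear = collinear
        super().__init__(f"design matrix is rank deficient; collinear terms: {collinear}")


def age_transform(age) -> np.ndarray:
    """Centered, rescaled age: ``(age - 45) / 10`` (referent 45 years)."""
    return (np.asarray(age, dtype=float) - 45.0) / 10.0


def build_design(frame: pd.DataFrame, terms=PATIENT_TERMS) -> np.ndarray:
    """Design matrix for patient records, columns in ``terms`` order."""
    n = len(frame)
    cols = {}
    if {"age_lin", "age_quad"} & set(terms):
        x_age = age_transform(frame["age"].to_numpy())
    if "private" in terms or "private_2006" in terms or "private_2007" in terms:
        private = (frame["clinic_type"].to_numpy() == "private").astype(float)
    for t in terms:
        if t == "intercept":
            cols[t] = np.ones(n)
        elif t == "age_lin":
            cols[t] = x_age
        elif t == "age_quad":
            cols[t] = x_age**2
        elif t in ("female", "who34"):
            cols[t] = frame[t].to_numpy(dtype=float)
        elif t == "south":
            cols[t] = (frame["region"].to_numpy() == "South").astype(float)
        elif t.startswith("year_"):
            cols[t] = (frame["year"].to_numpy() == int(t[5:])).astype(float)
        elif t == "private":
            cols[t] = private
        elif t.startswith("private_"):
            year = int(t.split("_")[1])
            cols[t] = private * (frame["year"].to_numpy() == year)
        else:
            raise KeyError(f"unknown term {t!r}")
    return np.column_stack([cols[t] for t in terms])


# ---------------------------------------------------------------------------
# IRLS engine
# ---------------------------------------------------------------------------

_MU_EPS = 1e-12


@dataclass
class _IRLSFit:
    beta: np.ndarray
    info: np.ndarray  # observed information X' W X at the solution
    llf: float
    converged: bool
    n_iter: int


def _loglik(y, mu, m, w):
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    return float(np.sum(w * m * (y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu))))


def _check_rank(X: np.ndarray, names) -> None:
    gram = X.T @ X
    eigs = np.linalg.eigvalsh(gram)
    if eigs[0] > eigs[-1] * 1e-10:
        return
    # identify the collinear columns via pivoted QR
    _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
    rank = int(np.sum(eigs > eigs[-1] * 1e-10))
    collinear = [names[j] for j in sorted(piv[rank:])]
    raise RankDeficientError(collinear)


def irls_logit(
    X: np.ndarray,
    y: np.ndarray,
    *,
    trials: np.ndarray | None = None,
    freq_weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    start: np.ndarray | None = None,
    term_names=None,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    max_iter: int = 100,
    check_rank: bool = True,
) -> _IRLSFit:
    """Maximize the (possibly weighted, grouped, offset) Bernoulli likelihood.

    Convergence is declared when the maximum absolute score falls below
    ``score_tol`` or the relative log-likelihood change falls below
    ``ll_tol``.  The likelihood never decreases across iterations: a full
    Newton step that would decrease it is halved (up to 30 times).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    m = np.ones(n) if trials is None else np.asarray(trials, dtype=float)
    w = np.ones(n) if freq_weights is None else np.asarray(freq_weights, dtype=float)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    names = list(term_names) if term_names is not None else [f"x{j}" for j in range(p)]

    if trials is None and (np.all(y == y[0])):
        raise SeparationError("degenerate outcome: all responses identical")
    if check_rank:
        _check_rank(X * np.sqrt(w * m)[:, None], names)

    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    eta = X @ beta + off
    mu = special.expit(eta)
    ll = _loglik(y, mu, m, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = w * m * (y - mu)
        score = X.T @ resid
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        W = w * m * np.clip(mu * (1.0 - mu), _MU_EPS, None)
        info = X.T @ (X * W[:, None])
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:  # pragma: no cover - guarded by rank check
            raise SeparationError(f"singular information matrix: {err}") from err
        step = 1.0
        for _ in range(30):
            beta_new = beta + step * delta
            mu_new = special.expit(X @ beta_new + off)
            ll_new = _loglik(y, mu_new, m, w)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            raise SeparationError("step-halving failed to increase the likelihood")
        beta, mu = beta_new, mu_new
        if abs(ll_new - ll) <= ll_tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        if np.max(np.abs(beta)) > 15.0:
            raise SeparationError(
                "no convergence and diverging coefficients: data are likely "
                "perfectly separated"
            )
        warnings.warn("IRLS did not converge within the iteration cap", RuntimeWarning)
    if trials is None and bool(np.all(np.abs(y - mu) < 1e-4)):
        raise SeparationError(
            "perfect separation: the model predicts every outcome exactly"
        )
    W = w * m * np.clip(mu * (1.0 - mu), _MU_EPS, None)
    info = X.T @ (X * W[:, None])
    return _IRLSFit(beta=beta, info=info, llf=_loglik(y, mu, m, w), converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class WaldResult:
    """Wald chi-square test of a coefficient subset being jointly zero."""

    statistic: float
    df: int
    p_value: float

    def __str__(self):
        return f"Wald chi2({self.df}) = {self.statistic:.3f}, p = {self.p_value:.4g}"


class LogitResults:
    """Estimates, covariance, and inference summaries for a fitted logit model.

    Parameters
    ----------
    params : pd.Series
        Coefficient estimates on the log-odds scale, indexed by term name.
    cov : pd.DataFrame
        Estimated covariance of the coefficients.
    method : str
        One of ``ml``, ``quasi``, ``weighted``, ``pseudo``, ``twophase_ml``.
    """

    def __init__(self, params, cov, *, method="ml", nobs=0, converged=True,
                 llf=np.nan, n_iter=0):
        self.params = pd.Series(params)
        self.cov_params = pd.DataFrame(cov, index=self.params.index,
                                       columns=self.params.index)
        self.method = method
        self.nobs = int(nobs)
        self.converged = bool(converged)
        self.llf = float(llf)
        self.n_iter = int(n_iter)
        self._validate()

    def _validate(self):
        c = self.cov_params.to_numpy()
        if not np.allclose(c, c.T, atol=1e-8):
            raise ValueError("covariance matrix must be symmetric")
        eigs = np.linalg.eigvalsh((c + c.T) / 2.0)
        if eigs[0] < -1e-8 * max(1.0, eigs[-1]):
            raise ValueError("covariance matrix must be positive semi-definite")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)

    def wald_test(self, terms) -> WaldResult:
        """Wald test that the named coefficients are jointly zero."""
        terms = [terms] if isinstance(terms, str) else list(terms)
        if not terms:
            raise ValueError("term subset must be non-empty")
        missing = [t for t in terms if t not in self.params.index]
        if missing:
            raise KeyError(f"terms not in fit: {missing}")
        b = self.params[terms].to_numpy()
        V = self.cov_params.loc[terms, terms].to_numpy()
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular covariance block for {terms}"
            ) from err
        stat = max(stat, 0.0)
        df = len(terms)
        return WaldResult(stat, df, float(stats.chi2.sf(stat, df)))

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        """Odds ratios with Wald confidence intervals at ``level``."""
        if not 0.0 < level < 1.0:
            raise ValueError("level must be in (0, 1)")
        z = stats.norm.ppf(0.5 + level / 2.0)
        b, se = self.params.to_numpy(), self.bse.to_numpy()
        return pd.DataFrame(
            {
                "OR": np.exp(b),
                "CI_low": np.exp(b - z * se),
                "CI_high": np.exp(b + z * se),
            },
            index=self.params.index,
        )

    def combined_or(self, main_term: str, interaction_term: str,
                    level: float = 0.95) -> tuple[float, float, float]:
        """OR for ``main + interaction`` with a delta-method CI.

        For an interaction model this is the subgroup-specific odds ratio,
        e.g. the private-vs-public OR in a later year.
        """
        for t in (main_term, interaction_term):
            if t not in self.params.index:
                raise KeyError(f"term {t!r} not in fit")
        b = self.params[main_term] + self.params[interaction_term]
        var = (
            self.cov_params.loc[main_term, main_term]
            + self.cov_params.loc[interaction_term, interaction_term]
            + 2.0 * self.cov_params.loc[main_term, interaction_term]
        )
        if not np.isfinite(var):
            raise ValueError("missing covariance entry for the delta method")
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = np.sqrt(max(var, 0.0))
        return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se))

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {
                "low": self.params - z * self.bse,
                "high": self.params + z * self.bse,
            }
        )

    def summary(self) -> str:
        """Human-readable coefficient table."""
        tab = self.or_table()
        lines = [
            f"Binary logistic fit  [method={self.method}, n={self.nobs}, "
            f"converged={self.converged}]",
            f"{'term':<16}{'coef':>10}{'SE':>10}{'OR':>8}{'95% CI':>20}",
        ]
        for t in self.params.index:
            lines.append(
                f"{t:<16}{self.params[t]:>10.4f}{self.bse[t]:>10.4f}"
                f"{tab.loc[t, 'OR']:>8.3f}"
                f"{'(' + format(tab.loc[t, 'CI_low'], '.3f') + ', ' + format(tab.loc[t, 'CI_high'], '.3f') + ')':>20}"
            )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "params": self.params.tolist(),
            "cov": self.cov_params.to_numpy().tolist(),
            "method": self.method,
            "nobs": self.nobs,
            "converged": self.converged,
            "llf": None if np.isnan(self.llf) else self.llf,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "LogitResults":
        return cls(
            pd.Series(d["params"], index=d["terms"]),
            np.asarray(d["cov"]),
            method=d["method"],
            nobs=d["nobs"],
            converged=d["converged"],
            llf=np.nan if d.get("llf") is None else d["llf"],
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LogitResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class PatientLogit:
    """Maximum-likelihood logistic regression for patient-level records.

    Examples
    --------
    >>> res = PatientLogit.from_frame(patients).fit()
    >>> res.or_table().loc["private"]
    >>> res.wald_test(["private_2006", "private_2007"])
    """

    def __init__(self, endog, exog, term_names=None, *, freq_weights=None,
                 offset=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.term_names = (
            list(term_names)
            if term_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        self.freq_weights = freq_weights
        self.offset = offset

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, terms=PATIENT_TERMS) -> "PatientLogit":
        """Build from a patient table with the documented column schema."""
        outcome = frame["outcome"].to_numpy()
        if np.any((outcome != 0) & (outcome != 1)):
            raise ValueError("outcome must be binary 0/1 (is it unset?)")
        return cls(outcome, build_design(frame, terms), term_names=list(terms))

    def fit(self, *, start=None, check_rank=True) -> LogitResults:
        fit = irls_logit(
            self.exog,
            self.endog,
            freq_weights=self.freq_weights,
            offset=self.offset,
            start=start,
            term_names=self.term_names,
            check_rank=check_rank,
        )
        cov = np.linalg.inv(fit.info)
        cov = (cov + cov.T) / 2.0
        return LogitResults(
            pd.Series(fit.beta, index=self.term_names),
            cov,
            method="ml",
            nobs=len(self.endog),
            converged=fit.converged,
            llf=fit.llf,
            n_iter=fit.n_iter,
        )


def fit_logistic(frame: pd.DataFrame, terms=PATIENT_TERMS) -> LogitResults:
    """Fit the patient-level logistic model to a patient table."""
    return PatientLogit.from_frame(frame, terms).fit()
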