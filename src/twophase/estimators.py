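"""Logistic-model estimation from two-phase samples.

Three estimators of the patient-level logistic regression parameters from a
:class:`~twophase.design.TwoPhaseSample`:

``weighted``
    Design-weighted (Horvitz-Thompson) likelihood: each sampled patient is
    weighted by the inverse of its cell's sampling fraction, ``N_ys / n_ys``.
    Covariance is the model information plus a design-based sandwich term
    with per-cell finite-population correction.

``pseudo``
    Offset logistic regression with the fixed per-stratum offset
    ``log[(n_1s / N_1s) / (n_0s / N_0s)]`` added to the linear predictor.
    Covariance is the information-based sandwich adjusted for the
    between-stratum variability of the estimated sampling fractions.

``ml``
    Full two-phase maximum likelihood (phase-I stratum-outcome counts times
    the phase-II conditional likelihood), computed through the profile/offset
    formulation: profiling the nonparametric within-stratum covariate
    distributions reduces the score to an offset-logistic score whose
    per-stratum offsets ``delta_s = log((N_s - u_s) / (N_s - v_s))`` with
    ``u_s = (N_1s - n_1s)/P_1s`` and ``v_s = (N_0s - n_0s)/P_0s`` depend on
    the stratum case probability ``P_1s``, itself pinned down by the NPMLE
    normalization ``sum_i g_si = 1``.  Covariance is the inverse observed
    profile information (finite-difference curvature of the profile score).

All three coincide with ordinary maximum likelihood when the "sample" is a
census.  For efficiency on stratifying variables, ML <= pseudo <= weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .design import TwoPhaseSample
from .logistic import PATIENT_TERMS, LogitResults, build_design, irls_logit


class InestimableDesignError(RuntimeError):
    """A phase-I cell with members received no phase-II sample (or similar)."""


@dataclass
class _Stratum:
    label: str
    rows: np.ndarray  # sample row indices in this stratum
    n1: int
    n0: int
    N1: int
    N0: int

    @property
    def N(self) -> int:
        return self.N0 + self.N1

    @property
    def c1(self) -> int:
        return self.N1 - self.n1

    @property
    def c0(self) -> int:
        return self.N0 - self.n0


class TwoPhaseResults(LogitResults):
    """LogitResults plus the per-cell sample/population counts of the design."""

    def __init__(self, *args, design_cells=None, **kwargs):
        super().__init__(*args, **kwargs)
        self.design_cells = design_cells


class TwoPhaseLogit:
    """Two-phase logistic regression model bound to a drawn sample.

    Examples
    --------
    >>> sample = draw_phase2(patients, phase1, allocation, seed=1)
    >>> res = TwoPhaseLogit(sample).fit(method="ml")
    >>> res.wald_test(["private_2006", "private_2007"])
    """

    def __init__(self, sample: TwoPhaseSample, terms=PATIENT_TERMS):
        self.sample = sample
        self.terms = list(terms)
        df = sample.data
        self.X = build_design(df, self.terms)
        self.y = df["outcome"].to_numpy(dtype=float)
        self.stratum_labels = df["stratum"].to_numpy()

        counts = sample.phase1.counts
        realized = df.groupby(["stratum", "outcome"]).size()
        self.strata: list[_Stratum] = []
        bad_cells = []
        for label in sample.phase1.strata:
            N0, N1 = int(counts.loc[label, "N0"]), int(counts.loc[label, "N1"])
            n0 = int(realized.get((label, 0), 0))
            n1 = int(realized.get((label, 1), 0))
            for y, N, n in ((0, N0, n0), (1, N1, n1)):
                if N > 0 and n == 0:
                    bad_cells.append((y, label, N))
            if N0 + N1 == 0:
                continue
            rows = np.flatnonzero(self.stratum_labels == label)
            self.strata.append(_Stratum(label, rows, n1, n0, N1, N0))
        if bad_cells:
            raise InestimableDesignError(
                "phase-I cells with members but no phase-II sample "
                f"(outcome, stratum, N): {bad_cells}"
            )

    # -- public API --------------------------------------------------------

    def fit(self, method: str = "ml") -> TwoPhaseResults:
        if method == "weighted":
            beta, cov, extra = self._fit_weighted()
        elif method == "pseudo":
            beta, cov, extra = self._fit_pseudo()
        elif method == "ml":
            beta, cov, extra = self._fit_ml()
        else:
            raise KeyError(f"unknown method {method!r}")
        tag = {"weighted": "weighted", "pseudo": "pseudo", "ml": "twophase_ml"}[method]
        cells = pd.DataFrame(
            [
                {"stratum": s.label, "n0": s.n0, "n1": s.n1, "N0": s.N0, "N1": s.N1}
                for s in self.strata
            ]
        )
        return TwoPhaseResults(
            pd.Series(beta, index=self.terms),
            (cov + cov.T) / 2.0,
            method=tag,
            nobs=len(self.y),
            converged=extra["converged"],
            llf=extra.get("llf", np.nan),
            n_iter=extra.get("n_iter", 0),
            design_cells=cells,
        )

    # -- helpers -----------------------------------------------------------

    def _cell_index(self):
        """Iterate (stratum, outcome, row indices, N, n) over sampled cells."""
        for s in self.strata:
            for y in (0, 1):
                rows = s.rows[self.y[s.rows] == y]
                N = s.N1 if y == 1 else s.N0
                n = s.n1 if y == 1 else s.n0
                if n > 0:
                    yield s, y, rows, N, n

    def _weights(self) -> np.ndarray:
        w = np.empty(len(self.y))
        for _, _, rows, N, n in self._cell_index():
            w[rows] = N / n
        return w

    # -- weighted likelihood ----------------------------------------------

    def _fit_weighted(self):
        w = self._weights()
        fit = irls_logit(
            self.X, self.y, freq_weights=w, term_names=self.terms, check_rank=True
        )
        mu = special.expit(self.X @ fit.beta)
        bread = np.linalg.inv(fit.info)
        scores = self.X * (self.y - mu)[:, None]
        meat = np.zeros_like(bread)
        for s, y, rows, N, n in self._cell_index():
            if n == 1:
                if N > n:
                    warnings.warn(
                        f"cell ({y}, {s.label}) has a single sampled patient; "
                        "its variance contribution is unestimable and set to 0",
                        RuntimeWarning,
                    )
                continue
            e = scores[rows]
            e = e - e.mean(axis=0)
            meat += (N * (N - n) / n) * (e.T @ e) / (n - 1)
        cov = bread + bread @ meat @ bread
        return fit.beta, cov, {"converged": fit.converged, "llf": fit.llf,
                               "n_iter": fit.n_iter}

    # -- pseudo-likelihood --------------------------------------------------

    def _offsets_fixed(self) -> np.ndarray:
        off = np.zeros(len(self.y))
        for s in self.strata:
            if s.n1 + s.n0 == 0:
                continue
            if (s.N1 > 0 and s.n1 == 0) or (s.N0 > 0 and s.n0 == 0):
                raise InestimableDesignError(
                    f"stratum {s.label!r} has a zero outcome cell "
                    f"(n1={s.n1}, n0={s.n0}, N1={s.N1}, N0={s.N0}); "
                    "its sampling-fraction offset is undefined"
                )
            # a cell with no members is vacuously fully sampled (fraction 1)
            f1 = s.n1 / s.N1 if s.N1 > 0 else 1.0
            f0 = s.n0 / s.N0 if s.N0 > 0 else 1.0
            off[s.rows] = np.log(f1 / f0)
        return off

    def _fit_pseudo(self):
        off = self._offsets_fixed()
        fit = irls_logit(
            self.X, self.y, offset=off, term_names=self.terms, check_rank=True
        )
        mu = special.expit(self.X @ fit.beta + off)
        v = mu * (1.0 - mu)
        bread = np.linalg.inv(fit.info)
        scores = self.X * (self.y - mu)[:, None]
        meat = np.zeros_like(bread)
        # within-cell variability of the estimating function (about cell means:
        # cell means are nonzero individually and cancel across outcome levels)
        for s, y, rows, N, n in self._cell_index():
            if n == 1:
                continue
            e = scores[rows]
            e = e - e.mean(axis=0)
            meat += n * (e.T @ e) / (n - 1)
        # between-stratum variability of the estimated phase-I log-odds
        # entering through the sampling-fraction offsets
        for s in self.strata:
            if s.N1 == 0 or s.N0 == 0:
                continue  # no case-control contrast is estimated in this stratum
            t_s = (self.X[s.rows] * v[s.rows][:, None]).sum(axis=0)
            meat += np.outer(t_s, t_s) * (1.0 / s.N1 + 1.0 / s.N0)
        cov = bread @ meat @ bread
        return fit.beta, cov, {"converged": fit.converged, "llf": fit.llf,
                               "n_iter": fit.n_iter}

    # -- two-phase maximum likelihood ---------------------------------------

    def _solve_stratum(self, s: _Stratum, p: np.ndarray, start: float | None) -> float:
        """Stratum case probability P_1s solving the NPMLE stationarity.

        Given current model probabilities ``p`` for the stratum's sampled
        rows, finds the root of ``h(P1) = sum_i g_si - 1`` with
        ``g_si = 1/(N_s - u*p_i - v*(1-p_i))`` on the feasible interval
        (c1/N_s, 1 - c0/N_s) that is also self-consistent,
        ``sum_i g_si * p_i = P1``.  The normalization alone always admits the
        degenerate solution ``P1 = c1/(c1+c0)`` (constant g = 1/n_s), which
        is not a stationary point of the strictly concave inner problem and
        must be rejected.
        """
        c1, c0, Ns = s.c1, s.c0, s.N
        if c1 == 0 and c0 == 0:
            return s.N1 / s.N if s.N > 0 else 0.5
        ps = p[s.rows]

        def parts(P1: float):
            u = c1 / P1 if c1 else 0.0
            v = c0 / (1.0 - P1) if c0 else 0.0
            denom = Ns - u * ps - v * (1.0 - ps)
            return denom

        def h(P1: float) -> float:
            denom = parts(P1)
            if np.any(denom <= 0.0):
                return np.inf
            return float(np.sum(1.0 / denom)) - 1.0

        def self_consistency_gap(P1: float) -> float:
            g = 1.0 / parts(P1)
            return abs(float(g @ ps) - P1)

        lo = c1 / Ns if c1 else 0.0
        hi = 1.0 - c0 / Ns if c0 else 1.0
        eps = 1e-10 * (hi - lo)

        def roots_on(grid: np.ndarray) -> list[float]:
            u = np.where(grid > 0, c1 / np.clip(grid, 1e-300, None), 0.0) if c1 else np.zeros_like(grid)
            v = np.where(grid < 1, c0 / np.clip(1.0 - grid, 1e-300, None), 0.0) if c0 else np.zeros_like(grid)
            denom = Ns - np.outer(u, ps) - np.outer(v, 1.0 - ps)
            vals = np.where(
                (denom > 0.0).all(axis=1), (1.0 / np.clip(denom, 1e-300, None)).sum(axis=1) - 1.0, np.inf
            )
            out = []
            for a in range(len(grid) - 1):
                if not (np.isfinite(vals[a]) and np.isfinite(vals[a + 1])):
                    continue
                if vals[a] == 0.0:
                    out.append(float(grid[a]))
                elif vals[a] * vals[a + 1] < 0.0:
                    out.append(
                        float(optimize.brentq(h, grid[a], grid[a + 1], xtol=1e-14))
                    )
            return [r for r in out if self_consistency_gap(r) < 1e-6]

        # warm start: scan a small expanding bracket around the cached solution
        if start is not None and lo + eps < start < hi - eps:
            width = 1e-3 * (hi - lo)
            for _ in range(4):
                a = max(lo + eps, start - width)
                b = min(hi - eps, start + width)
                genuine = roots_on(np.linspace(a, b, 9))
                if genuine:
                    return genuine[0]
                width *= 16.0
        genuine = roots_on(np.linspace(lo + eps, hi - eps, 129))
        if genuine:
            if len(genuine) > 1:
                genuine.sort(key=self_consistency_gap)
            return genuine[0]
        # fallback: damped self-consistency iteration
        P1 = start if start is not None and lo < start < hi else (lo + hi) / 2.0
        for _ in range(500):
            u = c1 / P1 if c1 else 0.0
            v = c0 / (1.0 - P1) if c0 else 0.0
            denom = np.clip(Ns - u * ps - v * (1.0 - ps), 1e-12, None)
            g = 1.0 / denom
            P1_new = float(np.clip((g @ ps) / g.sum(), lo + eps, hi - eps))
            if abs(P1_new - P1) < 1e-13:
                break
            P1 = 0.5 * P1 + 0.5 * P1_new
        else:
            raise RuntimeError(
                f"stratum {s.label!r}: nuisance update failed to converge "
                "(boundary case probability)"
            )
        return P1

    def _profile_offsets(self, p: np.ndarray, cache: dict) -> np.ndarray:
        """Per-observation offsets delta_s(beta) at model probabilities p."""
        off = np.zeros(len(self.y))
        for s in self.strata:
            if len(s.rows) == 0:
                continue
            P1 = self._solve_stratum(s, p, cache.get(s.label))
            cache[s.label] = P1
            u = s.c1 / P1 if s.c1 else 0.0
            v = s.c0 / (1.0 - P1) if s.c0 else 0.0
            num, den = s.N - u, s.N - v
            if num <= 0.0 or den <= 0.0:
                raise RuntimeError(
                    f"stratum {s.label!r}: boundary nuisance estimate (P1={P1:.4g})"
                )
            off[s.rows] = np.log(num / den)
        return off

    def _profile_score(self, beta: np.ndarray, cache: dict) -> np.ndarray:
        p = special.expit(self.X @ beta)
        off = self._profile_offsets(p, cache)
        p_star = special.expit(self.X @ beta + off)
        return self.X.T @ (self.y - p_star)

    def _profile_loglik(self, beta: np.ndarray, cache: dict) -> float:
        """Exact profile log-likelihood (nonparametric G_s profiled out)."""
        p = np.clip(special.expit(self.X @ beta), 1e-12, 1.0 - 1e-12)
        self._profile_offsets(p, cache)  # refresh P_1s in the cache
        ll = float(np.sum(self.y * np.log(p) + (1.0 - self.y) * np.log(1.0 - p)))
        for s in self.strata:
            if len(s.rows) == 0:
                continue
            P1 = cache[s.label]
            u = s.c1 / P1 if s.c1 else 0.0
            v = s.c0 / (1.0 - P1) if s.c0 else 0.0
            ps = p[s.rows]
            g = 1.0 / (s.N - u * ps - v * (1.0 - ps))
            ll += float(np.sum(np.log(g)))
            if s.c1:
                ll += s.c1 * np.log(P1)
            if s.c0:
                ll += s.c0 * np.log(1.0 - P1)
        return ll

    def _profile_information(self, beta: np.ndarray, cache: dict) -> np.ndarray:
        """Observed profile information, by central differences of the score."""
        p_dim = len(beta)
        J = np.empty((p_dim, p_dim))
        for j in range(p_dim):
            h = 1e-5 * max(1.0, abs(beta[j]))
            e = np.zeros(p_dim)
            e[j] = h
            s_plus = self._profile_score(beta + e, dict(cache))
            s_minus = self._profile_score(beta - e, dict(cache))
            J[:, j] = (s_plus - s_minus) / (2.0 * h)
        return -(J + J.T) / 2.0

    def _fit_ml(self, *, tol: float = 1e-8, max_outer: int = 100):
        """Damped Newton ascent of the exact profile log-likelihood.

        Each iteration re-profiles the per-stratum nuisance (closed-form given
        the current fitted probabilities and the phase-I counts) and takes a
        Newton step on the resulting offset-logistic score, halving the step
        whenever the profile likelihood would decrease.
        """
        cache: dict = {}
        # initialize from the pseudo-likelihood fit (cheap, consistent)
        beta = irls_logit(
            self.X, self.y, offset=self._offsets_fixed(),
            term_names=self.terms, check_rank=True,
        ).beta
        ll = self._profile_loglik(beta, cache)
        converged = False
        it = 0
        info = None
        for it in range(1, max_outer + 1):
            score = self._profile_score(beta, cache)
            if np.max(np.abs(score)) < tol:
                converged = True
                break
            info = self._profile_information(beta, cache)
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as err:
                raise RuntimeError(f"singular profile information: {err}") from err
            scale = 1.0
            for _ in range(30):
                beta_new = beta + scale * step
                try:
                    ll_new = self._profile_loglik(beta_new, dict(cache))
                except RuntimeError:
                    ll_new = -np.inf  # boundary nuisance along the trial step
                if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                    break
                scale /= 2.0
            else:
                raise RuntimeError(
                    "two-phase ML step-halving failed to increase the "
                    "profile likelihood"
                )
            delta = np.max(np.abs(beta_new - beta))
            beta = beta_new
            ll = self._profile_loglik(beta, cache)
            if delta < tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"two-phase ML did not converge within {max_outer} iterations"
            )
        if len([s for s in self.strata if len(s.rows)]) == 1:
            # single-stratum (case-control) design: the profile information is
            # near-singular in the intercept direction, and the ML estimates
            # coincide with the offset-logistic fit; use that model's observed
            # information, which is the standard (slope-exact) covariance
            p = special.expit(self.X @ beta)
            off = self._profile_offsets(p, cache)
            fit = irls_logit(
                self.X, self.y, offset=off, start=beta,
                term_names=self.terms, check_rank=False,
            )
            cov = np.linalg.inv(fit.info)
            return beta, cov, {"converged": True, "llf": ll, "n_iter": it}
        info = self._profile_information(beta, cache)
        eigs = np.linalg.eigvalsh(info)
        if eigs[0] <= 0:
            raise RuntimeError("profile information is not positive definite")
        cov = np.linalg.inv(info)
        return beta, cov, {"converged": True, "llf": ll, "n_iter": it}


def fit_weighted_likelihood(sample: TwoPhaseSample, terms=PATIENT_TERMS):
    """Design-weighted logistic fit of a two-phase sample."""
    return TwoPhaseLogit(sample, terms).fit("weighted")


def fit_pseudo_likelihood(sample: TwoPhaseSample, terms=PATIENT_TERMS):
    """Offset (pseudo-likelihood) logistic fit of a two-phase sample."""
    return TwoPhaseLogit(sample, terms).fit("pseudo")


def fit_max_likelihood(sample: TwoPhaseSample, terms=PATIENT_TERMS):
    """Full two-phase maximum-likelihood fit of a two-phase sample."""
    return TwoPhaseLogit(sample, terms).fit("ml")
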