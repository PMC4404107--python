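"""Monte-Carlo power of the clinic-by-year interaction test across designs.

For each replicate a fresh set of Bernoulli outcomes is drawn over a fixed
covariate population, the design's phase-I table is rebuilt from the
*realized* outcomes, a phase-II sample is drawn and fitted, and the two
clinic-by-year interaction coefficients are tested jointly with a
2-degree-of-freedom Wald test.  Power is the fraction of replicates that
reject.  Supported designs: analysis of the complete patient-level data,
a balanced case-control sample, and balanced two-phase samples stratified on
clinic type (design1) or clinic type by year (design2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import PopulationConfig
from .design import allocate_balanced, build_phase1, draw_case_control, draw_phase2
from .estimators import TwoPhaseLogit
from .logistic import INTERACTION_TERMS, PATIENT_TERMS, build_design, irls_logit
from .population import (
    assign_outcomes,
    calibrate_intercept,
    generate_covariates,
)

POWER_DESIGNS = ("complete", "case_control", "twophase_design1", "twophase_design2")


class PowerSimulationError(RuntimeError):
    """Raised when the estimator fails in too many replicates."""


@dataclass
class PowerScenario:
    """One cell of the power study.

    ``phase2_n`` is ignored for the complete-data design.  ``estimator``
    (weighted / pseudo / ml) applies to the sampling designs; the
    case-control design is fitted as the single-stratum two-phase model,
    for which all estimators share their slope estimates.
    """

    design: str
    phase2_n: int = 0
    estimator: str = "ml"
    replicates: int = 200
    alpha: float = 0.05
    regenerate_covariates: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.design not in POWER_DESIGNS:
            raise KeyError(f"unknown design {self.design!r}; choose from {POWER_DESIGNS}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PowerEstimate:
    """Estimated rejection probability with its Monte-Carlo standard error."""

    scenario: PowerScenario
    power: float
    mc_se: float
    replicates: int
    n_rejected: int
    n_failed: int = 0
    coef_estimates: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_converged(self) -> int:
        return self.replicates - self.n_failed

    def as_row(self) -> dict:
        s = self.scenario
        return {
            "design": s.design,
            "n": _n_label(s),
            "estimator": s.estimator if s.design != "complete" else "ml",
            "replicates": self.replicates,
            "power": self.power,
            "mc_se": self.mc_se,
            "n_converged": self.n_converged,
        }


def _n_label(scenario: PowerScenario):
    return "all" if scenario.design == "complete" else scenario.phase2_n


def _replicate_pvalue_and_params(
    scenario, patients, X_full, model, config, rep
) -> tuple[float, pd.Series | None]:
    """P-value of the 2-df interaction test for one outcome replicate."""
    sim = assign_outcomes(patients, model, config.seed, replicate=rep)
    if scenario.design == "complete":
        fit = irls_logit(
            X_full, sim["outcome"].to_numpy(dtype=float),
            term_names=list(PATIENT_TERMS), check_rank=False,
        )
        cov = np.linalg.inv(fit.info)
        idx = [PATIENT_TERMS.index(t) for t in INTERACTION_TERMS]
        b = fit.beta[idx]
        V = cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        params = pd.Series(fit.beta, index=list(PATIENT_TERMS))
        return float(stats.chi2.sf(stat, len(idx))), params

    draw_seed = int(
        np.random.SeedSequence((scenario.seed, rep)).generate_state(1)[0] % (2**31)
    )
    if scenario.design == "case_control":
        sample = draw_case_control(sim, scenario.phase2_n, seed=draw_seed)
    else:
        design = "design1" if scenario.design.endswith("design1") else "design2"
        phase1 = build_phase1(sim, design)
        alloc = allocate_balanced(phase1, scenario.phase2_n)
        sample = draw_phase2(sim, phase1, alloc, seed=draw_seed)
    res = TwoPhaseLogit(sample).fit(scenario.estimator)
    wald = res.wald_test(list(INTERACTION_TERMS))
    return wald.p_value, res.params


def run_power(
    scenario: PowerScenario,
    config: PopulationConfig,
    *,
    keep_estimates: bool = False,
    _patients: pd.DataFrame | None = None,
) -> PowerEstimate:
    """Monte-Carlo power of the 2-df interaction Wald test for one scenario.

    Covariates are generated once and held fixed across replicates (outcomes
    are redrawn each time), unless ``regenerate_covariates`` is set.
    Replicates in which the sampled data cannot support the model (e.g. an
    empty interaction cell or non-convergence) count as non-rejections and
    are tallied; if they exceed 5% of replicates the run aborts.
    """
    cfg = config.replace(seed=int(config.seed + 7919 * scenario.seed))
    patients = generate_covariates(cfg) if _patients is None else _patients
    model = cfg.coefficients
    if model.intercept is None:
        model = model.replace(intercept=calibrate_intercept(cfg, patients=patients))
    X_full = (
        build_design(patients, PATIENT_TERMS)
        if scenario.design == "complete"
        else None
    )

    rejected = 0
    failures: list[tuple[int, str]] = []
    estimates = []
    for rep in range(scenario.replicates):
        if scenario.regenerate_covariates and rep > 0:
            patients = generate_covariates(cfg.replace(seed=cfg.seed + rep))
            if scenario.design == "complete":
                X_full = build_design(patients, PATIENT_TERMS)
        try:
            pval, params = _replicate_pvalue_and_params(
                scenario, patients, X_full, model, cfg, rep
            )
        except Exception as err:  # inestimable draw: tally as a non-rejection
            failures.append((rep, f"{type(err).__name__}: {err}"))
            continue
        if pval < scenario.alpha:
            rejected += 1
        if keep_estimates and params is not None:
            estimates.append(params)
    if len(failures) > 0.05 * scenario.replicates:
        raise PowerSimulationError(
            f"estimator failed in {len(failures)}/{scenario.replicates} replicates; "
            f"first failures: {failures[:3]}"
        )
    power = rejected / scenario.replicates
    return PowerEstimate(
        scenario=scenario,
        power=power,
        mc_se=float(np.sqrt(power * (1.0 - power) / scenario.replicates)),
        replicates=scenario.replicates,
        n_rejected=rejected,
        n_failed=len(failures),
        coef_estimates=pd.DataFrame(estimates) if keep_estimates else None,
    )


def power_curve(
    scenarios: list[PowerScenario], config: PopulationConfig
) -> pd.DataFrame:
    """Run several scenarios over one shared covariate realization.

    Returns one row per scenario (design, n, estimator, replicates, power,
    mc_se, n_converged).
    """
    if not scenarios:
        raise ValueError("scenario list must be non-empty")
    patients = generate_covariates(config)
    rows = []
    for sc in scenarios:
        est = run_power(sc, config, _patients=patients if sc.seed == 0 else None)
        rows.append(est.as_row())
    return pd.DataFrame(rows)


def plot_power_curve(results: pd.DataFrame, path) -> None:
    """Power-vs-n curves per design (PNG); complete data drawn as a reference line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for design, sub in results.groupby("design"):
        if design == "complete":
            ax.axhline(sub["power"].iloc[0], color="grey", ls="--",
                       label="complete data")
            continue
        sub = sub[sub["n"] != "all"].sort_values("n")
        ax.errorbar(sub["n"].astype(int), sub["power"], yerr=2 * sub["mc_se"],
                    marker="o", label=design)
    ax.set_xlabel("phase-II sample size n")
    ax.set_ylabel("power (2-df interaction Wald test)")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
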