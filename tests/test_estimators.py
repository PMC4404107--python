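"""Two-phase estimators: reductions, hand-checked weighting, orderings."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import twophase as tp
from twophase.design import Allocation, PhaseOneTable, TwoPhaseSample
from twophase.estimators import InestimableDesignError, TwoPhaseLogit
from twophase.logistic import fit_logistic


@pytest.fixture(scope="module")
def census_sample(small_population):
    patients, _ = small_population
    p1 = tp.build_phase1(patients, "design2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alloc = tp.allocate_balanced(p1, len(patients))
    return tp.draw_phase2(patients, p1, alloc, seed=2)


@pytest.fixture(scope="module")
def cc_sample(small_population):
    patients, _ = small_population
    return tp.draw_case_control(patients, 1_200, seed=6)


TERMS = ("intercept", "age_lin", "age_quad", "female", "who34", "south",
         "year_2006", "year_2007", "private")
# reduced term set (no interactions): the scaled test population is too small
# to estimate clinic-by-year interactions stably


class TestCensusReduction:
    """On a 100% sample all three estimators are ordinary maximum likelihood."""

    @pytest.mark.parametrize("method", ["weighted", "pseudo", "ml"])
    def test_estimates_reduce_exactly(self, census_sample, small_population, method):
        patients, _ = small_population
        full = fit_logistic(patients, terms=TERMS)
        res = TwoPhaseLogit(census_sample, terms=TERMS).fit(method)
        np.testing.assert_allclose(
            res.params.to_numpy(), full.params.to_numpy(), atol=1e-6
        )

    def test_weighted_covariance_reduces_exactly(self, census_sample, small_population):
        patients, _ = small_population
        full = fit_logistic(patients, terms=TERMS)
        res = TwoPhaseLogit(census_sample, terms=TERMS).fit("weighted")
        np.testing.assert_allclose(
            res.cov_params.to_numpy(), full.cov_params.to_numpy(), atol=1e-10
        )

    def test_ml_covariance_reduces_to_inverse_information(
        self, census_sample, small_population
    ):
        patients, _ = small_population
        full = fit_logistic(patients, terms=TERMS)
        res = TwoPhaseLogit(census_sample, terms=TERMS).fit("ml")
        np.testing.assert_allclose(
            res.bse.to_numpy(), full.bse.to_numpy(), rtol=1e-5
        )

    def test_pseudo_offsets_vanish_and_covariance_is_close(
        self, census_sample, small_population
    ):
        patients, _ = small_population
        full = fit_logistic(patients, terms=TERMS)
        fitter = TwoPhaseLogit(census_sample, terms=TERMS)
        assert np.allclose(fitter._offsets_fixed(), 0.0)
        res = fitter.fit("pseudo")
        # the sandwich equals the inverse information only asymptotically;
        # terms tied to the small private strata deviate most
        np.testing.assert_allclose(
            res.bse.to_numpy(), full.bse.to_numpy(), rtol=0.15
        )


class TestSingleStratumEquivalence:
    """Case-control sampling shifts only the intercept of the logistic model."""

    @pytest.mark.parametrize("method", ["pseudo", "ml"])
    def test_slopes_equal_plain_logistic(self, cc_sample, method):
        res = TwoPhaseLogit(cc_sample, terms=TERMS).fit(method)
        plain = fit_logistic(cc_sample.data, terms=TERMS)
        np.testing.assert_allclose(
            res.params.to_numpy()[1:], plain.params.to_numpy()[1:], atol=1e-6
        )

    def test_intercept_shift_is_the_sampling_fraction_offset(self, cc_sample):
        res = TwoPhaseLogit(cc_sample, terms=TERMS).fit("pseudo")
        plain = fit_logistic(cc_sample.data, terms=TERMS)
        p1 = cc_sample.phase1
        n1 = (cc_sample.data["outcome"] == 1).sum()
        n0 = (cc_sample.data["outcome"] == 0).sum()
        offset = math.log((n1 / p1.n_cases) / (n0 / p1.n_controls))
        assert res.params["intercept"] == pytest.approx(
            plain.params["intercept"] - offset, abs=1e-6
        )


def _toy_weighted_sample():
    """8 patients, 2 strata; weighted fit solvable by hand.

    With design weights w constant within each (outcome, stratum) cell, the
    weighted MLE of the intercept+female model is the log cross-product ratio
    of the weight-summed 2x2 table.
    """
    rows = []
    # stratum, female, outcome; one patient per combination
    for stratum in ("s1", "s2"):
        for female in (0, 1):
            for y in (0, 1):
                rows.append((stratum, female, y))
    df = pd.DataFrame(rows, columns=["stratum", "female", "outcome"])
    df["patient_id"] = range(len(df))
    df["age"] = 40
    df["who34"] = 1
    df["region"] = "South"
    df["year"] = 2005
    df["clinic_type"] = "public"
    counts = {"s1": (4, 6), "s2": (3, 10)}  # (N0, N1) per stratum; n_ys = 2
    phase1 = PhaseOneTable.from_counts("toy", counts)
    alloc = pd.DataFrame(
        [
            {"outcome": y, "stratum": s, "N": counts[s][y], "n": 2}
            for s in counts
            for y in (0, 1)
        ]
    )
    df["weight"] = [
        counts[s][y] / 2.0 for s, _, y in zip(df["stratum"], df["female"], df["outcome"])
    ]
    sample = TwoPhaseSample(
        data=df, phase1=phase1, allocation=Allocation(table=alloc, n=8)
    )
    return sample, counts


def test_weighted_estimate_matches_hand_computed_cross_product():
    sample, counts = _toy_weighted_sample()
    res = TwoPhaseLogit(sample, terms=("intercept", "female")).fit("weighted")
    w = {
        (s, y): counts[s][y] / 2.0 for s in counts for y in (0, 1)
    }
    # weight-summed 2x2 table over (female, outcome)
    t = {
        (f, y): sum(w[(s, y)] for s in counts) for f in (0, 1) for y in (0, 1)
    }
    expected = math.log((t[(1, 1)] * t[(0, 0)]) / (t[(1, 0)] * t[(0, 1)]))
    assert res.params["female"] == pytest.approx(expected, abs=1e-8)


def test_weight_invariants(small_population):
    patients, _ = small_population
    p1 = tp.build_phase1(patients, "design1")
    alloc = tp.allocate_balanced(p1, 500)
    sample = tp.draw_phase2(patients, p1, alloc, seed=9)
    w = sample.data["weight"]
    assert (w >= 1.0 - 1e-12).all()
    assert w.sum() == pytest.approx(len(patients))


def test_unsampled_cell_aborts_estimation(small_population):
    patients, _ = small_population
    p1 = tp.build_phase1(patients, "design1")
    table = pd.DataFrame(
        [
            {"outcome": 0, "stratum": "public", "N": p1.cell(0, "public"), "n": 60},
            {"outcome": 1, "stratum": "public", "N": p1.cell(1, "public"), "n": 60},
            {"outcome": 0, "stratum": "private", "N": p1.cell(0, "private"), "n": 30},
            # (1, private) deliberately unsampled although members exist
            {"outcome": 1, "stratum": "private", "N": p1.cell(1, "private"), "n": 0},
        ]
    )
    sample = tp.draw_phase2(patients, p1, Allocation(table=table, n=150), seed=3)
    with pytest.raises(InestimableDesignError, match="no phase-II sample"):
        TwoPhaseLogit(sample, terms=TERMS)


def test_efficiency_ordering_on_stratifying_variables(full_config):
    """Empirical variance ordering ML <= pseudo <= weighted (5% slack) for the
    clinic-type coefficient under the clinic-by-year design, and agreement of
    the estimators' means; paired replicates keep the comparison tight."""
    from twophase.population import assign_outcomes, calibrate_intercept, generate_covariates

    patients = generate_covariates(full_config)
    model = full_config.coefficients.replace(
        intercept=calibrate_intercept(full_config, patients=patients)
    )
    reps = 120
    params = {m: [] for m in ("weighted", "pseudo", "ml")}
    for rep in range(reps):
        sim = assign_outcomes(patients, model, full_config.seed, replicate=rep)
        p1 = tp.build_phase1(sim, "design2")
        alloc = tp.allocate_balanced(p1, 2_000)
        sample = tp.draw_phase2(sim, p1, alloc, seed=500 + rep)
        fitter = TwoPhaseLogit(sample)
        for m in params:
            params[m].append(fitter.fit(m).params)
    frames = {m: pd.DataFrame(v) for m, v in params.items()}
    for term in ("private", "private_2006", "year_2006"):
        var = {m: frames[m][term].var() for m in frames}
        assert var["ml"] <= 1.05 * var["pseudo"], term
        assert var["pseudo"] <= 1.05 * var["weighted"], term
        means = {m: frames[m][term].mean() for m in frames}
        mc = frames["ml"][term].std() / math.sqrt(reps)
        assert abs(means["ml"] - model.coefficients()[term]) < 4 * mc, term
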