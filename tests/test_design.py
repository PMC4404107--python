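"""Phase-I stratification, balanced allocation, and phase-II draws."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twophase as tp
from twophase import survey
from twophase.design import (
    AllocationError,
    PhaseOneTable,
    allocate_balanced,
    build_phase1,
    cohort_strata,
    draw_case_control,
    draw_phase2,
)


@pytest.fixture(scope="module")
def survey_margin_population(full_population):
    """Full population with outcomes overwritten to realize the published
    clinic-type margins exactly (302/2,095 private, 15,839/64,651 public)."""
    patients, _ = full_population
    pats = patients.sort_values("patient_id").reset_index(drop=True).copy()
    outcome = np.zeros(len(pats), dtype=np.int8)
    priv = np.flatnonzero(pats["clinic_type"] == "private")
    pub = np.flatnonzero(pats["clinic_type"] == "public")
    outcome[priv[:302]] = 1
    outcome[pub[:15_839]] = 1
    pats["outcome"] = outcome
    return pats


class TestBuildPhase1:
    def test_design1_reproduces_survey_cells(self, survey_margin_population):
        p1 = build_phase1(survey_margin_population, "design1")
        assert p1.cell(0, "private") == 2_095
        assert p1.cell(1, "private") == 302
        assert p1.cell(0, "public") == 64_651
        assert p1.cell(1, "public") == 15_839

    def test_single_stratum_reduces_to_case_control_margin(
        self, survey_margin_population
    ):
        p1 = build_phase1(survey_margin_population, "case_control")
        assert p1.strata == ["all"]
        assert p1.n_cases == 16_141
        assert p1.n_controls == 66_746

    def test_design2_cells_sum_to_design1_margins(self):
        """Published year-by-clinic cells aggregate to the clinic-type table."""
        p2 = PhaseOneTable.from_counts("design2", survey.DESIGN2_COUNTS)
        public = [s for s in p2.strata if s.endswith("public")]
        assert p2.counts.loc[public, "N0"].sum() == 64_651
        assert p2.counts.loc[public, "N1"].sum() == 15_839
        assert p2.total == survey.N_PATIENTS

    def test_every_design_partitions_the_population(self, full_population):
        patients, _ = full_population
        cohorts = tp.aggregate_cohorts(patients)
        for design in ("design1", "design2", "design3", "design4", "design5",
                       "design6", "case_control"):
            p1 = build_phase1(patients, design, cohorts=cohorts)
            assert p1.total == len(patients)
            assert p1.patient_strata.notna().all()
            assert len(p1.strata) >= 2 or design == "case_control"

    def test_requires_outcomes(self, small_config):
        covs = tp.generate_covariates(small_config)
        with pytest.raises(ValueError, match="outcomes"):
            build_phase1(covs, "design1")

    def test_unknown_design_rejected(self, small_cohorts):
        with pytest.raises(KeyError, match="unknown design"):
            cohort_strata(small_cohorts, "design9")


class TestAllocateBalanced:
    def test_design1_worked_example(self):
        p1 = PhaseOneTable.from_counts("design1", survey.DESIGN1_COUNTS)
        alloc = allocate_balanced(p1, 5_000)
        assert alloc.base_target == 1_250
        assert alloc.cell(0, "public") == 1_250
        assert alloc.cell(0, "private") == 1_250
        # the 302 private cases are exhausted; the shortfall moves to the
        # public case stratum
        assert alloc.cell(1, "private") == 302
        assert alloc.cell(1, "public") == 2_198

    def test_design2_base_target(self):
        p1 = PhaseOneTable.from_counts("design2", survey.DESIGN2_COUNTS)
        alloc = allocate_balanced(p1, 5_000)
        assert alloc.base_target == 416  # floor(5000 / 12)
        # exhausted case cells keep their full population
        assert alloc.cell(1, "2005/private") == 22
        assert alloc.cell(1, "2006/private") == 167
        assert alloc.cell(1, "2007/private") == 113

    def test_census_allocation_equals_population(self):
        p1 = PhaseOneTable.from_counts("design1", survey.DESIGN1_COUNTS)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            alloc = allocate_balanced(p1, p1.total)
        merged = alloc.table
        assert (merged["n"] == merged["N"]).all()

    def test_n_exceeding_population_rejected(self):
        p1 = PhaseOneTable.from_counts("design1", {"a": (5, 5), "b": (5, 5)})
        with pytest.raises(AllocationError, match="exceeds"):
            allocate_balanced(p1, 21)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 60), st.integers(0, 60)),
            min_size=2,
            max_size=6,
        ),
        frac=st.floats(0.05, 1.0),
    )
    def test_allocation_invariants(self, counts, frac):
        """Conservation, feasibility, and outcome-locality of redistribution."""
        mapping = {f"s{i}": c for i, c in enumerate(counts)}
        p1 = PhaseOneTable.from_counts("designX", mapping)
        total = p1.total
        if total == 0:
            return
        n = max(1, int(frac * total))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            alloc = allocate_balanced(p1, n)
        t = alloc.table
        assert t["n"].sum() == n
        assert (t["n"] <= t["N"]).all()
        crossed = any("crossed outcome levels" in str(w.message) for w in caught)
        if crossed:
            # a whole outcome level must have been exhausted
            sums = t.groupby("outcome")[["n", "N"]].sum()
            assert (sums["n"] == sums["N"]).any()

    def test_single_stratum_equals_case_control_split(self):
        p1 = PhaseOneTable.from_counts("case_control", {"all": (1_000, 400)})
        alloc = allocate_balanced(p1, 600)
        assert alloc.cell(0, "all") == 300 and alloc.cell(1, "all") == 300


class TestDrawPhase2:
    def test_realized_counts_match_allocation(self, small_population):
        patients, _ = small_population
        p1 = build_phase1(patients, "design2")
        alloc = allocate_balanced(p1, 400)
        sample = draw_phase2(patients, p1, alloc, seed=5)
        realized = sample.cell_counts().set_index(["outcome", "stratum"])["n"]
        for _, row in alloc.table.iterrows():
            if row["n"]:
                assert realized[(row["outcome"], row["stratum"])] == row["n"]
        # design weights add back to the population size
        assert sample.data["weight"].sum() == pytest.approx(len(patients))

    def test_draws_are_seed_deterministic(self, small_population):
        patients, _ = small_population
        p1 = build_phase1(patients, "design1")
        alloc = allocate_balanced(p1, 300)
        ids_a = set(draw_phase2(patients, p1, alloc, seed=3).data["patient_id"])
        ids_b = set(draw_phase2(patients, p1, alloc, seed=3).data["patient_id"])
        ids_c = set(draw_phase2(patients, p1, alloc, seed=4).data["patient_id"])
        assert ids_a == ids_b
        assert ids_a != ids_c

    def test_census_draw_is_the_population(self, small_population):
        patients, _ = small_population
        p1 = build_phase1(patients, "design1")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            alloc = allocate_balanced(p1, len(patients))
        sample = draw_phase2(patients, p1, alloc, seed=1)
        assert set(sample.data["patient_id"]) == set(patients["patient_id"])
        assert (sample.data["weight"] == 1.0).all()

    def test_exhausted_private_cases_all_sampled(self, survey_margin_population):
        p1 = build_phase1(survey_margin_population, "design1")
        alloc = allocate_balanced(p1, 5_000)
        sample = draw_phase2(survey_margin_population, p1, alloc, seed=8)
        private_cases = sample.data[
            (sample.data["stratum"] == "private") & (sample.data["outcome"] == 1)
        ]
        assert len(private_cases) == 302
        assert (private_cases["weight"] == 1.0).all()


class TestCaseControl:
    def test_balanced_split(self, small_population):
        patients, _ = small_population
        sample = draw_case_control(patients, 400, seed=2)
        by_outcome = sample.data.groupby("outcome").size()
        assert by_outcome[0] == 200 and by_outcome[1] == 200

    def test_two_patient_draw(self, small_population):
        patients, _ = small_population
        sample = draw_case_control(patients, 2, case_fraction=0.5, seed=2)
        assert sorted(sample.data["outcome"]) == [0, 1]

    def test_infeasible_case_demand_raises(self, small_population):
        patients, _ = small_population
        n_cases = int(patients["outcome"].sum())
        # at the boundary every case is sampled; one beyond must fail
        ok = draw_case_control(patients, 2 * n_cases, seed=2)
        assert (ok.data["outcome"] == 1).sum() == n_cases
        with pytest.raises(AllocationError, match="cases"):
            draw_case_control(patients, 2 * n_cases + 2, seed=2)
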