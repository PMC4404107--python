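"""Published aggregate summaries of the 2005-2007 Malawi national ART survey.

The Malawian Ministry of Health's one-time cross-sectional survey of its
national antiretroviral-therapy (ART) program recorded a binary "status at
six months post-registration" outcome for N = 82,887 adult registrants at
189 clinics, alongside baseline demographics.  Only the *aggregated*
summaries of that survey are public, and they are the inputs this package
treats as ground truth:

* outcome margins by patient characteristics (:data:`OUTCOME_MARGINS`);
* the six candidate phase-I cross-classifications of the whole registrant
  population by outcome and routinely available group-level information
  (:data:`DESIGN1_COUNTS` ... :data:`DESIGN6_COUNTS`);
* patient-level covariate margins (:data:`PATIENT_MARGINALS`) used to
  parameterize the synthetic population generator; and
* the adjusted odds ratios from the gold-standard patient-level logistic
  regression (:data:`GOLD_STANDARD_ODDS_RATIOS`), which drive outcome
  generation in simulations.

A "negative" six-month status means the registrant stopped treatment, was
lost to follow-up, or died within 180 days; transfers and patients alive on
treatment are "non-negative".

Note on internal consistency: the published year-by-clinic-type table prints
6,104 for the (2006, public, negative) cell, but the clinic-type margin
(15,839 public negatives) and the public total of 80,490 are consistent only
with 6,014.  :data:`DESIGN2_COUNTS` carries the reconciled value;
:data:`DESIGN2_COUNTS_PRINTED` preserves the printed one.
"""

from __future__ import annotations

import math

#: Total registrants in the survey (sum of the outcome margin).
N_PATIENTS = 82_887
#: Number of quarterly-clinic cohorts the registrants aggregate into.
N_COHORTS = 1_518
#: Registrants with a negative six-month status ("cases").
N_NEGATIVE = 16_141
#: Registrants with a non-negative six-month status ("controls").
N_NONNEGATIVE = 66_746

#: Outcome margins, ``{panel: {category: (non_negative, negative)}}``.
OUTCOME_MARGINS: dict[str, dict] = {
    "overall": {"all": (66_746, 16_141)},
    "age_band": {
        "16-25": (7_116, 2_130),
        "26-35": (26_460, 6_575),
        "36-45": (21_078, 4_756),
        "46-55": (8_835, 1_888),
        "56-65": (2_785, 656),
        ">65": (472, 136),
    },
    "gender": {"male": (25_150, 7_172), "female": (41_596, 8_969)},
    "who_stage": {"1/2": (4_418, 314), "3/4": (62_328, 15_827)},
    "region": {"central_north": (27_662, 7_269), "south": (39_084, 8_872)},
    "year": {2005: (12_238, 3_514), 2006: (23_893, 6_181), 2007: (30_615, 6_446)},
    "clinic_type": {"public": (64_651, 15_839), "private": (2_095, 302)},
}

# ---------------------------------------------------------------------------
# Phase-I stratification tables: {stratum label: (non_negative, negative)}.
# ---------------------------------------------------------------------------

#: Design #1 -- outcome x clinic type.
DESIGN1_COUNTS = {"public": (64_651, 15_839), "private": (2_095, 302)}

#: Design #2 -- outcome x registration year x clinic type, as printed.
DESIGN2_COUNTS_PRINTED = {
    (2005, "public"): (11_991, 3_492),
    (2005, "private"): (247, 22),
    (2006, "public"): (22_887, 6_104),
    (2006, "private"): (1_006, 167),
    (2007, "public"): (29_773, 6_333),
    (2007, "private"): (842, 113),
}

#: Design #2 with the (2006, public, negative) cell reconciled to the margins.
DESIGN2_COUNTS = {
    **DESIGN2_COUNTS_PRINTED,
    (2006, "public"): (22_887, 6_014),
}

#: Design #3 -- outcome x cohort percent WHO stage 1/2 (<=5% vs >5%).
DESIGN3_COUNTS = {"who12<=5%": (50_570, 13_191), "who12>5%": (16_176, 2_950)}

#: Design #4 -- outcome x cohort average age band.
DESIGN4_COUNTS = {
    "age<=35": (12_954, 3_570),
    "age36-40": (51_959, 12_239),
    "age>40": (1_833, 332),
}

#: Design #5 -- outcome x cohort percent-female band.
DESIGN5_COUNTS = {
    "pf=0%": (189, 20),
    "pf1-40%": (3_360, 630),
    "pf41-50%": (4_766, 1_144),
    "pf51-60%": (19_255, 5_248),
    "pf60-99%": (38_949, 9_081),
    "pf=100%": (227, 18),
}

#: Design #6 -- outcome x WHO-band x clinic type.
DESIGN6_COUNTS = {
    "who12<=5%/public": (49_160, 12_796),
    "who12>5%/public": (15_491, 2_863),
    "who12<=5%/private": (1_410, 215),
    "who12>5%/private": (685, 87),
}

#: Registrants per (registration year, clinic type), from the reconciled
#: Design #2 table; these are the exact cell sizes the synthetic generator
#: reproduces.  Sums to :data:`N_PATIENTS`; public total 80,490, private 2,397.
STRATUM_SIZES = {
    (year, ctype): sum(cell) for (year, ctype), cell in DESIGN2_COUNTS.items()
}

# ---------------------------------------------------------------------------
# Patient-level covariate margins.
# ---------------------------------------------------------------------------

#: Patient counts per age band (band edges in years, inclusive).
AGE_BAND_COUNTS = {
    (16, 25): 9_246,
    (26, 35): 33_035,
    (36, 45): 25_834,
    (46, 55): 10_723,
    (56, 65): 3_441,
    (66, 80): 608,  # ">65" in the survey; the generator draws uniform 66-80
}

#: Marginal counts used to parameterize the covariate generator.
PATIENT_MARGINALS = {
    "female": 50_565,
    "who34": 78_155,
    "south": 47_956,
}

#: Adjusted odds ratios from the gold-standard patient-level logistic
#: regression (complete-data analysis).  Age uses the transform
#: x = (age - 45) / 10; "private_2006"/"private_2007" are clinic-by-year
#: interactions.  The model intercept is not public and is calibrated to the
#: overall 19.5% negative rate at simulation time.
GOLD_STANDARD_ODDS_RATIOS = {
    "age_lin": 0.96,
    "age_quad": 1.06,
    "female": 0.72,
    "who34": 3.33,
    "south": 0.92,
    "year_2006": 0.91,
    "year_2007": 0.76,
    "private": 0.31,
    "private_2006": 2.16,
    "private_2007": 2.05,
}

#: Overall negative six-month outcome rate the intercept is calibrated to.
OVERALL_NEGATIVE_RATE = 0.195


def negative_rate(non_negative: int, negative: int) -> float:
    """Percent of registrants with a negative status, e.g. 19.5 for overall."""
    return 100.0 * negative / (negative + non_negative)


def rate_table(margins: dict | None = None) -> dict:
    """Negative-outcome rate (percent, 1 dp) for every margin category.

    Parameters
    ----------
    margins
        ``{panel: {category: (non_negative, negative)}}``; defaults to the
        survey's :data:`OUTCOME_MARGINS`.

    Returns
    -------
    dict
        ``{panel: {category: rate_percent}}`` rounded to one decimal, the
        precision at which the survey reports them.
    """
    margins = OUTCOME_MARGINS if margins is None else margins
    out: dict[str, dict] = {}
    for panel, cats in margins.items():
        out[panel] = {
            cat: round(negative_rate(nn, neg), 1) for cat, (nn, neg) in cats.items()
        }
    return out


def _check_internal_consistency() -> None:
    assert sum(STRATUM_SIZES.values()) == N_PATIENTS
    assert sum(n for n, _ in DESIGN1_COUNTS.values()) == N_NONNEGATIVE
    assert sum(c for _, c in DESIGN1_COUNTS.values()) == N_NEGATIVE
    assert sum(c for _, c in DESIGN2_COUNTS.values()) == N_NEGATIVE
    assert math.isclose(
        negative_rate(*OUTCOME_MARGINS["overall"]["all"]), 19.5, abs_tol=0.05
    )


_check_internal_consistency()
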