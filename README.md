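# twophase

**Two-phase outcome-dependent sampling designs for monitoring patient-level
outcomes in ART programs that only collect aggregated facility data.**

National antiretroviral-therapy (ART) programs in resource-limited settings
typically monitor outcomes through *quarterly-clinic cohorts*: every three
months each clinic reports one aggregate record (number of registrants,
number female, number WHO stage 3/4, number with a negative six-month
outcome, ...) with no cross-classification and no patient-level detail.
Risk-factor analyses run on such aggregates are exposed to **ecological
bias** — group-level associations that differ from, and can even reverse,
the patient-level ones.

The only reliable cure is patient-level data, but collecting it nationally
is prohibitively expensive. This package implements the middle road: the
**two-phase design**. Phase I stratifies the *entire* registrant population
by outcome status crossed with information that already sits in the
aggregated cohort records (clinic type, registration year, cohort
composition bands). Phase II draws a balanced without-replacement subsample
within each stratum and retrospectively collects patient-level covariates on
it alone. Because the phase-I stratum counts `N_ys` are known for the whole
population, estimation can combine them with the phase-II data for large
efficiency gains over a conventional case–control sample of the same size.

The running example is the Malawi national ART program's 2005–2007
cross-sectional survey: N = 82,887 adult registrants at 189 clinics,
N* = 1,518 quarterly-clinic cohorts, and a binary "negative status at six
months" outcome (stopped treatment, lost to follow-up, or death within 180
days; overall rate 19.5%).

## The models

**Patient level (gold standard).** Logistic regression for patient *i*:

```
logit P(y_i = 1 | x_i) = β₀ + β₁·a_i + β₂·a_i² + β₃·female_i + β₄·who34_i
                        + β₅·south_i + β₆·I(yr=2006) + β₇·I(yr=2007)
                        + β₈·private_i + β₉·private_i·I(yr=2006)
                        + β₁₀·private_i·I(yr=2007),      a_i = (age_i − 45)/10
```

fitted by IRLS. The clinic-by-year interactions (β₉, β₁₀) carry the study's
substantive question — did the private/public outcome gap change over time —
and are tested jointly with a 2-df Wald test.

**Group level (ecological).** The same structure fitted to cohort aggregates
as a binomial outcome `n_negative / n_total` with group covariates (mean
age, percent female per 20 points, an indicator of >90% WHO stage 3/4),
using quasi-likelihood: covariance inflated by the Pearson dispersion
φ = X²/(N* − p).

**Two-phase estimators.** From a `TwoPhaseSample` the logistic parameters
can be estimated by

* `weighted` — design-weighted (Horvitz–Thompson) likelihood, weights
  `N_ys/n_ys`, sandwich variance with finite-population correction;
* `pseudo` — offset logistic regression with per-stratum offsets
  `log[(n_1s/N_1s)/(n_0s/N_0s)]` and an offset-estimation variance
  correction;
* `ml` — full two-phase maximum likelihood via the profile/offset
  formulation (nonparametric within-stratum covariate distributions profiled
  out; inverse observed profile information for the covariance).

All three reduce to ordinary maximum likelihood on a census sample, and the
empirical efficiency ordering on stratifying variables is ml ≤ pseudo ≤
weighted.

## Worked example

```python
import twophase as tp

config = tp.default_config(seed=7)            # the Malawi-survey scenario
patients, model = tp.simulate_population(config)
print(len(patients), round(patients["outcome"].mean(), 3))
# 82887 0.198

gold = tp.fit_logistic(patients)              # complete patient-level data
print(gold.or_table().loc["private"].round(2).to_dict())
# {'OR': 0.26, 'CI_low': 0.16, 'CI_high': 0.41}

phase1 = tp.build_phase1(patients, "design2")  # outcome x year x clinic type
alloc = tp.allocate_balanced(phase1, 5_000)
sample = tp.draw_phase2(patients, phase1, alloc, seed=7)
res = tp.TwoPhaseLogit(sample).fit("ml")
print(res.or_table().loc["private"].round(2).to_dict())
# {'OR': 0.26, 'CI_low': 0.16, 'CI_high': 0.41}
print(res.wald_test(["private_2006", "private_2007"]))
# Wald chi2(2) = 15.317, p = 0.0004721
```

With detailed data on 5,000 of 82,887 patients (6%), the two-phase ML fit
reproduces the gold-standard private-clinic odds ratio and confidently
detects the clinic-by-year interaction; the same Wald test from a 5,000
patient case–control sample of this population gives chi2(2) = 4.58
(p = 0.10), because a random case–control draw contains only a handful of
private-clinic patients.

A thin CLI wraps the same pipeline:

```bash
twophase simulate --out patients.csv
twophase aggregate --patients patients.csv --out cohorts.csv
twophase sample --patients patients.csv --design design2 --n 5000 --out d2
twophase fit-twophase --sample d2_sample.csv --phase1 d2_phase1.csv --out fit.json
```

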