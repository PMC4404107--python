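# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the places where the design was genuinely open.

## Setting and notation

A national ART program registers patients at clinics; monitoring data are
aggregated into *quarterly-clinic cohorts* (one record per clinic per
quarter, marginal summaries only). The outcome is binary "negative status at
six months post-registration" (stopped treatment, lost to follow-up, death
within 180 days). The reference population is the Malawi 2005–2007 survey:
N = 82,887 adult (≥16 years) registrants, N* = 1,518 cohorts at 189 clinics
(150 public, 39 private), overall negative rate 19.5%.

A two-phase design stratifies all N patients into cells (y, s) — outcome y
crossed with a stratum s computable from the aggregated records — with known
counts N_ys (phase I), then samples n_ys patients without replacement per
cell and collects their covariates (phase II).

## Patient-level model

Logistic regression with terms: intercept; age linear and quadratic on
a = (age − 45)/10; female; WHO stage 3/4; region South; year indicators
(2005 reference); private clinic (public reference); private×2006 and
private×2007 interactions.

*Age transform.* The published age odds ratios (0.96 linear, 1.06
quadratic) are printed without units. We use the decade scale centered at
45 years — the published referent age for the age–outcome curve — because it
produces a U-shaped risk profile of plausible magnitude against the
published crude age-band rates (23.0% at 16–25 falling to 17.6% at 46–55 and
rising to 22.4% above 65). This choice is fixed across the patient model,
the group model, and the generator, so all internal comparisons are
coherent; only the absolute scale of the age coefficients depends on it.

*Fitting.* IRLS (Newton scoring) with step-halving on any likelihood
decrease (≤30 halvings), convergence when max |score| < 1e-8 or relative
log-likelihood change < 1e-10, cap 100 iterations; covariance = inverse
observed information. Degenerate outcomes and perfect separation raise
errors (separation detected by perfect prediction of every response);
rank-deficient designs raise an error naming the collinear terms via
pivoted QR.

*Inference.* Wald tests b'V⁻¹b on coefficient sub-vectors with chi-square
reference; OR tables exp(b ± z·SE); subgroup ("combined") ORs
exp(b_main + b_int) with delta-method variance. α = 0.05 throughout — the
study never states its level, and 0.05 is the convention its 95% intervals
imply.

## Group-level (ecological) model

Binomial-logit on cohort records: n_negative of n_total, covariates mean
age (same transform; the quadratic is ((mean_age − 45)/10)², chosen for
comparability since the group-level age scaling is unstated), percent
female entered as proportion/0.20 (so its coefficient is per 20-point
contrast, the published convention), an indicator pct_who34 > 0.90, region,
year, clinic type, clinic×year. Quasi-likelihood: point estimates are the
binomial MLE; φ = Pearson X²/(N* − p) multiplies the covariance exactly.
Cohorts are assumed unweighted beyond their binomial denominators (the
study does not say otherwise).

The attenuation of the quadratic age term at the cohort level — the
ecological-bias phenomenon the package exists to demonstrate — arises
mechanically: averaging ages within cohorts collapses the variance of the
quadratic regressor, leaving the group model little information about
curvature.

## Sampling designs

Six phase-I stratifications (all computable from cohort aggregates): clinic
type; clinic type × year; percent WHO stage 1/2 ≤/> 5%; mean-age bands
≤35 / 36–40 / >40; percent-female bands 0 / 1–40 / 41–50 / 51–60 / 60–99 /
100%; WHO band × clinic type. The single-stratum special case is the
case–control design.

*Balanced allocation.* Base target ⌊n/#cells⌋ per (y, s) cell; the
remainder goes one apiece to the largest cells (ties by lexicographic
stratum key). Cells smaller than their target are exhausted; the shortfall
is redistributed **equally** among unexhausted cells of the same outcome
level, iterating until absorbed, and crosses outcome levels only as a last
resort (with a warning). Equal-split redistribution (rather than
proportional) is chosen because it preserves balance and matches the
published worked example: at n = 5,000 under the clinic-type design, the
302 private cases are exhausted and the 2,198-patient shortfall moves to
the public-case cell. The remainder rule is our fixed reproducibility
convention; the published example allocates 416 × 12 = 4,992 and is silent
about the last 8.

*Draws.* Simple random sampling without replacement within cells, seeded;
case–control draws default to an equal case:control split (the published
n = 5,000 case–control comparator does not state its split).

## Two-phase estimators

All three estimate the same patient-level logistic parameters from a
phase-II sample plus the phase-I table, and all reduce to ordinary ML on a
census. Cells with members but no phase-II sample abort estimation
(silently dropping their population counts would bias the phase-I
contribution).

**Weighted likelihood.** Horvitz–Thompson weights w = N_ys/n_ys solve the
weighted score equation. Covariance B + B·M·B with B the inverse weighted
information and M = Σ_cells N(N−n)/n · S_cell, S_cell the within-cell
sample covariance of the unweighted scores: model-based uncertainty plus
design-based sampling variance with per-cell finite-population correction
(a census has M = 0 and reduces exactly).

**Pseudo-likelihood.** Ordinary logistic fit with fixed per-stratum offsets
log[(n_1s/N_1s)/(n_0s/N_0s)] (a cell with no members counts as fully
sampled). Covariance I⁻¹[Σ_cells n·S_cell + Σ_s t_s t_s'(1/N_1s + 1/N_0s)]I⁻¹
with t_s = Σ_{i∈s} v_i x_i, derived from joint estimating equations for the
slopes and the phase-I stratum log-odds: the first term is the within-cell
variability of the estimating function, the second the between-stratum
variability of the estimated sampling fractions. The bracket converges to I
at a census, so the reduction of the covariance is asymptotic (estimates
reduce exactly).

**Maximum likelihood.** The full likelihood is the phase-I stratum-outcome
multinomial times the phase-II conditional likelihood, with the
within-stratum covariate distributions G_s treated nonparametrically.
Profiling G_s gives masses g_si = 1/(N_s − u_s p_i − v_s(1−p_i)) with
u_s = (N_1s−n_1s)/P_1s, v_s = (N_0s−n_0s)/P_0s, and the profile score is an
offset-logistic score with offsets δ_s = log((N_s−u_s)/(N_s−v_s)). The
stratum case probability P_1s solves the normalization Σ_i g_si = 1 on
(c_1s/N_s, 1 − c_0s/N_s); this equation also admits the degenerate solution
P_1s = c_1s/(c_1s+c_0s) (constant g), which is not a stationary point of
the strictly concave inner problem and is rejected by checking
self-consistency Σ g_si p_i = P_1s. Root search: vectorized bracket scan +
Brent, warm-started from the previous solve; damped self-consistency
iteration as fallback.

β is found by damped Newton ascent of the exact profile log-likelihood
(step-halving on any decrease), initialized at the pseudo-likelihood
estimate, converged at max |Δβ| < 1e-8 or max |score| < 1e-8. Covariance =
inverse observed profile information, computed by central finite
differences of the profile score (relative step 1e-5, symmetrized). A
boundary nuisance estimate (fitted stratum case probability at 0 or 1)
raises an error. For a single-stratum (case–control) design the profile
information is near-singular in the intercept direction and the ML
estimates coincide with the offset-logistic fit, so the covariance is taken
from that model's observed information — the standard choice, exact for the
slopes. Note that when the stratification is saturated by model
terms — as it is for the clinic-type and clinic-type×year designs under the
default model — the ML and pseudo-likelihood point estimates coincide
exactly; they differ on covariate-band stratifications.

## Synthetic population generator

The generator's defaults *are* the study conditions; they are not tuning
knobs.

* **Cell sizes.** Exact (year × clinic type) counts from the published
  phase-I table: public 15,483 / 28,901 / 36,106 and private 269 / 1,173 /
  955 (total 82,887, public 80,490, private 2,397). The published table
  prints 6,104 for the 2006-public-negative cell, which is inconsistent
  with its own clinic-type margin; we use the reconciled 6,014 (the only
  value consistent with 15,839 public negatives and the 82,887 total).
* **Cohort structure.** 150 public + 39 private clinics; each clinic opens
  at a uniform random quarter among the first 9 of the 12 quarters (one
  clinic of each type is always open from the start), emulating program
  scale-up; each stratum's patients are split multinomially over the active
  clinic-quarter cells. This yields ≈1,515 nonempty cohorts against the
  survey's 1,518. The real clinic-size distribution is not public; this
  device reproduces the cohort count and realistic cohort sizes, not the
  size distribution itself.
* **Covariates.** Age band from the published margins (11.2% 16–25 … 0.7%
  >65), uniform integer age within band (66–80 for the open top band);
  female (61.0%) and WHO 3/4 (94.3%) drawn per patient with cohort-specific
  probabilities from Beta distributions centered at the marginal with
  concentration 6 — chosen once so that cohort compositions spread across
  the published percent-female and WHO bands (including all-male/all-female
  cohorts) while keeping the marginals; region South (57.9%) assigned per
  clinic; covariates independent given the cohort (no joint distribution is
  published; case-mix confounding by clinic type is therefore absent by
  default).
* **Outcomes.** Bernoulli draws from the patient-level model with the
  published adjusted odds ratios as slopes and the intercept calibrated by
  Brent root-finding so the population-average outcome probability is
  19.5% (±0.001).
* **Randomness.** One root seed; every stochastic step draws from a named
  deterministic sub-stream (clinics, cohort splits, covariates, outcomes by
  replicate), so identical configs give byte-identical tables and power
  replicates redraw outcomes over a fixed covariate realization.

What the generator does **not** emulate: the survey's joint covariate
structure (and hence confounding by case-mix), clinic-size inequality,
within-clinic correlation of outcomes, missing data and measurement error.
Passing tests therefore demonstrate correctness of the estimators and the
qualitative and approximate quantitative behavior of the designs — not
exact reproduction of the survey's coefficient table, which is impossible
without the patient data.

## Power study

Per replicate: outcomes are redrawn over the fixed covariate population,
the phase-I table is rebuilt from the realized outcomes, a phase-II sample
is allocated/drawn/fitted (default estimator: maximum likelihood), and the
two interaction terms are Wald-tested at α = 0.05. Power = rejections /
replicates; replicates whose sampled data cannot support the model (empty
interaction cell, non-convergence) count as non-rejections and are tallied,
which mimics what an analyst would face and is conservative; the run aborts
if they exceed 5%. Default 1,000 replicates; the tests and the acceptance
script use the documented scaled-down default of 200 (Monte-Carlo SE ≈ 3
percentage points at power 80%), with 1,000 kept for the type-I-error
calibration checks and 500 draws for interval-coverage checks — sizes chosen
to make the checks sharp at interactive runtimes.

Under these conditions the complete-data analysis rejects in ≈86–90% of
replicates; the clinic-by-year design keeps ≈83–85% at n = 500; the
clinic-type design reaches ≈75–80% at n = 5,000; case–control needs
n = 10,000 for ≈23%. The design ordering (clinic-by-year > clinic-type >
case–control at matched n) is sharp and stable. These match the published
figures to within a few points; the residual gap is consistent with the
generator's independent-covariate assumption and with the published
two-phase interaction standard errors themselves, which imply power in the
high 70s for the clinic-type design at n = 5,000.

## Known limitations

* Registrants are treated as independent; within-clinic correlation would
  require cluster-aware variances (not implemented — it is untreated in the
  two-phase literature this package follows).
* No Neyman/optimal allocation, raking or calibration estimators; balanced
  allocation only.
* The pseudo-likelihood covariance is asymptotic in the per-stratum counts;
  strata with a single sampled patient contribute no variance term (warned).
* The ecological model fits cohorts independently; no spatial or clinic
  random effects.
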