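# Methods

## The problem

Routine electronic medical records (EMR) from HIV-care programs are an
attractive source for estimating pregnancy incidence among women using
contraception and antiretroviral therapy (ART) concomitantly — in
particular the suspected loss of implant effectiveness under
efavirenz-containing ART — but the recorded exposures (contraceptive
method, ART regimen) and the outcome (incident pregnancy) are
error-prone.  Naive analyses of such data attenuate or distort rate
ratios.  This package implements a three-phase validation-sampling
design and the matching bias-corrected estimator:

1. **Phase 1** — the full EMR cohort, coded into observation periods.
2. **Phase 2** — a stratified random subsample of women whose charts are
   manually reviewed (smaller errors), over-sampling informative cells.
3. **Phase 3** — a priority-ordered subsample of chart-reviewed women
   interviewed by telephone (smallest errors).

The corrected estimator is inverse-probability-weighted Poisson
regression with weights calibrated by generalized raking against the
influence functions of the phase-1 fit, so that the validated subsample
is forced to "look like" the whole cohort in the directions that matter
for the target coefficients.

## Cohort coding

A woman's follow-up runs from her first to her last visit inside the
study window; women with a single visit contribute no person-time.
Observation periods are maximal half-open intervals `[start, end)` (day
resolution, years = days/365.25) over which the contraceptive category,
ART category and pregnancy status are constant; a new exposure value
takes effect on its visit date, the only documented change point.

* **Contraceptive hierarchy** (several methods at one visit): MEC
  (IUD/permanent) > implants > DMPA > OCPs > LEC (condoms/natural).
  Empty record → NONE; unrecognized labels → MISSING (logged).
* **ART categories**: a regimen is ≥3 antiretrovirals; exactly one
  anchor class among {efavirenz, nevirapine, PI} names the category, two
  or more anchors → COMBINATION, three NRTIs alone → NRTI_ONLY, empty →
  NO_ART, 1–2 drugs → MISSING (never assumed NO_ART).  NRTI_ONLY and
  COMBINATION are dropped before model fitting by default
  (configurable); PI is retained.
* **Conception dating** precedence: LMP + 14 days > report date −
  7·(gestational weeks) + 14 days > EDD − 266 days; the result is
  clamped to the report date, and a >30-day disagreement between
  available sources is logged.  Standard obstetric dating; the data
  sources themselves do not dictate a precedence.
* **Censoring**: after each conception the woman is not at risk for 266
  days (38 weeks) from conception (`FIXED_38_WEEKS`), or until the
  recorded pregnancy-outcome date when outcome records exist
  (`OUTCOME_RECORDS`).  Risk time resumes afterwards; women may
  contribute multiple pregnancies.  Pregnancies conceived before the
  administrative study end but reported up to nine months later are
  counted; visits after study end contribute reports only, never
  exposure time.
* **Covariates** are snapshotted from the last visit at or before each
  period start (last observation carried forward per covariate); `age`
  is shifted to the period midpoint and calendar time is continuous.

Person-time is conserved exactly in day arithmetic: risk time plus
censored windows equals the span from first to last visit.

## The model

Log-linear Poisson regression of the per-period pregnancy indicator
with offset log(exposure years):

    log E[Y_ij] = log t_ij + x_ij' β

`x` holds the contraceptive factor (reference NONE, configurable), the
ART factor (reference NVP — "no ART" is not a clinically meaningful
reference), their full interaction (the study question lives in the
interaction), and optionally: program, average age and age², marital
status, education, any-children indicator, WHO stage, CD4 and √CD4,
log BMI and √log BMI, anti-TB treatment, and calendar time.

Estimation is by GLM maximum (pseudo-)likelihood; the variance is the
sandwich A⁻¹BA⁻¹ with B formed from woman-level (cluster-summed,
weighted) scores and a G/(G−1) small-sample factor — periods within a
woman are never treated as independent.  The per-woman influence
functions A⁻¹·score_w sum to ≈0 at the estimate (score identity,
checked to 1e−6) and are the calibration auxiliaries.

Within-stratum adjusted incidence-rate ratios (e.g. efavirenz vs
nevirapine among implant users) are linear contrasts c'β built by
differencing counterfactual design rows, so they remain correct under
any identifiable parameterization; 95% CIs are exp(c'β ± 1.96·√(c'Vc)).

**Sparse cells.** A full 4×4 interaction cannot be identified in a
small validated subsample where some cells are empty, and a cell with
person-time but no events drives its coefficient to −∞ (wrecking the
influence functions).  With `ModelSpec(drop_empty_cells=True)` such
columns — all-zero, zero-event, or collinear (pivoted QR) — are pruned;
a contrast touching a pruned column raises.  The strict default instead
raises a rank-deficiency error naming the empty cell.

## Validation sampling and weights

Women (not periods) are the sampling units, since charts and interviews
are per woman.  Each woman maps to one of 32 cells — contraceptive
{implant, DMPA, MEC, none} × ART {EFV, NVP, PI, no ART} × pregnancy
{0,1} — via her periods; a woman spanning several cells is assigned to
her cohort-rarest candidate cell (ties toward pregnancy cells), keeping
rare exposure–outcome combinations visible to the sampler.  Women whose
exposures never enter the grid form an explicit OTHER stratum with its
own sampling fraction.

Phase 2 samples without replacement within each stratum at configured
targets (fractions are rounded up so no non-empty stratum with a
positive target is left unsampled); `p1` is the realized sampling
fraction.  Phase 3 takes chart-reviewed women in priority order —
pregnant implant users, non-pregnant implant users, pregnant DMPA
users, non-pregnant DMPA users, everyone else — until the budget is
exhausted, restricted to phone-reachable women (a Bernoulli trait in
synthetic data); `p2` is estimated by saturated logistic regression of
interview selection on the priority categories (empirical fractions on
separation), clipped to [1e−3, 1] to bound weights.

Reconciliation takes the interview value over the chart value over the
EMR value for the three validated variables only, except that an ART
answer of "unsure" falls back to the chart; validated observation time
outside the EMR window is trimmed; and the reconciled visits are
re-coded so corrected exposures redefine period boundaries.

## Raking calibration

Base weights are 1/p1 (chart analyses) or 1/(p1·p2) (interview
analyses).  Calibration solves

    Σ_sample w_i h_i = Σ_cohort h_i,  w_i = d_i·exp(η'h_i)

by Newton iteration with backtracking (absolute tolerance 1e−8, max 50
iterations), falling back to the linear (GREG) distance — which can
produce negative weights, logged — on non-convergence.  A constant-1
auxiliary is always appended (weights sum to the cohort size) and
collinear auxiliary columns are dropped by pivoted QR.

The auxiliaries `h_i` are phase-1 influence functions.  Two regimes:

* `aux="all"`: every influence column.  Appropriate when the validated
  sample is large relative to the coefficient count (as in a full-scale
  study with thousands of charts).
* `aux=[contrast…]` (the simulation default): the influence functions
  projected onto the target contrast vectors.  With ~120 validated
  women, calibrating on ~17 columns is routinely infeasible under the
  positive-weight exponential distance, while the 1-D projection is the
  standard efficient auxiliary for a designated parameter and converges
  in a few Newton steps.

## Variance for the weighted fit

Default: the cluster-robust sandwich with calibrated weights treated as
fixed.  It ignores both the variance reduction from calibration and the
finite sampling fractions, so it is somewhat conservative; in the
package's replicate experiments its CIs for the chart-phase raking
estimator cover at ≈96%, inside the nominal band, while the
interview-phase CIs are conservative (≈99%).  An approximate
design-based alternative (`variance="linearized"`: scores residualized
on the auxiliaries, stratified without-replacement variance with
finite-population correction) is provided but not default — with many
sparsely sampled strata, single-unit strata contribute no variance
estimate and it understates the truth.

## Multiple imputation

Covariate missingness is handled by chained equations before any
weighting (p1/p2 depend only on fully observed sampling variables):
continuous variables by predictive-mean matching (k = 5 donors, with a
normal posterior draw of the regression coefficients), categorical
variables by multinomial-logistic draws (lightly ridge-regularized to
survive sparse categories), predictors = contraceptive, ART, pregnancy,
log exposure time, and the other covariates at current values; 10
burn-in cycles; m = 10 independent chains, each deterministically
seeded.  Fits are pooled by Rubin's rules (total variance = within +
(1 + 1/m)·between); pooled influence functions are the across-chain
means.  Exposure categories still MISSING after coding are excluded
from fitting.

## The synthetic-data generator

The generator emulates the EMR's *structure*, not any particular
cohort's numbers: Poisson visit process (default 3 visits/woman/year,
entry uniform over 2011–2015, visits continue nine months past study
end so late conceptions can be reported); exposures switching at visits
with exponential hazards (0.45/yr contraceptive, 0.25/yr ART);
pregnancies from a piecewise-constant intensity with 38-week non-risk
windows, reported at the first subsequent visit with an LMP,
gestational-age, or EDD record (3:1.25:0.75 mix) that back-dates
conception exactly; covariates drawn from simple parametric families
matching routine-EMR marginals (age ≈ N(32.5, 7), CD4 log-normal with
median 428, categorical frequencies per the usual EMR mix), masked
completely at random per woman at per-covariate rates spanning
0.004–0.257; and three degraded copies (EMR, chart, interview) produced
by applying per-phase confusion matrices independently per
constant-exposure spell, with pregnancy sensitivities of 0.92 / 0.98 /
0.995 and an interview-specific "unsure" ART answer (4.5%).

**Scaled-down study conditions.** The default cohort is 2,000 women
(the real design is ~85,000 with ~6% chart review), and the validation
design samples ≈6% of women with heavy over-sampling of pregnant
implant users (50% of pregnant-implant cells), 72 interview slots, 85%
phone reachability.  Two deliberate departures from real-world rates
keep every cell informative at this scale: the baseline rate is 0.10
pregnancies/woman-year, and the contraceptive main effects are
compressed (implant −0.7, DMPA −0.5, MEC −0.9 on the log scale) —
realistic implant failure rates (<1%/yr) would leave the implant×NVP
reference cell with ~1 validated event at n = 2,000 and make every
estimator degenerate.  The efavirenz×implant interaction is log 3.2.
What the generator does **not** emulate: loss to follow-up and
mortality, error dependence across periods or phases, covariate
time-variation within woman, informative (differential)
misclassification, or calibration to any real cohort's printed
estimates.  Passing tests therefore demonstrate the estimator's design
properties — not that any particular clinical estimate is correct.

## Simulation study and its verdicts

`run_study` executes, per replicate: generate → code EMR → phase-1 fit
→ stratify/sample phases 2–3 → reconcile → re-code → seven estimator
paths (naive EMR; unweighted, plain-IPW and raking variants of the
chart and interview analyses).  Replicate i uses seed base+i so single
replicates re-run in isolation; failed estimator runs are recorded with
their error and excluded from aggregates with counts reported (>20%
failures marks the study unreliable).  The aggregate report gives mean
estimate, Monte-Carlo SD, mean SE, CI coverage of the generator truth,
and the raking-vs-IPW variance ratio.

At the default conditions (500 replicates, n = 2,000) the naive EMR
estimate of the implant×EFV interaction is attenuated by ≈0.2 on the
log scale (>10 MC-SEs), the chart-phase raking estimator is unbiased
within Monte-Carlo error with in-band CI coverage, and raking is
1.1–1.3× more efficient than plain IPW.  The acceptance script
(`scripts/acceptance.py`) recomputes exactly these quantities.

## Numerical choices and degenerate inputs

* GLM: IRLS, tolerance 1e−10, max 100 iterations; non-convergence is
  carried on the results object.
* Raking: absolute residual tolerance 1e−8; exponent clipped at ±60
  during iteration; step-halving line search (30 halvings max).
* Duplicate same-day visits: the last record wins.  Unsorted input to
  `segment_periods` raises; `code_cohort` sorts internally.
* A pregnancy re-reported inside a previous pregnancy's censor window is
  treated as the same pregnancy (dropped); conceptions dated before the
  first visit are dropped from risk sets with a logged warning.
* p2 floor 1e−3; strata sampled 0-of-N are excluded from weighted
  analyses with an explicit log line.

## Known limitations

* The interview-phase robust CIs are conservative (coverage ≈99% in the
  default design); the provided linearized alternative is anticonservative
  in sparse strata.  A fully rigorous multiphase calibration variance is
  out of scope.
* The rarest-cell stratum rule and the per-spell independent error model
  are pragmatic choices; real audit errors are likely correlated within
  woman and chart.
* MI for categoricals draws from fitted class probabilities without a
  posterior draw of the multinomial coefficients, slightly
  under-propagating imputation uncertainty for those variables.
* The generator's rates are scaled for desk-size cohorts; its defaults
  are study conditions for method validation, not a calibrated model of
  any real program.
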