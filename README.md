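# threephase

Three-phase validation sampling and generalized-raking IPW Poisson
estimation for error-prone EMR cohorts.

## The problem

Routine electronic medical records (EMR) from HIV-care programs let us
ask whether contraceptive implants lose effectiveness when used
concomitantly with efavirenz-containing ART — but the recorded
contraceptive method, ART regimen, and incident-pregnancy outcome are
error-prone, and naive incidence-rate ratios computed from them are
biased.  A practical remedy is to validate a *subsample* of records
(manual chart review for some women, telephone interviews for fewer
still) and to propagate what the validation teaches back into the full-
cohort estimate.

This package implements that design end to end, for methodologists and
analysts of routine clinical data:

* **Cohort coding** — visit-level records → observation periods with an
  exposure hierarchy (MEC > implant > DMPA > OCP > LEC), ≥3-drug ART
  categorization, conception back-dating (LMP > gestational age > EDD),
  and 38-week pregnancy censoring.
* **Validation sampling** — stratified phase-2 chart sampling over the
  32 contraceptive × ART × pregnancy cells, priority phase-3 interview
  sampling, empirical inclusion probabilities p1 and p2, and
  interview > chart > EMR record reconciliation (ART "unsure" falls
  back to the chart).
* **Estimation** — Poisson models of pregnancy incidence with full
  exposure interactions, offset log person-time, woman-clustered
  sandwich variance, per-woman influence functions, chained-equation
  multiple imputation with Rubin pooling, and inverse-probability
  weights calibrated by **generalized raking** against the phase-1
  influence functions.
* **Simulation** — a synthetic-cohort generator with known truth
  (configurable misclassification per phase, covariate missingness,
  switching exposures) and a replicate-study harness reporting bias,
  SE calibration, CI coverage, and raking-vs-IPW efficiency.

## The estimator

With validated data on a subsample S drawn with known inclusion
probabilities, the corrected fit solves the weighted Poisson score
equations

    Σ_{i∈S} w_i s_i(β) = 0,   w_i = d_i · exp(η' h_i),

where d_i = 1/p1 (chart phase) or 1/(p1·p2) (interview phase) and η is
chosen so the calibrated weights reproduce the full-cohort totals of
the auxiliaries h_i — the influence functions A⁻¹·score_i of the
Poisson fit to the *unvalidated* EMR data, known for every woman.
Under missing-at-random validation sampling this is a consistent
estimate of what full validation would give, and calibration makes it
strictly more efficient than plain IPW.  Within-stratum adjusted
incidence-rate ratios (aIRR) and 95% CIs come from linear contrasts
c'β with the cluster-robust covariance.

## Worked example

Generate a 2,000-woman synthetic cohort whose true implant×EFV
interaction is an aIRR of 3.2, code the error-prone EMR copy, validate
~7% of women by (simulated) chart review, and compare the naive and
raking-corrected estimates:

```python
import threephase as tp
from threephase.model import ModelSpec
from threephase.pipeline import naive_fit, weighted_corrected_fit

truth = tp.TruthConfig(n_women=2000, seed=23)   # true aIRR(implant, EFV vs NVP) = 3.2
study = tp.generate_cohort(truth)
emr = study.emr_cohort()

spec = ModelSpec(drop_empty_cells=True)
phase1 = naive_fit(emr.periods, spec=spec)
print(phase1.irr_contrasts([tp.DEFAULT_CONTRAST]).round(3).to_string(index=False))

design = tp.SamplingDesign.default()
strata = tp.assign_strata(emr.periods)
a2 = tp.sample_phase2(strata, design, seed=1)
a3 = tp.fit_p2_model(tp.sample_phase3(
    a2, design, study.women.set_index("woman_id")["reachable"], seed=2))

chart_ids = set(a2.loc[a2.sampled_phase2, "woman_id"])
cvis = study.chart_visits[study.chart_visits.woman_id.isin(chart_ids)]
chart = tp.code_cohort(tp.reconcile(study.emr_visits, cvis),
                       study_end=truth.study_end)
corrected = weighted_corrected_fit(chart.periods, a3, phase1, spec=spec,
                                   phase="chart", aux=[tp.DEFAULT_CONTRAST])
print(corrected.irr_contrasts([tp.DEFAULT_CONTRAST]).round(3).to_string(index=False))
```

which prints

```
              stratum   contrast  log_irr  se_log_irr   irr  ci_low  ci_high
contraceptive=IMPLANT EFV vs NVP    1.053       0.253 2.865   1.747    4.701
              stratum   contrast  log_irr  se_log_irr   irr  ci_low  ci_high
contraceptive=IMPLANT EFV vs NVP    1.066       0.472 2.905   1.151     7.33
```

Reading the output: the EMR cohort holds 1,968 women and 4,591
women-years; 139 women had their charts "reviewed".  The naive EMR
estimate of the efavirenz-vs-nevirapine pregnancy rate ratio among
implant users is 2.87 (95% CI 1.75–4.70) — attenuated by the 10–15%
exposure misclassification — while the raking-corrected estimate is
2.90 (1.15–7.33), consistent with the true 3.2 at the cost of a wider
CI that honestly reflects validating only 7% of the cohort.  A single
replicate is noisy; `tp.run_study` averages hundreds of replicates and
shows the naive estimator's systematic attenuation (≈0.2 on the log
scale) against the raking estimator's unbiasedness.

A command-line interface mirrors the stages
(`threephase generate|code|sample|estimate|simulate|report`); run any
subcommand with `--help`.

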