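# Methods

## Scope and model

`occohort` implements an external/internal mortality comparison pipeline
for occupational cohorts with a lagged, time-dependent exposure, and two
families of indirect confounding adjustment:

1. **Negative-control-outcome (NCO) adjustment** of internal rate ratios:
   if the exposure does not cause the NCO (negative-control condition) and
   the unmeasured confounder multiplies the NCO's and the outcome's rates
   by the same factor (equi-confounding), then subtracting the NCO's log
   rate ratio from the outcome's removes the confounding.  Both
   assumptions are untestable from the data; when equi-confounding holds
   only approximately the adjustment is partial and the adjusted estimate
   is an indicator of uncontrolled confounding rather than an unbiased
   effect.
2. **Confounding-risk-ratio (CRR) adjustment** of external SMRs:
   `CRR = (P1(RR−1)+1)/(P0(RR−1)+1)` for a binary confounder with cohort
   prevalence P1, reference-population prevalence P0, and confounder →
   disease rate ratio RR; `SMR_adj = SMR/CRR`.  A Monte Carlo sensitivity
   analysis draws (P1, P0, RR) from priors — Beta for prevalences
   (moment-matched), log-normal for the RR (matched to a point estimate
   and 95% interval) — and optionally redraws the SMR from its Poisson
   (gamma) sampling distribution given O, reporting 2.5th/97.5th
   percentiles of the adjusted SMR.  Variances of adjusted log rate
   ratios are the sum of the component variances, treating outcome and
   NCO fits as independent; this is deliberately conservative (the two
   fits share controls, inducing positive covariance that subtraction
   would partially cancel).

## Time scale and person-time

All date arithmetic runs on a leap-aware decimal-year scale
(`year + elapsed_days / days_in_year`).  Calendar-aligned intervals then
have exact integer lengths — one calendar year at 2 ppm is exactly
2.0 ppm-years — and an L-year exposure lag is an exact subtraction, which
keeps lag-window edge cases sharp at daily resolution.  Intervals are
half-open; each worker's follow-up is split at every 5-year age-band
boundary, 5-year calendar-period boundary, and exposure-category
transition date (computed exactly for cumulative exposure, whose running
lagged value is piecewise linear and non-decreasing; on a yearly grid for
average intensity, which is not monotone).  Deaths are assigned to the
cell active at the death date.  Exposure categories are right-closed at
each cutpoint, matching the convention of printed tables ("0–0.09" then
">0.09–0.64"); time before the first lagged exposure, and never-exposed
workers, sit in the baseline category.  Average intensity is defined as
lagged cumulative exposure divided by lagged exposed duration — one of
several possible definitions; the lag on average intensity defaults to
the cumulative-exposure lag and is configurable.

## SMRs and trend tests

Expected deaths use indirect standardization over race × sex × age band ×
period strata.  Confidence limits are exact Poisson (gamma-quantile):
`lower = qgamma(α/2; O)/E` (0 when O = 0), `upper = qgamma(1−α/2; O+1)/E`.
These limits are conservative by construction — their true coverage is at
least the nominal level, e.g. exactly 97.5% at E = 10 for a nominal 95%
interval (the discreteness penalty), which reproduces two-decimal printed
intervals (checked at O = 808).  The cross-category trend test is the
two-sided Wald test of the slope in the Poisson model
`O_k ~ offset(log E_k) + score_k`, with scores defaulting to category
ranks; exposure-midpoint scores can be supplied.  Reported tables apply a
disclosure-suppression rule: any nonzero count below 10 prints as "d.s.".

## Risk sets and conditional likelihood

For each death from the index cause, the risk set contains every cohort
member under follow-up at the case's exact attained age (in days) whose
birth year is within a ±1-year caliper; all eligible controls are used
(no sampling).  A member who later dies of the index cause is a control
in earlier sets but never at or after their own death age; members dying
of other causes remain at risk through their death day.  Exposures are
evaluated at the calendar date each member attains the case's event age,
with the configured lag.  Race, sex, and pay type enter as covariates
rather than matching factors.  Sets with no eligible controls are flagged
and excluded from fitting (their conditional-likelihood contribution is
undefined) and counted in diagnostics.

With one case per set the exact conditional-logistic and Breslow/Cox
partial likelihoods coincide, so no tie approximation is needed.  The
fitter is Newton–Raphson with step-halving from β = 0 on the concave
softmax log-likelihood, converging at gradient sup-norm < 1e-8; variances
come from the inverse observed information.  Terms whose total
within-set variance is below 1e-12 are reported non-identifiable rather
than fitted; non-convergence or |β| > 15 flags separation, reported with
an infinite upper bound.  The two-parameter log-linear-quadratic
dose-response model standardises its columns internally and transforms
the coefficients back; RR(0) = 1 holds by construction.

## The synthetic-cohort generator

The generator emulates a large mid-20th-century multi-plant chemical
cohort: 8 plants, hire years 1942–1990, mortality follow-up through 2011,
per-plant ever-smoking prevalences 0.53–0.78, smoking → lung-cancer rate
ratio 19.1 (and the same for COPD by default — exact equi-confounding),
smoking → bladder 3.5, an optional asbestos-confounded plant
(asbestos → lung 3.5, → mesothelioma 10), cumulative-exposure quintile
cutpoints 0.09/0.64/2.30/12.08 ppm-years lagged 10 years, and
average-intensity cutpoints 0.06/0.14/0.37/1.46 ppm.  Deaths arise from a
yearly discrete-time competing-risks draw: each worker-year's
cause-specific hazards are the baseline (never-smoker, Gompertz-in-age)
rates times the worker's smoking/asbestos/exposure-category multipliers,
a single uniform draw decides death, and the cause is drawn proportional
to the cause-specific hazards.  The reference rate table mixes the
never-smoker baseline with ever-smokers at a 27.1% reference prevalence,
so external SMRs against it are confounded exactly when the cohort's
prevalence differs — making the CRR workflow exercisable with known
truth.

Deliberate design choices, stated once:

- **Null default.**  The true exposure effect defaults to 1.0 in every
  category; confounding scenarios are explicit named constructors.
- **Confounding knobs.**  `confounded_scenario` sets
  P(exposed job | smoker) = 0.9 and scales smokers' job intensities ×3.
  Both knobs are needed: job-assignment mixing alone confounds only the
  exposed/unexposed contrast, while intensity mixing propagates the
  confounding into the continuous dose-response, which is the situation
  the NCO method is meant to repair.  Intensities are log-normal
  (median 0.25 ppm, σ = 0.6 in this scenario); heavier tails leave the
  quadratic dose-response term dominated by a handful of high-leverage
  members at this cohort size.
- **Asbestos plant.**  `asbestos_scenario` flags one plant where asbestos
  co-exposure is far likelier in exposed jobs (0.8 vs 0.1) with a lung
  rate ratio of 3.5 — the magnitude reported for heavily exposed
  shipyard/insulation trades — so excluding the plant measurably lowers
  the exposed lung rate ratio.
- **Event-count enrichment.**  Baseline lung/COPD magnitudes are set so a
  5,000-worker cohort yields roughly 450–500 lung and 350–400 COPD deaths.
  Relative cause mix follows mid-century US industrial cohorts, but the
  absolute levels are enriched for stable risk-set estimation at desk
  scale; matching any real cohort's death counts is a non-goal.  The COPD
  baseline is proportional to the lung baseline (same age slope and
  covariate multipliers) because exact equi-confounding of
  event-time-evaluated exposures requires the two outcomes to share their
  event-age structure.
- **Default scale.**  n = 5,000 workers; larger cohorts are a config
  change, not a code change.

What the generator does **not** emulate: hire-wave demographics, plant
closures, loss to follow-up, misclassified or imputed smoking histories,
multi-segment work histories with re-hire gaps (each worker has at most
one exposure segment), or calendar-period trends in baseline rates.
Passing recovery tests on these cohorts therefore demonstrates the
estimators' correctness under the stated assumptions, not robustness to
the messiness of real cohort files.

## Validation and pipeline conventions

Cohort CSVs are validated row-wise with line-numbered parse errors; more
than 1% bad rows aborts.  Deaths dated after the follow-up end are
recoded to the end date and counted — the standard handling when a
registry returns deaths just past the closing date.  The pipeline is
deterministic given (config, seed): reruns produce byte-identical
bundles, and a manifest (config + seed + version) suffices to regenerate
a bundle.

## Numerical conventions

- Person-years conserve total follow-up to < 1e-6 years on simulated
  cohorts; self-derived rates give an overall SMR of 1 to 1e-9.
- Printed-table comparisons round half-away-from-zero to 2 decimals;
  quantities chained from already-rounded printed inputs are compared
  within ±0.01 (±0.015 where two rounded inputs compound).
- Monte Carlo draws that violate parameter ranges (prevalence outside
  [0,1], RR ≤ 0) are rejected, redrawn, and counted.
- Dose-response curves are compared over the 5th–95th percentile of
  observed at-event exposures; outside the supported range the quadratic
  model is extrapolation and comparisons there are meaningless.

## Known limitations

- The NCO variance treats outcome and NCO estimates as independent;
  a joint fit sharing controls could tighten the intervals.
- The conditional-likelihood fitter handles only single-case sets (the
  builder never produces ties, since each death defines its own set).
- Average-intensity category transitions are located on a yearly grid,
  not exactly.
- The bladder-cancer pathway is lightly exercised in simulation (few
  synthetic bladder deaths at desk scale); its adjustment arithmetic is
  validated on published inputs instead.
- The generator's competing-risks step is yearly; hazards within a year
  are treated as constant, which slightly understates exposure-category
  transitions occurring mid-year of death.
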