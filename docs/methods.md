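# Methods

## The experiment

A large development population stands for the historical cohort a risk model
would be built from.  A Cox proportional-hazards model of time to first CVD
event, with nine predictors (age, systolic blood pressure, BMI,
cholesterol/HDL ratio, smoking status, Townsend deprivation quintile, treated
hypertension, family history of CVD, type 2 diabetes; 13 coefficients after
dummy coding), fitted to the *whole* population, defines each patient's
**population-derived risk** — the reference point for everything else.

For each sample size *N*, the experiment draws *N* patients from the
development population without replacement, fits the same Cox specification,
converts it to 10-year risks for (a) a contemporary cohort that represents
the patients who would be scored in practice and (b) a held-out validation
cohort, and records four performance measures on the validation cohort.
Repeating this *R* times yields a patients × replicates risk matrix.  The
instability measure is the per-patient 5–95th percentile range of the matrix
rows; the decision-relevance measure is the per-patient fraction of replicate
models on the opposite side of the 10% treatment threshold from the
population-derived risk.  Both are summarised within 1%-wide bins of
population-derived risk.

A bootstrap variant draws with replacement from a single cohort (the only
option available in practice, where the overarching population cannot be
resampled).  Its risks are centred on the cohort's own fitted risks rather
than the population-derived risks, but the *spread* is comparable, which is
what the stability assessment needs; the experiment confirms the two
median ranges agree to within a few percent at equal *N*.

## Risk model conventions

* **Fitting.** Cox partial likelihood with Breslow tie handling and the
  matching Breslow baseline cumulative hazard (scikit-survival's Newton
  optimiser).  Design columns are centred at fitting-sample means before the
  baseline is estimated; predictions use the same centring, so risks are
  invariant to the convention.
* **Risk conversion.** `risk = 100·(1 − exp(−H₀(t)·exp(lp)))` at horizon
  t = 10 years, with H₀ the step function evaluated at the largest event time
  ≤ t (no interpolation; flat extrapolation with a warning beyond follow-up).
  Risks are carried on the percent scale end-to-end because every stability
  quantity is an absolute difference in risk, in percentage points.
* **Categorical encoding.** Reference-level dummy coding with the reference
  set to the most prevalent level in the fitting sample (alphabetical
  tie-break).  The two most prevalent Townsend quintiles differ by 0.03
  percentage points in the reference marginals, so the realised reference may
  be either; predicted risks are invariant to this.
* **Kaplan–Meier.** Standard product-limit estimator (lifelines): events at
  t are included in the risk by t, censorings at t leave the risk set after
  t.
* **Harrell's C.** Implemented in-package (numba kernel): a pair is
  comparable iff the strictly earlier observed time is an event; risk ties
  score 0.5; tied times are not comparable.  This exact convention is
  enforced by a brute-force pair-enumeration oracle in the tests, plus a
  cross-check against lifelines on tie-free data.
* **Net benefit.** Survival-adapted decision-curve form: with h patients at
  or above the threshold and q the Kaplan–Meier event risk at the horizon
  *within that group*, NB = (h·q − h·(1−q)·θ/(1−θ))/n.  Kaplan–Meier rather
  than a crude proportion because censoring is present.
* **Fit failures.** Rank deficiency, non-convergence, non-finite
  coefficients, or a sample missing a categorical level (whose model cannot
  score the full cohorts) mark the replicate as failed.  Failures are logged
  and excluded, never retried: retrying would condition on fit success and
  bias the instability estimate.  At the smallest sample sizes (≈20 events on
  13 coefficients) occasional failures are expected and reported in the run
  manifest.

## Stability conventions

* **Percentile range.** Linear interpolation between closest order
  statistics: the q-th percentile of x₍₁₎ ≤ … ≤ x₍ₙ₎ sits at fractional
  position 1 + q(n−1)/100.  The convention matters at small replicate
  counts, which is why it is fixed here.
* **Bins.** Half-open [k, k+1)% by population-derived risk; a patient at
  exactly 10.0% falls in [10, 11).  Empty bins are omitted; summaries report
  per-bin n, median and quartiles of the per-patient ranges.
* **Threshold side.** risk ≥ threshold counts as high-risk (the boundary is
  assigned to treatment, matching statin-eligibility practice); the boundary
  convention is a documented constant, not data-dependent.
* **Performance-conditioned subsets.** Best floor(fraction·R) replicates by
  highest C, smallest |CITL − population CITL|, or smallest MAPE_practical;
  ties broken by replicate id.  Thirds of a replicate count are inexact
  either way; floor is used deterministically.
* **Seeding.** Every replicate's RNG seed derives from (master seed,
  sampling mode, sample size, replicate index), so any single replicate can
  be reproduced in isolation and reruns are byte-identical.  Replicate draws
  are sorted by patient index before fitting, which makes the fitted model
  independent of draw order and makes the full-population draw *exactly*
  reproduce the population model (ranges identically zero) rather than up to
  floating-point summation order.

## The synthetic truth

Real primary-care extracts of this kind are access restricted, so cohorts
are simulated from an explicit proportional-hazards truth:

* **Covariates** match the published marginals of a female CVD
  primary-prevention development cohort: age 43.07 ± 15.94 (truncated to the
  25–85 eligibility window), SBP 123.91 ± 18.28, BMI 25.6 ± 5.60, chol/HDL
  3.72 ± 1.20 (each truncated at ±5 sd), smoking never/ex/current
  56.04/16.97/27.00%, Townsend quintiles 21.96/21.99/21.17/20.46/14.42%,
  treated hypertension 6.18%, family history 15.08%, type 2 diabetes 1.16%.
  Marginals are independent by default (the published table constrains only
  marginals); the contemporary cohort uses the same truth with the published
  shifted marginals (older, heavier, more ex-smokers).
* **True coefficients** are plausible female-CVD log hazard ratios chosen
  once: age 0.115/yr (the dominant predictor), SBP 0.012/mmHg, BMI 0.025,
  chol/HDL 0.15, smoking ex/current 0.25/0.70, Townsend q2–q5
  0.05/0.12/0.20/0.30, treated hypertension 0.45, family history 0.45,
  type 2 diabetes 1.00.  The age coefficient was set so the large-sample
  model's C-statistic lands near 0.87, the regime of the reference cohort.
* **Event times** are exponential (Weibull shape configurable) with
  `H(t|x) = λ₀·t^k·exp(lp(x))`, lp centred at the covariate means.
* **Censoring** is Uniform(0, 14) years (emulating staggered registration,
  mean 7 years) plus an administrative cut at 18 years (inactive under the
  default uniform bound but configurable).
* **Calibration.** λ₀ is solved so the *expected* observed-event proportion
  equals 82 065/1 865 079 ≈ 4.40%: the censoring integral is evaluated in
  closed form (incomplete-gamma for Weibull shapes) and averaged over a
  400,000-draw fixed-seed sample of the linear predictor, then inverted with
  Brent's method.  The frozen default rate is 1.4161×10⁻³/yr; a test asserts
  it matches recalibration.  Realised values at n = 100,000: event
  proportion 4.43%, mean follow-up 6.79 years (target ≈ 7.0).

What the generator does **not** emulate: covariate correlation (an optional
Gaussian copula was considered and dropped — the reference table gives no
correlations to calibrate it to), missing data and imputation, calendar-time
registration dynamics, non-proportional hazards, and measurement error.
Consequently, passing tests show that the *pipeline* behaves as the theory
predicts under a faithful PH truth (monotone √N stability, linear
instability in risk, subset improvements); they do not certify the magnitude
of instability in any particular real cohort, which also depends on features
the generator idealises away.

## Sample-size calculators

* **Events per variable**: required events = EPV·p, cohort size rounded to
  the nearest integer of events/φ (nearest, not ceiling, reproduces the
  standard worked value 2954 for p = 13, φ = 0.0440008).
* **Minimum-sample-size criteria**: (i) expected shrinkage ≥ S:
  n = p/((S−1)·ln(1−R²cs/S)); (ii) small optimism δ in R²: recompute
  S* = R²cs/(R²cs + δ·R²max) with R²max = 1 − exp(2(φ·lnφ + (1−φ)·ln(1−φ)))
  and apply (i) with max(S, S*); (iii) precise overall risk:
  n = (1.96/δ_risk)²·φ(1−φ).  Each is rounded up; the overall minimum is
  their maximum.  All inputs are user-supplied (defaults S = 0.9,
  R²cs = 0.05, δ = 0.05, δ_risk = 0.05); with those defaults and φ = 4.40%
  the binding criterion is shrinkage, n = 2275.  A person-time variant of
  criterion (iii) (delta-method bound on the 10-year cumulative incidence
  from an exponential rate over the anticipated person-time) is available
  behind a flag; the proportion forms are the defaults.

## Problem sizes

The shipped experiment runs at desk scale: a 50,000-patient development
population (validation 5,000 carved out of 55,000 before the development
cohort is formed), a 5,000-patient contemporary cohort, 200 replicates, and
N ∈ {500, 2000, 8000}.  These sizes preserve every qualitative conclusion —
the √N scaling of the median percentile range (ratios ≈ 2.3 per 4× step),
the through-origin linearity of median range in population-derived risk
(R² > 0.99), the strict improvement from keeping the best-MAPE third of
models, and the concentration of threshold-crossing probability in the bins
adjacent to 10% — while a full-size run (10⁶-patient population, 1000
replicates, N up to 100,000) is a configuration change, not a code change.

## Known limitations

* Performance-conditioned subsetting uses the validation cohort's metrics;
  with a 5,000-patient validation cohort the metric estimates are themselves
  noisy, which attenuates (but does not remove) the stability gain from
  subsetting.
* The calibration-in-the-large of a well-specified synthetic truth is near
  zero by construction; miscalibration patterns seen with real cohorts
  (where Kaplan–Meier and Cox censoring assumptions disagree) are not
  reproduced.
* At N ≈ 500 (≈22 events on 13 coefficients) some replicate fits produce
  extreme but finite coefficients; these are genuine manifestations of the
  instability under study and are retained, while outright failures are
  excluded and counted.
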