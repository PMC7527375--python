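# Methods

This note documents the models, defaults and design choices behind
`retiscreen`, in the spirit of a statistical-methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Problem and outcome definition

Three screening strategies for diabetic retinopathy in type 2 diabetes are
replayed over a longitudinal cohort with (roughly) annual care visits:

* **annual** — screen every 12 months;
* **Dutch guideline** — 24 months after a retinopathy-free screen, 36 months
  after two consecutive retinopathy-free screens, 12 months for mild
  retinopathy (EURODIAB grades 1–2);
* **personalised** — the interval at which the individual's modelled
  cumulative STR risk reaches a preset risk margin ε, clamped to 6–60 months.

All strategies refer at an observed grade ≥ 3 (sight-threatening
retinopathy, STR). The health outcome is the number of **delayed STR
diagnoses**; the economic outcome is discounted screening cost, from a
healthcare perspective (screening cost only) or a societal perspective
(adding travel cost and productivity loss per screen).

### Delayed-diagnosis semantics

Replaying a strategy over *recorded* cohort data means the patient's disease
course is fixed; only the screening calendar changes. Two quantities are
therefore computed separately:

1. **Schedule replay** (screen counts, costs): screens are scheduled
   iteratively from t = 0, next screen = current time + the policy's
   interval, truncated at end of follow-up, stopping at referral. The grade
   and covariates a screen observes are carried forward from the latest
   visit at or before it (LOCF).
2. **Delay** (clinical outcome): at the *last visit before onset with an
   observed retinopathy grade* — the last assessment that could have
   informed the policy — the policy assigns interval `I`; the delay is
   `max(0, I − (onset − anchor))`.

The anchored definition was chosen over "time from the replayed schedule's
own last screen to the next screen" because it preserves, as theorems rather
than tendencies, the structural facts a screening evaluation on annually
observed data must satisfy:

* annual screening is never delayed (its interval equals the visit spacing);
* no delay can exceed `max_interval − visit_spacing` = 48 months;
* the delayed count is monotone non-decreasing in the risk margin (the
  assigned interval is monotone in ε at a fixed anchor);
* the fast-progression scenario dominates the slow one patient-by-patient,
  because both scenarios share the same anchor assessment and fast onset ≤
  slow onset.

Onsets exactly at a scheduled screen count as detected on time. A delay may
extend past follow-up end (the model would have scheduled the next screen
beyond the observation window); it is still reported in full.

## 2. The personalised risk model

Weibull proportional hazards on time to STR (months):
`F(t|x) = 1 − exp(−exp(βᵀx)·t^p)`, inverted analytically at margin ε and
clamped to [6, 60] months, then floored to whole months. Patient-level
rounding is floor (conservative: never later than the exact solution); an
optional `snap_to_menu` discretises to {6, 12, 24, 36, 48, 60} and is off by
default. "Retinopathy present" means the most recent non-missing grade is 1
or 2. HbA1c (mmol/mol) is used rather than mean glucose.

The shipped coefficients (`configs/risk_model.yaml`, mirrored in
`risk_model.DEFAULT_COEFFICIENTS`) are a calibration chosen by this package,
not a transcription of any published fit: shape p = 1.6, intercept −23.0,
male +0.15, log-duration +0.35, log-HbA1c +1.8, log-SBP +1.3, retinopathy
+1.2. The calibration reproduces the published structure of such models: a
typical profile (HbA1c 56 mmol/mol, SBP 143 mmHg, short duration, no
retinopathy) gets ≈ 26 months at ε = 2.0%; the lowest-risk profiles exceed
the 60-month cap at ε = 4.0%; extreme high-risk profiles fall below the
6-month floor. Everything in the package except the two clamp checks is
coefficient-agnostic (monotonicity, inversion consistency, oracle
equivalence), so replacing the config with another transcription leaves the
machinery valid.

## 3. Missing data

Applied in this order (the order is a package choice; covariate strata are
better populated after grades are interpolated):

1. **Grade interpolation** (within patient): an internal run of missing
   grades flanked by equal observed sub-STR grades is filled with that
   grade; differing flanks are filled by independent draws from a continuous
   uniform between the two flanking grades, rounded half-away-from-zero (for
   flanks (0, 2): P(0) = P(2) = ¼, P(1) = ½). Gaps ending in an STR grade
   are left missing — they carry the onset uncertainty. Leading/trailing
   missing grades are not interpolated; baseline is the earliest visit with
   an observed grade. Grades missing after onset are irrelevant to outcomes
   and stay missing.
2. **Onset scenarios**: for each STR case, *fast* progression puts onset at
   the first missing-grade visit after the last observed sub-STR grade;
   *slow* at the first visit with an observed STR grade. No gap ⇒ both equal
   the observed STR visit. Fast ≤ slow by construction.
3. **Covariate imputation**: missing HbA1c/SBP/duration become the
   cohort-wide mean conditional on the visit's grade; an empty stratum falls
   back to the overall mean with a warning.

All stochastic fills derive from one master seed through per-patient
substreams (CRC32 of the patient id), so subsetting a cohort does not change
any patient's imputed values.

## 4. Synthetic cohort generator

The generator emulates a dynamic primary-care type 2 diabetes cohort and is
the package's test bed; its defaults are fixed study conditions, not tuning
knobs:

* n = 5,000 patients by default (≈ the scale of the motivating cohorts);
  follow-up uniform over 0–18 years; visits every 12 months from entry.
  Calendar entry dates are not materialised — the analysis is entirely in
  time-from-entry.
* baseline grade mix 93.8 / 5.1 / 1.1 % (grades 0/1/2); grade-stratified
  baseline covariates: HbA1c N(55.7, 17.1²)/N(60.9, 19.7²)/N(70.4, 19.4²)
  mmol/mol, SBP N(142.5, 20.1²)/N(145.2, 22.3²)/N(149.1, 20.5²) mmHg, age
  N(60.3, 10.8²)/N(61.2, 10.8²)/N(60.0, 9.9²) years, diabetes duration
  log-normal matched to median (IQR) 0.8 (0.2–2.9) / 2.11 (0.3–7.1) /
  5.8 (1.5–13.6) years; 53.9% male.
* **STR onset** is drawn from exactly the Weibull model evaluated at
  baseline covariates — with a weaker baseline hazard than the screening
  model (intercept −25 vs −23). The gap is deliberate and mirrors the
  setting the package targets: a well-controlled cohort whose realised STR
  incidence (≈ 2.8–3.5% of patients over follow-up, ≈ 155 STR cases among
  5,514 analysable patients) is far below the screening model's calibration,
  so the model errs toward frequent screening. Because the generating hazard
  is exact, the scale parameter is recoverable in closed form
  (`fit_onset_scale`); the suite demands recovery within ±10% at n = 20,000.
* **Sub-STR grades** drift upward (never downward) as a Markov chain: step
  probability 0.025·exp(0.5·z_HbA1c + 0.3·z_SBP) per visit, clipped to
  [0.002, 0.3], rising to 0.5 per visit over the three visits before onset so
  that severe retinopathy usually develops through the milder grades —
  without the ramp, most synthetic STR cases would jump 0 → 3, which real
  EURODIAB trajectories do not. After onset, grades step 3 → 4 → 5 with
  probability 0.15 per visit.
* **Covariates at visits** follow a random walk around baseline (SD 1.5
  mmol/mol and 3 mmHg per annual step); duration grows deterministically.
* **Missingness** is MCAR within strata, applied after complete data are
  kept in a hidden truth channel: 12.2% of sub-STR grade records; for 22% of
  STR cases, 1–2 grades from the onset visit onwards (creating the gap the
  fast/slow scenarios bracket, while always leaving one observed STR visit);
  1.7% / 2.0% / 1.0% of HbA1c / SBP / duration records.

What the generator does **not** emulate: irregular real-world visit spacing
and dropout patterns (visits are exactly annual; exit is uniform),
per-eye grades, calendar effects, screening non-attendance, and any
correlation between missingness and disease state (MCAR within strata).
Passing tests therefore demonstrate the machinery's correctness and the
structural properties of the strategies, not the reproduction of any real
cohort's point estimates.

## 5. Selection filters

In order, attributing each exclusion to the first failing criterion:
(1) at least one observed retinopathy grade; (2) no STR at baseline
(baseline = earliest visit with an observed grade; patients whose first
observed grade is ≥ 3 are excluded here); (3) follow-up ≥ 60 months, the
maximum personalised interval. Retained + excluded always equals the input
count, and the filter is idempotent.

## 6. Health economics

* Cost categories per screen (euros, 2015): screening 15.25–41.07, travel
  1.58–14.19, productivity loss 2.63–16.62. Healthcare perspective uses
  screening only; societal adds the other two.
* **Gamma fits**: "fitted to the minimum and maximum" is interpreted as
  matching the 2.5%/97.5% quantiles (solved by bracketed root-finding on the
  shape; the quantile ratio is strictly monotone in the shape). A
  moment-matching alternative (mean = midpoint, SD = range/4) sits behind
  `gamma_fit="moment"`.
* **Discounting**: costs at 4.0%/year, applied per screen at its scheduled
  month. Effects (delayed-diagnosis counts) are reported undiscounted by
  default — counts are integers out of the STR caseload; a 1.5%/year
  discounted-effect variant exists behind `discount_effects=True`.
* **Best risk margin**: over the 0.0–4.0% grid (step 0.1%), each step's
  incremental saving per extra delayed case is computed; plateau steps
  (no new delayed cases) carry their savings forward so ratios stay
  well-defined. The optimum is the peak ratio; ties break toward the lowest
  delayed count, then the lowest margin. A flat delayed curve raises
  `NoOptimumError` (inside the bootstrap this falls back to the largest,
  cheapest margin, since no marginal harm was observed in that resample).
* **Two-stage bootstrap** (B = 1000 by default; tests use B = 100–200 on
  cohorts of a few hundred patients to keep the suite fast): stage 1
  resamples patients and records each resample's best margin
  (healthcare-perspective point costs — the main cost analysis); stage 2
  fixes the grid margin nearest the stage-1 mean and resamples patients
  *and* unit costs (one gamma draw per category per iteration), yielding
  total-cost and delayed-count draws for all three strategies and both
  perspectives. Percentile (2.5%, 97.5%) intervals throughout; no BCa.
* **ICER** ("saving per delayed STR diagnosis"): summarised as the mean of
  per-draw ratios, excluding draws with a zero delayed increment; the ratio
  of means is reported alongside. Saving per patient-year divides by the
  resample's undiscounted follow-up years.
* **CEAC**: acceptance probability at threshold λ is the fraction of draws
  with net benefit λ·(−Δdelayed) − Δcost > 0, with Δ taken strategy minus
  comparator and a delayed diagnosis avoided as the unit of effect.
* Randomness: one master seed, split into named substreams (stage-1
  resampling, stage-2 resampling, cost draws), so results are bit-identical
  under a fixed seed and stages are independently reproducible.

## 7. Numerical choices and degenerate inputs

* Intervals are computed in exact arithmetic then floored; the clamp is
  applied before flooring, so the floor never pushes below 6 months.
* Gamma-fit bracketing expands adaptively; shapes up to ~10¹² (near-
  degenerate ranges) are solved to 1e-6 relative quantile error.
* A zero risk margin yields interval 0 before clamping → the 6-month floor.
* Cohorts with zero STR cases report a delayed fraction of `None` rather
  than 0/0.
* Visit times are integer months, strictly increasing per patient;
  duplicate (patient, time) pairs and out-of-range grades are validation
  errors listing every offence with its CSV line number.

## 8. Known limitations

* The delayed-diagnosis anchor assumes at least one assessed visit before
  onset; this is guaranteed by the baseline-STR exclusion but would need
  revisiting for cohorts with sparse early grading.
* QALYs, treatment costs and pathways after referral, and attendance
  behaviour under variable intervals are out of scope.
* The synthetic generator's sub-STR grade dynamics and covariate walks are
  package choices anchored only to baseline cross-sections; cross-sectional
  grade prevalence at later times is not calibrated to any external data.
* The best-margin rule is sensitive to where the first delayed case appears
  on the grid (plateau savings accumulate into the first positive step); on
  cohorts where the screening model is much more cautious than the true
  hazard, the optimum can sit at stricter margins than intuition suggests.
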