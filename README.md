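# retiscreen

Cost-effectiveness simulation of diabetic retinopathy screening strategies
for people with type 2 diabetes, built for health-economics and screening
researchers who want to compare **personalised risk-based screening
intervals** against **fixed annual screening** and the **stratified Dutch
guideline** (1–3 years by previous retinopathy grade) on longitudinal cohort
data — or on synthetic cohorts with the same statistical structure when
patient-level data are unavailable.

## The model

Retinopathy severity follows the EURODIAB grading scale 0–5; grades 3–5 are
sight-threatening retinopathy (STR), the referral threshold. Time to STR is
modelled with a Weibull proportional-hazards cumulative incidence

```
F(t | x) = 1 − exp(−exp(βᵀx) · t^p),     t in months,
```

where `x` holds sex, log diabetes duration, log HbA1c, log systolic blood
pressure, and an indicator for present (sub-STR) retinopathy. Given a preset
**risk margin** ε — the accepted probability of developing STR before the
next screen — the personalised interval is the analytic inversion

```
t*(ε | x) = ( −ln(1 − ε) / exp(βᵀx) )^(1/p),
```

clamped to 6–60 months. The simulator replays each strategy over a patient's
visit history (schedule, screen counts, discounted costs at 4%/year) and
counts **delayed STR diagnoses**: at the last assessed visit before STR
onset the strategy assigns an interval; the diagnosis is delayed by
`max(0, interval − (onset − visit))` months. Missing grades are interpolated
between observed flanking grades; onset inside a run of missing grades is
bracketed by *fast* (first possible time point) and *slow* (last possible)
progression scenarios. Cost uncertainty uses gamma distributions fitted to
(min, max) cost ranges via their 2.5%/97.5% quantiles; a two-stage bootstrap
optimises the risk margin and produces cost-effectiveness planes, percentile
confidence intervals, and cost-effectiveness acceptability curves (CEACs).

## Worked example

```python
from retiscreen import (CohortGenConfig, generate_cohort, select_analysis_cohort,
                        apply_scenario, make_policy, simulate_cohort,
                        RiskModelParams, bootstrap_two_stage, EconParams)
from retiscreen.imputation import ImputationScenario

cohort = generate_cohort(CohortGenConfig(n_patients=5000, seed=0))
kept, counts = select_analysis_cohort(cohort.patients)
print(f"retained {counts.retained} of {counts.total_input} patients "
      f"(excluded: {counts.no_grade} no grade, {counts.baseline_str} baseline STR, "
      f"{counts.short_follow_up} short follow-up)")
imputed, onsets = apply_scenario(kept, ImputationScenario("fast", 0))
params = RiskModelParams()
for name in ("annual", "guideline", "personalised"):
    _, s = simulate_cohort(imputed, onsets, make_policy(name, 0.02, params))
    print(f"{name:13s} delayed {s.delayed_count:3d} / {s.str_cases} STR cases "
          f"({s.delayed_pct_of_str or 0:.1f}%), {s.total_screens} screens")
res = bootstrap_two_stage(imputed, onsets, B=200, econ=EconParams(), params=params, seed=1)
print(f"best risk margin: {res.best_margin_mean*100:.2f}% "
      f"(95% CI {res.best_margin_ci[0]*100:.1f}-{res.best_margin_ci[1]*100:.1f}%)")
row = res.table.query("item == 'saving_per_patient_year_personalised_vs_annual'"
                      " and perspective == 'healthcare'").iloc[0]
print(f"saving/patient-year, personalised vs annual (healthcare): "
      f"EUR {row['mean']:.1f} (95% CI {row['ci_2.5']:.1f}-{row['ci_97.5']:.1f})")
```

prints (exact output of this script):

```
retained 3608 of 5000 patients (excluded: 46 no grade, 2 baseline STR, 1344 short follow-up)
annual        delayed   0 / 157 STR cases (0.0%), 42530 screens
guideline     delayed  15 / 157 STR cases (9.6%), 21414 screens
personalised  delayed  18 / 157 STR cases (11.5%), 34182 screens
best risk margin: 0.76% (95% CI 0.4-1.3%)
saving/patient-year, personalised vs annual (healthcare): EUR -5.0 (95% CI -7.6--3.2)
```

Reading the output: annual screening detects every STR case at the visit of
onset (zero delay, by construction), at the price of ~2× the screens of the
guideline. At a 2.0% risk margin the personalised strategy delays 18 of 157
STR cases (11.5%), all by at most 48 months. The bootstrap then optimises the
margin per resample; on this synthetic cohort the incremental saving per
delayed case peaks at a stricter margin (~0.8%) than 2.0%, where the
personalised schedule is denser — and therefore more expensive — than annual
screening (negative saving per patient-year). Cost-effectiveness planes and
CEAC curves live in `res.increments` and `res.ceac_curves`.

The same pipeline is scriptable from the shell:

```
retiscreen run-all --n-patients 5000 --scenarios fast,slow \
    --bootstrap 1000 --seed 0 --out results/run
```

which writes `margin_grid.csv`, `table2.csv`, `ce_plane.csv`, `ceac.csv` and
a checksummed run manifest per scenario.

## Layout

| module | role |
| --- | --- |
| `retiscreen.synthetic_cohort` | cohort generator with known STR hazard + hidden truth channel |
| `retiscreen.cohort_io` | long-CSV round-trip, validation, study selection filters |
| `retiscreen.imputation` | grade interpolation, fast/slow onset scenarios, covariate means |
| `retiscreen.risk_model` | Weibull cumulative incidence and interval inversion |
| `retiscreen.strategies` | annual / Dutch-guideline / personalised policies |
| `retiscreen.screening_sim` | schedule replay, delayed-diagnosis accounting |
| `retiscreen.health_econ` | discounting, gamma PSA, margin optimisation, bootstrap, CEAC |
| `retiscreen.cli` | `retiscreen` command with generate/select/impute/simulate/cea/run-all |

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
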