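# cookfield

Questionnaire-based exposure assessment for the intermediate-frequency (IF)
magnetic fields that household induction cookers generate.

Epidemiological studies of IF exposure (300 Hz – 10 MHz) stall on a
practical problem: measuring the field in every participant's kitchen is
infeasible, so exposure must be estimated from things people can answer on a
questionnaire. `cookfield` implements, as a tested and reusable pipeline, a
two-phase workflow for doing exactly that:

1. **Phase 1 — model building.** Flux density *B* (μT) is measured on a
   canonical 20-point grid around each household's cooker (heights
   *h* ∈ {−20, −10, 0, 10, 20} cm relative to the cooktop, horizontal
   distances *d* ∈ {0, 10, 20, 30} cm from its edge). Treating the cooker as
   a magnetic dipole at the hob center, four nested decay models are fitted
   by least squares and ranked by AIC:

       B = (β₁ μ √W + β₂ (φc/2)² + ε) / (4π r³),   r = √(dh² + h²)

   with *W* the rated wattage (√W standing in for the coil current),
   φc the cookware diameter (its squared radius tracking the loaded area of
   the pot bottom), dh the horizontal distance from the hob center, and
   μ = 1.257 × 10⁻⁶. Model 1 uses all terms; model 2 drops β₂, model 3 drops
   β₁, model 4 keeps only ε — the fallback when a questionnaire reports
   nothing but a distance.

2. **Phase 2 — validation.** Exposure is estimated for surveyed subjects
   from stature (converted to iliac-crest height above the cooking table via
   a fixed linear formula), self-reported distance, cookware diameter and
   wattage, then compared with paired spot measurements by Spearman rank
   correlation with Fisher-z confidence intervals; models are compared
   against each other with Steiger's dependent-correlation z-test.

Because no raw campaign data are publicly deposited, the package ships a
synthetic-data module that reproduces the statistical structure of both
phases (wattage spread vs. 3 kW bias, hob-offset / table-height / positional
distributions, multiplicative lognormal measurement noise), so the whole
pipeline runs end to end out of the box. The published 20-cell campaign
summary table and the published coefficient table are packaged as reference
data.

## Worked example

```python
from cookfield import (SimulationConfig, build_design, fit_all_models,
                       load_default_coefficients, validate_survey)
from cookfield.synthetic_data import (generate_grid_campaign,
                                      generate_households,
                                      generate_phase2_survey)

truth = load_default_coefficients()[1]          # published full-model fit
devices = generate_households(45, phase=1, seed=1)
grid = generate_grid_campaign(devices, truth, noise_gsd=1.8, seed=2)
fits = fit_all_models(build_design(grid, devices), loss_scale="log")
for c in fits:
    print(f"model {c.model_id}: AIC={c.aic:8.1f}  "
          + "  ".join(f"{t}={getattr(c, t):.3g}" for t in c.terms))

survey = generate_phase2_survey(30, truth, noise_gsd=1.8, seed=3)
report = validate_survey(survey, {c.model_id: c for c in fits})
for r in report.results:
    print(f"model {r.model_id}: rho={r.rho:.3f} "
          f"(95% CI {r.ci_low:.3f}-{r.ci_high:.3f}) p={r.p_value:.2g}")
```

prints

```
model 1: AIC=  1607.7  beta1=9.74e+03  beta2=-29.9  epsilon=0.222
model 3: AIC=  1704.6  beta2=-29.2  epsilon=0.782
model 2: AIC=  1803.1  beta1=9.41e+03  epsilon=-0.109
model 4: AIC=  1853.2  epsilon=0.441
model 1: rho=0.814 (95% CI 0.641-0.908) p=4.6e-08
model 2: rho=0.766 (95% CI 0.560-0.882) p=8.3e-07
model 3: rho=0.799 (95% CI 0.616-0.900) p=1.2e-07
model 4: rho=0.762 (95% CI 0.553-0.880) p=1e-06
```

Reading this: a 45-household synthetic campaign was generated from the
reference full-model coefficients (β₁ = 10501.2, β₂ = −28.8, ε = 0.173)
with multiplicative noise of geometric SD 1.8. Fitting all four models on
the log scale recovers coefficients near truth and ranks the generating
model first by AIC (ΔAIC ≈ 97 to the runner-up). A 30-subject synthetic
validation survey then yields Spearman correlations around 0.8 between
questionnaire-based estimates and the paired measurements, with the four
models statistically indistinguishable from one another — the qualitative
pattern expected when the validation population's wattage is biased toward
a single level.

The same workflow is available from the shell:

```sh
cookfield run --seed 1 --out results/demo          # simulate -> fit -> validate
cookfield simulate --seed 1 --out data/
cookfield fit data/phase1_grid.csv --out fit.csv
cookfield validate data/phase2_survey.csv --out results/
```

## Limitations

The models describe instantaneous exposure at a fixed cooking position;
time-integrated exposure over cooking sessions, other IF sources, and
coil-level (Biot–Savart) field computation are out of scope. See
`docs/methods.md` for the full model description, generator calibration and
numerical choices.
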