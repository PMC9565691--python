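# Methods

## The exposure model

An induction cooker heats ferrous cookware with an intermediate-frequency
(roughly 20–75 kHz) magnetic field. At distances of tens of centimeters the
device is well approximated as a magnetic dipole at the hob center, so flux
density decays with the inverse cube of distance. The package's four nested
models share the form

    B(q) = N(q) / (4 π r³),        r = √(dh² + h²)

with the numerator N — an effective dipole strength in μT·m³ — built from
questionnaire-available covariates:

    model 1:  N = β₁ μ √W + β₂ (φc/2)² + ε
    model 2:  N = β₁ μ √W + ε
    model 3:  N = β₂ (φc/2)² + ε
    model 4:  N = ε

| symbol | meaning | units | default / notes |
|---|---|---|---|
| W  | rated maximum output | W | √W proxies the coil current (P = I²R) |
| φc | cookware diameter | m | (φc/2)² tracks the loaded pot-bottom area |
| dh | horizontal distance from hob center | m | grid distances are edge-referenced and shifted by the hob offset |
| h  | height above the cooking-table plane | m | iliac-crest height − table height |
| μ  | permeability constant | — | 1.257 × 10⁻⁶, kept at the printed precision of the reference calibration (not free-space 4π × 10⁻⁷) for coefficient compatibility; configurable |

Geometry conventions: the cooktop surface is h = 0; the cooktop edge is
d = 0 for grids, and hob-center distance = edge distance + hob offset
(default 0.239 m, the campaign mean). Subjects' h comes from stature via the
fixed linear conversion

    iliac crest [m] = (stature [cm] × 0.6935 − 16.997) / 100,

evaluated against the standard 0.85 m table by default (measured tables
averaged 0.8504 m; the default reproduces the reference estimator, and a
per-household override supports sensitivity analysis). The conversion
constants are treated as fixed calibration inputs and never refitted.

Negative predictions are possible for models 1 and 3 (β₂ < 0) with large
cookware. `predict` returns the raw value because fitting needs unfloored
residuals; `estimate_from_questionnaire` floors reported exposures at zero
with a warning, which is the physically meaningful output for epidemiology.

Questionnaire estimation prefers the lowest-numbered (most-adjusted) model
whose covariates are all answered, falling back to the geometry-only
model 4; self-reported hob-center distance is preferred over edge distance
plus the default offset when both are present.

## Fitting and model selection

Each grid reading is one design row. Every model is linear in its
coefficients given the data, but fitting still runs through iterative
Levenberg–Marquardt least squares (`scipy.optimize.least_squares`, analytic
Jacobian, cost tolerance 1e-10, ≤10⁴ evaluations) so that both loss scales
share one code path. Starting values: the leading coefficient from a
one-term pre-fit, remaining terms at zero; the geometry-only model starts
from the robust median ratio so its iterative path stays independent of the
least-squares closed form used as a test oracle.

Inference uses standard nonlinear-least-squares asymptotics: covariance
s² (JᵀJ)⁻¹ with s² = RSS/(n−k), t = coefficient/SE with n−k degrees of
freedom, two-sided p. Models are ranked by Gaussian-likelihood AIC,

    AIC = n (ln(2π RSS/n) + 1) + 2 (k + 1),

counting the error variance as a parameter and keeping the Gaussian
constant; only AIC differences matter for ranking, and the convention is
stated so other conventions can be reconciled by a constant shift.

Two loss scales are exposed:

* `natural` (default): squared residuals in μT, mirroring the original
  campaign analysis;
* `log`: squared log-residuals. Campaign summaries show stable geometric
  SDs across cells, i.e. multiplicative error, under which the log-scale
  fit is the maximum-likelihood estimator. The simulation-based test
  batteries (coefficient recovery, AIC selection) use the log scale because
  the synthetic noise is lognormal with median 1: its *mean* is
  e^{σ²/2} ≈ 1.19 at GSD 1.8, so a natural-scale fit converges to ≈1.19×
  the generating coefficients by construction, on top of strong
  heteroscedasticity.

AIC values are comparable only within one loss scale.

## Validation statistics

Estimates are meant to rank subjects, so validity is Spearman's ρ against
paired measurements (average ranks for ties; t-approximation p-value). The
95% CI uses the Fisher z transform, z ± z₀.₉₇₅/√(n−3), back-transformed.
Two models validated against the *same* measured vector are compared with
Steiger's z-test for dependent correlations, using the rank correlation
between the two estimate vectors as the coupling term. Both constructions
are the standard defaults for this situation; neither is uniquely mandated,
and alternatives (e.g. bootstrap CIs) would be drop-in replacements.

A two-sided variance-ratio F-test (larger variance over smaller, doubled
tail probability) compares wattage spread between the model-building and
validation populations — the mechanism proposed for why the four models
validate similarly when the validation population clusters at 3 kW. A
threshold flag marks readings above the 27.0 μT public reference level for
3 kHz–10 MHz.

## Synthetic data: what it emulates, what it does not

The generators encode the study conditions of the two campaign phases:

| quantity | distribution | source of the value |
|---|---|---|
| phase-1 wattage | uniform on {1.5, 2, 2.5, 3} kW | model-building sampling spread over the catalogue range |
| phase-2 wattage | 3 kW w.p. 0.8, else uniform on the rest | validation population's 3 kW bias (phase-2 variance is strictly smaller) |
| hob offset | Normal(0.239, 0.0338) m, redrawn > 0.10 | campaign mean (SD) |
| table height | Normal(0.8504, 0.0089) m | campaign mean (SD) |
| cookware diameter | uniform [0.14, 0.28] m | population-plausible choice (not campaign-printed) |
| stature | Normal(158.3, 5.5) cm | campaign mean; SD population-plausible |
| edge distance | Normal(15.00, 11.19) cm, redrawn ≥ 0 | campaign mean (SD) |
| measurement noise | × LogNormal(0, ln GSD), GSD 1.8 default | mid-range of the per-cell campaign GSDs (1.64–3.27) |
| detection floor | 0.001 μT | keeps log transforms defined; below every realistic reading |

Noise is multiplicative (the model value is the geometric mean of the
measurement distribution), matching the GM/GSD structure of the reference
summary table; truncations are by redrawing, not clipping. All parameters
live in `SimulationConfig` and every generator draws from a single seeded
`numpy` Generator, so a seed fixes the entire dataset.

What the generators deliberately do **not** emulate: within- vs
between-device error (no repeat measurements exist to calibrate a split, so
a single noise term is used), device-model heterogeneity beyond wattage
(inverter voltage differences), non-lognormal outliers, spectral content,
and movement during cooking. Passing closed-loop tests therefore
demonstrates the pipeline's internal consistency and statistical behaviour
under the assumed error structure — not the field validity of the dipole
approximation itself, which only the real campaigns speak to.

Per-cell geometric SDs of a large default-settings campaign land in
[1.3, 4.0]: the measurement GSD of 1.8 composed with between-device
numerator spread brackets the reference table's 1.64–3.27 range.

## Numerical choices and degenerate inputs

* Quantiles use the linear-interpolation (type-7) rule; the packaged
  reference summary is stored as printed, never recomputed, so the rule
  affects only synthetic summaries.
* Cells containing a zero reading report NaN GM/GSD with a warning rather
  than failing the whole summary.
* A query at the hob center (dh = h = 0) is a singularity error; negative
  distances are domain errors; a model asked to predict without its
  covariates raises a missing-variable error naming the requirement.
* Fits with n ≤ k rows, non-convergence, or a Jacobian condition number
  above 1e14 raise fitting errors; `fit_all_models` skips a failing model
  with a warning and ranks the rest.
* RSS = 0 yields AIC = −∞ with a warning (noiseless closed loops hit this
  legitimately).
* Spearman ρ = ±1 collapses the Fisher-z interval to the point itself
  (atanh diverges); constant vectors are undefined-correlation errors.

## Problem sizes

Simulation-based tests use the study-condition sizes throughout: 45
households × 20 grid points (n = 900) per campaign and 30 subjects per
validation survey, with 100 seeded replicates for the recovery/selection
batteries and 40 for the median-unbiasedness check — enough replication to
make the checked proportions stable at the asserted bounds.

## Known limitations

* The intercept-like term ε is weakly identified at campaign scale: its
  fitted relative SE is ~40% even under ideal lognormal noise (the
  reference fit itself reports t = 0.875 for ε). Downstream predictions are
  barely affected, but ε itself should not be interpreted tightly.
* AIC ranking across loss scales is undefined; choose the scale first.
* The anthropometric conversion is calibrated for adult women of the study
  population; applying it elsewhere requires re-deriving the constants.
* Exposure is instantaneous and positional; no cooking-duration weighting.
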