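# Methods

## Problem and model

`adipocut` implements a sex-stratified validity analysis of simple
anthropometric indices against DXA-measured body composition, together with
a probability-based procedure for turning a prediction equation into an
obesity screening cut-point.

Two outcomes are modelled per sex stratum:

- **whole-body fat percentage** (%FM), modelled on its natural scale;
- **visceral adipose tissue mass** (VAT, grams), modelled as ln VAT because
  VAT is strongly right-skewed and residuals on the raw scale misbehave.
  Subjects whose VAT is recorded as 0 g ("undetectable" by the densitometry
  software) are excluded from the VAT models only; %FM analyses keep them.

Each outcome is regressed on each of five candidate predictors — BMI
(kg/m²), waist circumference WC (cm), waist-to-hip ratio WHR, waist-to-height
ratio WHtR, and the allometric index WHT.5R = WC(m)/√height(m) — by
ordinary least squares:

    y_i = a + b x_i + e_i,   e_i ~ N(0, σ²)

with SEE = √(RSS/(n−2)) and adjusted R² = 1 − (1−R²)(n−1)/(n−2).

## Model comparison

Candidates are ranked by the Gaussian profile-likelihood AIC,

    AIC = n ln(RSS/n) + 2k,  k = 3,

which is defined only up to an additive constant shared by all candidates
fitted to the same observations; the package therefore exposes and labels
AIC *differences* Δ = AIC − min AIC within a stratum:

| Δ | support label |
|---|---|
| 0 | best |
| (0, 2) | essentially equivalent |
| [2, 7] | plausible alternative |
| (7, 14] | weak support |
| (14, ∞) | unsupported |

The half-open boundary assignment resolves the overlapping endpoints of the
conventional verbal scale ("<2", "2–7", "7–14", ">14") and is fixed by unit
tests at Δ = 2, 7 and 14. Ties for the minimum are broken deterministically
by the canonical predictor order (BMI, WC, WHR, WHtR, WHT.5R); the other
tied candidates sit at Δ = 0 labelled "equivalent". Comparing fits with
different n, outcome or sex is rejected — AIC differences across different
data are meaningless.

Because SEE estimates from small samples are themselves noisy, each SEE is
reported with its χ²-based 95% interval: SEE·√(df/χ²₀.₉₇₅) to
SEE·√(df/χ²₀.₀₂₅), with the single symmetric "×/÷ factor"
(χ²₀.₉₇₅/χ²₀.₀₂₅)^¼ (1.25 at df = 39, → 1 as df → ∞).

## Cut-point derivation

Given a fitted equation with slope b > 0 and a threshold T defining obesity
on the outcome scale, the cut-point is the index value at which an
individual has probability p (default 0.75, i.e. odds 3:1) of truly
exceeding T. Writing t\* for the p-quantile of Student's t with n−2
degrees of freedom:

1. **SEE inflation.** In small validity samples the SEE understates
   individual prediction uncertainty because the equation itself is
   estimated; the SEE is multiplied by √(1 + 1/n + 1/(n−3)). The
   square-root form is the default because it is the convention consistent
   with the package's worked reference chain (4.1 → 4.2 at n = 41); the
   plain factor (1 + 1/n + 1/(n−3)), which inflates roughly twice as much
   (4.1 → 4.3), is available via `inflate_see(..., literal_factor=True)`.
2. **Required predicted value.** P = T + t\*·SEE_adj, from inverting
   t = (predicted − T)/SEE.
3. **Inversion.** cut-point = (P − a)/b. The procedure is only defined for
   positively associated predictors; b ≤ 0 raises.

`paper_mode=True` reproduces a desk calculation by rounding t\* to 3
decimals and SEE_adj and P to 1 decimal between steps; the default carries
full precision. Degrees of freedom are n−2 throughout (simple regression).

Thresholds: %FM obesity is >25% (men) and >35% (women), strict, while
BMI obesity is ≥30 kg/m², inclusive — both as conventionally stated. VAT
has no accepted mass threshold, so visceral obesity is defined
distributionally as the highest third of detectable-VAT subjects: the
boundary is the empirical 2/3 quantile (numpy's linear-interpolation
convention) and the obese group is strictly above it; the derivation then
runs on the ln-gram scale with T = ln(boundary). All-equal inputs (no one
strictly above the boundary) are rejected as degenerate.

### Calibration

The central property is that the procedure is calibrated: at the derived
cut-point, the probability that a subject's true outcome exceeds T is p.
The test-suite oracle simulates true outcomes as

    predicted(cut-point) + SEE_adj · T_{n−2}

with T_{n−2} a Student-t draw — the error law under which the one-tailed
t-area argument is exact — and checks the exceedance fraction against p
within 3 binomial standard deviations at 10⁶ draws. (Gaussian draws would
instead converge to Φ(t\*_{p,df}), e.g. 0.7520 rather than 0.7500 at
df = 39; the t-draw oracle tests the procedure's own model rather than that
large-df approximation.)

## Synthetic cohort generator

The generator emulates the per-sex statistical structure the analysis
consumes, not a full human-biology simulator. Per sex it draws WHtR, BMI,
WHR, height and age from independent normals (truncated by resampling at
physiologic floors: height > 1.2 m, WHtR > 0.25, BMI > 13 kg/m², WHR > 0.4,
age ≥ 18) and back-derives the raw measurements — WC = WHtR × height,
HC = WC/WHR, mass = BMI × height² — so that the index–outcome regression
structure holds by construction. Outcomes follow

    %FM    = fm_intercept + fm_slope·WHtR + N(0, fm_see)      (resampled into (0,100))
    ln VAT = lv_intercept + lv_slope·WHtR + N(0, lv_see)
    VAT set to 0 g with probability p_zero_vat (undetectable)

A single seed expands into deterministic per-sex substreams
(`numpy.random.SeedSequence.spawn`), so identical configs give identical
cohorts and editing one sex's parameters leaves the other stratum's draws
unchanged. Residual SDs (`fm_see`, `logvat_see`) may be exactly zero — the
noiseless limit used to test the deterministic part of the model — while
the SDs of measured traits must be strictly positive.

### Default parameters (the modelled study conditions)

41 men and 40 women. Marginal moments per sex: male WHtR 0.50 (SD 0.07),
BMI 26.2 (4.1), WHR 0.91 (0.07), age 40.5 (20); female WHtR 0.48 (0.08),
BMI 24.8 (4.4), WHR 0.80 (0.07), age 36.3 (14.5). Mean heights (1.78 m men,
1.64 m women) are set so the implied mean waist (WHtR × height) matches the
cohort's 88.8/78.7 cm. The male %FM line is 99.7·WHtR − 24.7 with residual
SD 4.1; the female %FM line (76.2, −2.6, SD 5.0) and both ln-VAT lines
(men: 12.9, −0.04, SD ln 1.8; women: 16.1, −2.41, SD ln 2.6) are
back-derived once from the marginal moments and the fitted R²/SEE values
via slope = r·SD_y/SD_x. One woman in five has undetectable VAT
(p_zero_vat = 0.2); no men do.

### What the generator does and does not emulate

It reproduces the marginal moments, the linear index–outcome relations with
the stated residual scatter, the log-normal shape of VAT, and the
undetectable-VAT rate. It does **not** calibrate cross-index correlations
(BMI vs WHtR correlations are emergent from back-derivation, not fitted),
age–adiposity trends, DXA measurement error, or the empirical upper tail of
VAT: the parametric log-normal tertile boundary for men (~970 g) sits below
the empirical 1108 g of a real heterogeneous cohort, so synthetic VAT
cut-points come out near 0.56–0.57 rather than 0.59. Passing tests on
synthetic data therefore demonstrate the correctness and calibration of the
*pipeline*, not population validity of any particular cut-point.

## Numerical choices and degenerate inputs

- OLS is closed-form on mean-centred sums; fits with RSS numerically zero
  (relative to total variation, 10⁻¹²) raise `PerfectFitError` rather than
  propagate −∞ AICs; constant predictors raise `DegenerateDesignError`;
  n < 4 raises `InsufficientDataError`.
- Geometric summaries (geometric mean, ×/÷ factor SD = exp of the n−1
  sample SD of ln values) use natural logs and require strictly positive
  inputs; zeros must be excluded first.
- t-quantiles and χ² quantiles come from scipy.stats; no tabulated values
  are embedded.
- The cohort CSV stores height in cm and floats at 17 significant digits so
  write→read round-trips to ~1e−9 after the single cm↔m conversion.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` summarises synthetic cut-points as medians over 300
independently seeded cohorts at the study sample sizes, and recovers
generator parameters from one 4000-per-sex cohort; both sizes keep the full
run in a few seconds while leaving Monte-Carlo error well inside the
reported rounding.

## Known limitations

- Simple regression only: no multi-predictor models (e.g. BMI + WC), no
  robust or weighted variants, no AICc.
- Cut-points are derived for positively associated predictors only.
- The VAT obesity definition is sample-distributional (top tertile), so it
  inherits the arbitrariness of that choice; the quantile convention is
  linear interpolation, which can differ from other software by up to one
  order statistic at n ≈ 30–40.
- Ethnicity strata, longitudinal change and measurement error are out of
  scope for the generator.
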