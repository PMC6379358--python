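# Methods

## Model and fitting procedure

The estimand is end-exercise venous blood lactate Y (mmol/L) after a
constant-work-rate (CWR) cycling test. The model class is an exponential
regression Y = exp(A·x) in seven noninvasive predictors — tidal volume
(V_T, L), breathing frequency (BF, breaths/min), resting heart rate (ReHR,
beats/min), end-exercise heart rate (ExHR, beats/min), age (years), BMI
(kg/m²) and sex — linearized by a cubic Taylor expansion and solved as an
ordinary least-squares problem.

Concretely, `lacest.features` z-scores each predictor with training-set
mean and sample SD (denominator n−1) and expands it into the monomials
z, z², z³; an intercept column is prepended, giving 1 + 3·7 = 22 columns.
Two conventions are deliberate:

* **Per-variable (additive) expansion, no cross-terms.** A full
  multivariate cubic in 7 variables has 120+ columns and cannot be
  estimated on strata of 31–93 observations; the additive reading is the
  only one compatible with the intended data sizes. The expansion degree is
  configurable (`FeatureSpec.degree`).
* **Monomial basis.** The alternating signs and factorial divisors of the
  Taylor form a₀ − a₁z + a₂z²/2! − a₃z³/3! are a fixed, invertible
  per-column rescaling, which least squares absorbs into the coefficients
  (a₀ = c₀, −a₁ = c₁, a₂/2! = c₂, −a₃/3! = c₃). Fitted values are
  identical; the test suite verifies this invariance to 1e−10.

Z-scoring before expansion is a numerical necessity, not a cosmetic choice:
raw-scale cubics of heart rate (~140³ ≈ 3·10⁶) sit next to tidal-volume
cubics (~2³), and the resulting design is so ill-conditioned that even the
SVD solver loses several digits. Standardization parameters are estimated
on the training stratum only, frozen into the saved model, and reused at
prediction time.

### Solver

The normal-equations form A = (XᵀX)⁻¹XᵀY presumes full rank. The package
solves the system with `numpy.linalg.lstsq` (SVD-based), which returns the
same solution on full-rank input and the minimum-norm least-squares
solution otherwise, recording the effective rank and emitting a
`RankDeficiencyWarning`. Rank deficiency is the *normal* situation for the
default feature set: a binary sex code takes two values, so its z² and z³
columns are exact affine combinations of the intercept and z. The
minimum-norm solution distributes the sex effect across its collinear
columns; fitted and predicted values are unaffected (new rows share the
same collinearity pattern and lie in the training row space).

### Error statistics and agreement

Residuals are d = Y − Ŷ, D = Σd², variance σ² = D/(n−1) (sample
convention throughout), residual SD σ. Percent errors are dᵢ/yᵢ and
require measured lactate > 0. Bland–Altman differences are oriented
**estimated − measured**, with limits of agreement bias ± 1.96·SD(diff)
and a percent variant dividing each difference by the measured value.

### Leave-one-out cross-validation

LOOCV refits the *entire* pipeline per fold — standardizer and
coefficients on the n−1 training records — then predicts the held-out
record; MSE is reported on the mmol/L scale. The closed-form identity
eᵢ/(1−hᵢᵢ) with h the hat-matrix diagonal holds only when preprocessing
is fixed across folds, so it serves as an independent test oracle with
standardization disabled, never as the implementation.

### Stratification

`fit_stratified(..., strategy="paper")` pools LC and MC tests into a
`low_moderate` model and fits HC separately (`high`);
`strategy="combined"` fits one model on all tests. Each stratum gets its
own standardizer, in-sample error statistics, Bland–Altman summary and
LOOCV. With 31-subject cohorts the high stratum has 31 rows for 22
columns, so its in-sample residual SD is optimistically small — the same
small-sample caveat the original analysis carries; LOOCV is the honest
error measure at that size.

### Weighting analysis

The coefficient vector holds three coefficients per variable, but the
weighting analysis reports one signed number per variable. The extraction
rule is genuinely underdetermined, so two are implemented:
`first_order` (default) takes the degree-1 coefficient — the derivative
of the fitted surface at the standardized cohort mean, the cleanest
single-number sensitivity — and `signed_l1` takes sign(degree-1
coefficient) × Σ|coefficients| across orders. Normalized weights divide by
the total |weight| so their absolute values sum to 1. Weights are reported
on the standardized scale only; raw-scale weights would conflate units
with importance. Variable *rankings* on any particular cohort (e.g. which
variable dominates the low/moderate model) are data properties, not
package contracts, and are not asserted by tests.

### The 7-vs-8 variable question

The modelling narrative names seven independent variables while the
weighting description speaks of eight, without enumerating them. The
package defaults to the seven named variables; the feature list is
configurable, so an eighth variable (within the documented vocabulary) can
be added by the user. No attempt is made to guess the unnamed eighth.

## Synthetic cohort generator

`lacest.synth` exists because the original cohort is unavailable. It
emulates the *reported summary statistics*, not the raw data:

* **Anthropometrics**: age ~ N(33, 9²) clipped to [20, 50] years, male
  fraction 14/31, height ~ N(165, 9²) cm, weight ~ N(62.7, 11.6²) kg, BMI
  computed from height and weight, resting HR ~ N(70, 8²) beats/min, peak
  work rate ~ N(187, 78²) W floored at 40 W. Clipping (not truncated-normal
  resampling) keeps sample means within the tested 3-SE bands: resampling
  would shift the age mean by +0.75 y, clipping by +0.20 y.
* **Protocol**: three tests per subject at 35%/60%/90% of peak work rate
  for 15/10/4 minutes (LC/MC/HC).
* **Physiologic responses**: ExHR = ReHR + (220 − age − ReHR)·g(regime)
  + N(0, 4²), with g = 0.40/0.62/0.85 — an age-predicted-maximum reserve
  heuristic chosen for realism, not taken from any dataset. BF and V_T
  increase with regime around subject-level baselines (BF 22/27/35 ± 2.5
  within, ±2 between subjects; V_T 1.3/1.8/2.3 ± 0.2 within, ±0.15
  between).
* **Lactate link**: lactate = exp(c_regime + Σ_j b_j z_j) + N(0, τ²),
  floored at 0.3 mmol/L (a physiologic resting minimum — simpler than
  truncating the noise, and essentially never active at the default τ =
  0.3). z uses a *fixed nominal* population scale (`LINK_SCALE`), so the
  ground truth never depends on any fitted standardizer. The positive
  exponent makes lactate rise with heart rate and ventilation; coefficient
  signs absorb notational conventions.

**Link coefficients.** The default b (ExHR 0.12, BF 0.08, V_T 0.06, ReHR
0.05, age 0.04, BMI 0.03, sex 0.02) were fixed once by a design
calculation: magnitudes small enough that the exponential of a sum is
well-approximated by additive per-variable cubics over the cohort's
variable range (the best additive cubic leaves ≈0.15 mmol/L RMS, half the
default measurement noise), because the recovery guarantees of the
regression layer presume near-well-specified data; signs and ordering
follow exercise physiology (heart rate and ventilation dominate). A
consequence worth stating plainly: within-regime lactate SDs of synthetic
cohorts (≈0.5–1.3 mmol/L) are *smaller* than the reported cohort SDs
(2.3/4.2/4.1 mmol/L), because the generator omits the unexplained
between-subject heterogeneity a real cohort has. Calibration targets the
regime *means*; matching the SDs as well would require either a latent
subject effect (destroying well-specifiedness) or implausibly large b.

**Regime offsets.** c_regime is calibrated so that the population mean of
exp(c + Σb·z) hits the configured regime means (3.7/6.9/10.4 mmol/L):
c = log(target) − log(mean exp(η)) computed on an internal reference
cohort of 40,000 subjects drawn with a fixed private seed. Calibration is
therefore deterministic, independent of the user seed, and accurate to
≈0.1% (40,000 was chosen to keep calibration bias an order of magnitude
below the 3-SE acceptance band at 3,100 subjects).

**Two generator modes.**

* `regime_distinct=True` (default): each regime has its own offset and the
  HC regime doubles the ExHR coefficient. A single combined model is then
  misspecified while per-stratum models are not — the qualitative pattern
  (combined residual SD > each stratified SD) that motivates
  stratification, reproduced in ≥18/20 seeds by the acceptance suite.
* `regime_distinct=False`: one shared offset (calibrated to the pooled
  mean) and common coefficients everywhere — well-specified data for
  recovery tests (LOOCV RMSE ≤ 1.5τ at ~310 tests) and null-variable
  weighting tests.

**What passing tests do and do not show.** The generator reproduces
summary moments, monotone intensity responses and a known link; it has no
breath-by-breath kinetics, no VO₂, no subject-level correlation between
fitness and lactate response (none is reported to emulate), and its
lactate dispersion is optimistic (above). Green tests therefore establish
that the *machinery* — expansion, solver, LOOCV, agreement analysis,
weighting — is correct and that the stratification pattern emerges when
regimes genuinely differ; they do not certify the accuracy figures on any
real population.

## Numerical choices and degenerate inputs

* Sample (n−1) denominators for every variance/SD.
* Fold order in LOOCV equals row order; all simulation randomness is
  explicitly seeded; every CLI output is byte-deterministic given config +
  seed (floats serialized with shortest round-trip `repr`).
* Constant features raise `DegenerateFeatureError` rather than producing
  NaN z-scores; empty strata raise `StratificationError` naming the
  stratum; percent errors refuse non-positive measured values.
* Negative predictions are *not* clamped in the library (the polynomial is
  unbounded and a negative estimate flags extrapolation); `lacest predict
  --clamp` floors at zero for report-level use.
* Problem sizes used by the test and acceptance suites — 31–104 subjects
  for pipeline checks, 1,000 for weighting replicates, 3,100 for
  calibration checks, 20–50 seeds per property — were chosen so each
  property is measured well inside its Monte-Carlo margin while the whole
  suite stays fast.

## Known limitations

* The eighth weighting variable is unresolved (see above); defaults use
  seven.
* LOOCV MSE is reported on the mmol/L scale; whether the originally
  reported values (~0.25–0.27) are on that scale is not stated anywhere,
  so no numerical equivalence is claimed.
* Abstract-vs-figure discrepancy in the high-intensity residual SD
  (1.82 vs 1.83 mmol/L) is treated as the same quantity; neither value is
  asserted.
* The generator's correlations between variables are modelling choices;
  real cohorts will differ, and the reported residual SDs on synthetic
  data should not be compared to published cohort values.
* Prospective validation on real subjects is out of scope.
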