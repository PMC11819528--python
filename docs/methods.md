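# Methods

This note documents the statistical models, defaults and design
choices behind `cmamgrowth`, and what its synthetic-cohort tests do —
and do not — demonstrate about real programme data.

## Z-scores and severity

Z-scores use the LMS method: for a measurement x with reference
Box-Cox power L, median M and coefficient of variation S,
z = ((x/M)^L − 1)/(L·S), or log(x/M)/S when L = 0. Lookups
interpolate L, M and S linearly between tabulated keys (age in days
at 30.4375 d/month for WAZ/HAZ/MUAC-for-age; length/height in mm for
WHZ); keys outside the tabulated range yield missing values, never
extrapolation. For the weight-based indicators (WHZ, WAZ) the
WHO-style *restricted adjustment* recomputes |z| > 3 on a linear
scale anchored at the ±3 SD bounds (z = 3 + (x − sd3)/(sd3 − sd2)
above, symmetrically below), capping the influence of the Box-Cox
tail; a switch disables it. Whether the original pooled analysis
applied this adjustment is not stated in its methods; applying it is
the default of the reference z-scoring tools that analysis used.

Severity follows the WHO definitions: severe wasting MUAC < 115 mm or
WHZ < −3; moderate wasting 115 ≤ MUAC < 125 mm or −3 ≤ WHZ < −2;
concurrent wasting-and-stunting WHZ < −2 and HAZ < −2; severe
underweight WAZ < −3. Weight-gain velocity is
1000·(w_exit − w_adm)/(w_adm·days), i.e. over *admission* weight —
some protocols use nadir weight instead; admission weight is the
default because the admission visit anchors every other gain in the
pipeline.

## Cleaning

Three layers, in this order: (1) per-visit plausibility bounds
(height outside 60–120 cm, MUAC outside 70–200 mm, weight outside
3.5–40 kg → missing); (2) longitudinal consistency within child — any
height decrease blanks the *later* height, and a change beyond
±1.5 kg weight, ±15 mm MUAC or +1.5 cm height per week of inter-visit
gap (gap floored at 1 week and capped at 4) blanks the later value,
with comparisons skipping already-missing values so the admission
anchor is preserved; (3) z-scores are computed from the surviving
measurements and each indicator's pooled distribution is subjected to
Tukey fences (Q1 − k·IQR, Q3 + k·IQR, k = 1.5 by default), blanking
the z-score (not the measurement, which is what the original cleaning
description specifies). Visits recording no anthropometry at all are
dropped up front.

Running the pooled-outlier layer *after* the longitudinal layer is a
deliberate ordering choice: it makes a full cleaning pass an exact
fixed point (a second pass sees the identical measurement set, hence
the identical z pool, hence the identical fences), which would not
hold if fences were computed before longitudinal blanking. Which of
the two visits to blank on a delta violation, and how to scale
thresholds over non-weekly gaps, are not specified by the source
cleaning rules; blanking the later visit and scaling linearly with a
4-week cap are the package's choices, both configurable.

## Exit outcomes

Study-assigned recovered/non-responder labels are respected.
Children with oedema at admission are excluded (their fluid-retention
dynamics confound weight-based indices), as are deaths and medical
transfers. Defaulter/unknown outcomes with ≥ 12 weeks of stay
(floor(days/7)) are re-classified from exit anthropometry — the last
non-missing MUAC and WHZ, taken per indicator (they may come from
different final visits): recovered if at least one recovery criterion
is met (MUAC ≥ 125 mm or WHZ ≥ −2) with no remaining severe criterion
(MUAC ≥ 115 mm, WHZ ≥ −3, no oedema); non-responder if both MUAC
< 125 mm and WHZ < −2. A child meeting one recovery criterion while
severely low on the other indicator satisfies neither rule; such
children are excluded as unclassifiable rather than forced into
either group, since the two re-classification rules do not partition
that corner of the space. Missing indicators fail every comparison
they enter, which routes incomplete exits to unclassifiable rather
than guessing.

## The quartile split

Admission-to-exit gains (MUAC, weight, height, WHZ, WAZ, HAZ,
MUAC-for-age z, and g/kg/day velocity) use the first visit as
admission and the last non-missing observation per indicator as exit;
a gain is missing whenever either endpoint is. The first quartile of
the pooled *non-responder* gains defines the split: gain < Q1 → low
growth NR, gain ≥ Q1 (ties high) → high growth NR; recovered children
are never re-assigned. Q1 uses linear interpolation between order
statistics at position 0.25·(n−1) — the common default of statistical
software; the convention only matters in small samples and is
configurable. MUAC gain is the default split indicator (the one the
pooled analysis carried forward); the published study-data thresholds
(2 mm MUAC, 0.4 kg weight, 0.6 g/kg/day, 0.5 WAZ, 0.0 WHZ) are
exposed as documented constants in
`response.STUDY_REFERENCE_VALUES` — they depend on the original
pooled data and are not recomputed from anything else.

## Trajectory model

Weekly group curves come from a penalized least-squares additive
model

y_ij = f_g(i)(w_ij) + β_age·(age_i − mean) + b_i + ε_ij,

with one cubic B-spline smooth f_g per response category (10 interior
knots at pooled week quantiles by default, automatically reduced with
a warning when a group has too few distinct weeks), an optional
linear admission-age adjustment (used for MUAC and weight), and
per-child random intercepts b_i absorbed as a ridge-penalized block.
Each smooth carries a second-*divided*-difference penalty evaluated
at the Greville abscissae, so that straight-line trends in time are
exactly unpenalized even with non-uniform knots; as the smoothing
parameter → ∞ each group curve tends to its ordinary least-squares
line, and noiseless linear group means are reproduced to numerical
precision. One smoothing parameter is shared across the group
smooths and one controls the subject intercepts; both are selected by
GCV over a log-spaced grid (REML score available), trading a little
optimality for robust, fast selection at cohort scale. Pointwise 95%
intervals use the Bayesian-style covariance σ²(XᵀX + S)⁻¹ of the
penalized coefficients. Prediction is refused outside the fitted
week range — curves are only reported where data exist. A test
cross-checks the whole construction against an independent
penalized-GAM implementation (R mgcv with by-group smooths and a
child random effect) on a simulated panel.

Week index is floor(days since admission / 7). Random *slopes*,
tensor-product smooths and study-level effects are out of scope: the
pooled analysis modelled individual-level clustering only.

## Multinomial model

The 3-category outcome (reference: recovered) is fitted by Newton
iterations on the multinomial log-likelihood (converged when the
score norm falls below 1e-8, max 100 iterations), with standard
errors from the observed information; the fit is backed by
statsmodels' MNLogit. For a single categorical predictor the MLE
odds ratios equal the contingency cross-product
(a·d)/(b·c) exactly — that closed form is implemented independently
and used as the oracle in tests. Joint Wald tests pool all
coefficients of a variable across both non-reference contrasts
(χ², df = number of coefficients). The multivariate covariate set is
fixed to: sex, age category (6–11/12–23/24–59 months), admission MUAC
category (<110/110–114/115–119/≥120 mm), admission WHZ < −3,
admission WAZ < −3, any reported morbidity, and the no-MUAC-gain /
no-weight-gain-in-first-month flags ("first month" = the visit
closest to day 28 within days 21–42; children without such a visit
get a missing flag, and models are complete-case with counts logged).
VIF screening regresses each dummy-encoded column on the rest
(flagging VIF ≥ 1.5). Classification metrics are in-sample accuracy
and the Hand–Till multiclass AUC — the average of pairwise one-vs-one
AUCs — since a single AUC for a 3-class model needs a declared
construction; a one-vs-rest macro average is available by option.

## Synthetic cohorts

The generator emulates pooled CMAM study conditions: weekly visits to
16 weeks; latent classes recovering / delayed responder / non-grower
with default mix 0.86/0.105/0.035 (non-growers one quarter of the
eventual non-responder pool, matching the ~75/25 split the quartile
analysis found); admission MUAC means 120/111/120 mm and admission
WHZ −2.4/−3.0/−2.9 anchored to the pooled descriptive medians; 57%
girls; 20% oedema at admission; geometric weekly dropout (defaulters)
plus small death/transfer/unknown-label fractions so every exclusion
and re-classification branch is exercised. MUAC and WHZ follow
monotone saturating-exponential trajectories (class-specific start,
lift and time constant); non-growers keep weight and MUAC flat while
height continues to grow. Height comes from a drifting HAZ via the
inverse LMS transform and weight from the planted WHZ at the current
height, so pipeline-recomputed z-scores recover the planted
trajectories up to measurement noise (defaults 2 mm MUAC, 0.1 kg
weight, 0.5 cm height — field-realistic repeatability). Discharge
requires the observed recovery criterion on two consecutive visits,
as CMAM protocols typically do.

Because classes are latent, some planted delayed responders genuinely
cross the recovery thresholds before 16 weeks and are (correctly)
discharged as recovered — the generator reproduces the ambiguity of
real programmes rather than a clean partition. What the passing tests
show is therefore that the pipeline recovers planted structure under
realistic noise and censoring (≥ 90% class agreement on a low-noise
2,000-child cohort; exact quartile-split recovery in the noise-free
limit); they do not show anything about between-study heterogeneity,
informative dropout (available via config but off by default),
seasonal effects, or measurement error structure beyond additive
Gaussian noise, none of which the generator emulates. The bundled
LMS reference is synthetic: internally consistent and realistic in
magnitude, but not the WHO 2006 standards, so absolute z-score values
from it are only meaningful within simulations.

## Problem sizes and numerics

Test and demonstration runs use desk-scale cohorts (300–2,000
children; 300 children × 12 weeks for curve-recovery checks; 1,000
null replicates at n = 500 for Wald calibration), sizes at which
every statistical property under test is already stable. Penalized
fits solve dense normal equations via Cholesky with a 1e-10 relative
ridge for numerical safety; smoothing grids span 10⁻²–10⁶ (smooths)
and 10⁻¹–10⁸ (subject intercepts). Ties at the quartile threshold go
to high growth, matching the published "≥ Q1" convention. Degenerate
inputs fail loudly: all-missing pools, unsorted visit dates,
rank-deficient designs and out-of-range predictions are errors, not
silent repairs.
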