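# Methods

## Pipeline overview

`ptapls` estimates the association between coarse regional brain
microstructure and the duration of post-traumatic amnesia (PTA) in four
stages:

1. **Regional aggregation** (`ptapls.roi`).  A five-region label volume
   (FT, PO, CC, BS, BT), co-registered FA/MD maps and a binary
   lesion/microbleed mask are reduced to per-region means over
   normal-appearing tissue.  Cerebral white-matter voxels can first be
   assigned to the nearest cortical label in physical distance.
2. **Age adjustment and standardization** (`ptapls.adjustment`).
   Patient FA/MD values are corrected by the linear metric-on-age trend
   estimated in healthy controls, then all predictors and the outcome
   are z-scored (sample SD, n−1).
3. **Pattern decomposition** (`ptapls.pls`).  PLS1 extracts orthogonal
   components maximizing predictor–outcome covariance; loadings are the
   spatial patterns.
4. **Inference** (`ptapls.inference`).  Spearman associations of the
   first three component scores with PTA at the Bonferroni-corrected
   threshold, and leave-one-out prediction validated against a
   permutation null.

## Assumptions

* Volumes are co-registered; the NIfTI affine is consulted only for
  voxel size.  No reorientation, registration, segmentation or tensor
  fitting is performed.
* Age acts linearly on each regional metric within the control age
  range, and the patient ageing trend equals the control trend.
* PTA is treated as a continuous day count.  A subject who died before
  emerging from amnesia has PTA imputed to a fixed constant
  (default 400 days) *before* any analysis; the imputation is recorded
  in provenance.
* The five-region summary is deliberately coarse: the analysis targets
  global and deep-vs-superficial contrasts, not tract-level anatomy.

## Masking rules and their order

Per region: (1) erode the label mask by one voxel in all dimensions —
the structuring element is the full 3×3×3 cube (26-neighborhood), and
grid borders count as outside; (2) for the primarily-white-matter
regions FT, PO, CC, BS keep only voxels with FA **strictly** greater
than the threshold (default 0.3) — BT, being grey matter, is never
thresholded; (3) remove voxels in the exclusion mask.  Thresholding and
exclusion commute, erosion does not, hence the recorded order.
Non-finite metric voxels are dropped from means and counts (failed
tensor fits must not poison a regional mean).  An empty region raises a
named error rather than reporting zero.  Nearest-label distance ties go
to the lowest label id, making the assignment deterministic and
independent of scan order; distances use voxel size per axis, so
anisotropic acquisitions are handled.

White matter is assigned to cortical labels first and eroded per-region
afterwards; the two orders differ only at region interfaces and the
choice is fixed here for reproducibility.

## Age adjustment

The default subtracts `slope · (age − reference_age)` (the control-mean
age), keeping patient values on their native scale; full
residualization against the control line is available via
`method="residualize"`.  The two differ by a per-column constant and
are indistinguishable after z-scoring, which is why slope-only
centering is the default.  Microbleed count and volume are z-scored but
never age-adjusted: no comparable normative ageing trend is assumed for
them.  Trend fitting requires ≥ 3 controls with non-degenerate ages per
(region, metric).

## PLS1

Classical deflation PLS1 (single outcome): weights from the covariance
with the residual outcome, X deflated per component, coefficients
`B_k = W_k (P_kᵀ W_k)⁻¹ q_k`.  The algorithm is deterministic; at full
rank its fitted values equal ordinary least squares, which the tests
use as an oracle alongside an independent reference implementation.
Inputs must already be standardized (checked to |mean| ≤ 1e−8,
|SD − 1| ≤ 1e−6); components beyond rank(X) are refused.

PLS component signs are arbitrary, so each component is oriented so
that the sum of its predictor loadings is ≤ 0 (ties: first loading
≤ 0).  In this orientation a global *decrease* in FA loads negatively
and the component score correlates *positively* with PTA, which is the
direction the one-tailed tests assume; the convention is recorded in
output metadata, and recovery tests compare loadings up to global sign.

"Variance explained" for the component-count rule is cumulative
**predictor-block** variance (the rule is applied to the imaging
variables); outcome variance is reported alongside.  The selected count
is the smallest k whose cumulative percentage *strictly* exceeds the
threshold (default 80 %) for every analyzed variable.  The analysis
default is 3 components.

## Leave-one-out cross-validation and the permutation null

For each held-out subject, predictor columns and the outcome are
re-standardized using only the remaining subjects, PLS1 is refit, and
the held-out row is standardized with the fold's constants and
predicted; predictions are therefore in fold-standardized outcome
units (Spearman scoring makes this immaterial).  Each of the B
permutation draws permutes the outcome across subjects and re-runs the
*complete* LOOCV including fold-wise re-standardization — anything less
would understate the null variance.  Permutations are sampled uniformly
with replacement from the permutation group (standard Monte-Carlo
practice; distinctness is unattainable for B near n! anyway).

The empirical p is the fraction of null correlations **strictly
exceeding** the observed one, which can legitimately return 0; an
add-one smoothed variant, `(1 + #{null ≥ obs}) / (1 + B)`, is available
behind a flag for callers who need a positive lower bound.  The
prediction test is one-tailed positive: a model predicting worse than
chance in the negative direction carries no usable information.

Spearman correlations use mid-ranks for ties and the t-approximation
with n − 2 degrees of freedom for p-values (halved and directed when
one-tailed); constant vectors and n < 4 are errors.

## Synthetic data: what it emulates, what it does not

`ptapls.synthetic` generates cohorts with the structure the analysis
assumes.  Defaults are the study conditions: 14 patients, 21 controls,
ages uniform on 18–77 years.  For each metric, region r of patient i is

    x_ir = b_r + s_r·age_i + e_g·g_i·P_r + e_d·d_i·D_r + ε_ir,

with unit-norm patterns P (global, all-positive) and D
(deep-vs-superficial, CC/BS opposite FT/PO/BT), independent standard
normal severities g_i, d_i (controls: 0), and i.i.d. Gaussian noise.
PTA is `clip(190 + 80·g_i + 60·d_i + η, 0, 450)` days, rounded; the
intercept matches the reference cohort's mean PTA and the bounds bracket
its observed range plus the imputation constant.  All draws come from
one seeded stream in a documented order (ages, severities, metric noise
per metric, PTA noise), so output is bit-identical per (config, seed).

Default effect sizes (FA: −0.040 global and +0.025 deep per severity
SD against 0.010 measurement noise, and analogously for MD and the
microbleed scores) were chosen once so that the planted signal is
recoverable from 14 patients in the majority of seeds — they are a
design choice of this package, not estimates from any patient data.
Microbleed count/volume are generated as *continuous* damage scores
(no integer rounding, no floor at zero) so that the analytic moment
checks remain exact.

What the generator does **not** emulate: realistic brain geometry
(volumes are painted cuboid blocks), spatial noise correlation, partial
volume effects, non-linear ageing, outcome censoring, or correlated
severity dimensions.  Passing recovery tests therefore demonstrate that
the pipeline recovers the structure it assumes — not that real DTI data
satisfy those assumptions.

The volume generator computes its ground-truth regional means
analytically — the eroded block is the inner cuboid obtained by
shrinking the block bounds, lesion spheres are enumerated directly, and
the strict FA rule is applied to the painted values — independently of
the morphology code under test, so noiseless extraction can be checked
for exact equality.

## Numerical choices

* Sample SDs use n − 1 throughout.
* Score orthogonality and weight normalization hold to 1e−10 on random
  instances; full-rank/OLS agreement to 1e−8.
* Erosion via a boolean convolution with the 3×3×3 structuring element;
  nearest-label assignment via per-label Euclidean distance transforms
  with a 1e−9 guard so exact ties resolve to the lowest label.
* The corrected association threshold is α/m rounded to three decimals
  (0.05/3 → 0.017), matching how the threshold is conventionally
  quoted.
* Config hashes (SHA-256 of the canonical JSON) and the package version
  are embedded in every result bundle.

## Problem sizes used in validation

The calibration suite uses 200 replicate null cohorts with B = 200
permutations each (empirical p uniformity by Kolmogorov–Smirnov at
0.01, rejection rate inside the exact binomial 99 % band); pattern
recovery uses 100 seeded cohorts at n = 14 with B = 1000.  The
acceptance script analyzes one default cohort with B = 2000 and
measures recovery rates over 30 seeds with B = 500.  These sizes give
Monte-Carlo error comfortably below the decision margins they support.

## Known limitations

* n = 14 is very small; the permutation/LOOCV machinery quantifies, but
  cannot remove, the resulting instability of loadings.
* Predictions are in standardized units: the pipeline validates that
  microstructure carries information about PTA ranking, it does not
  output calendar-day predictions for new patients.
* The one-tailed component p-values depend on the sign convention; the
  convention is declared in output metadata rather than hidden.
* Slope-only age adjustment assumes patients follow the control ageing
  slope; violations fold into the patient noise term.
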