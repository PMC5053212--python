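# Methods

`mammodense` implements a case-case analysis of mammographic texture: given
pre-diagnostic screening mammograms of women later diagnosed with breast
cancer, it asks which features of the *dense area* of the normal breast
distinguish future interval cancers (IC — diagnosed between screens) from
screen-detected cancers (SC), beyond the established effect of percent
mammographic density (PD).  Because the motivating study's films and
registry data are not redistributable, every stage is driven and validated
by a synthetic-data module with known ground truth.

## Pipeline model

1. **Pre-processing.**  Artifact removal keeps the largest 8-connected
   component of the foreground (pixels above 2% of the dynamic range);
   intensity normalization maps the 1st/99th percentiles of breast pixels
   to 0/1 (monotone, clip-limited — robust to specks, unlike min–max);
   pectoral-muscle removal fits a straight-line boundary to the bright
   chest-wall-corner component (Otsu split of the upper chest-wall
   quadrant, component required to hug the chest wall at the top of the
   breast, robust Theil-Sen line through its per-row boundary with a small
   safety margin — sliver rows at the silhouette tip would tilt a
   least-squares fit and leave bright pectoral residue that contaminates
   the dense mask's second moments).  The source study
   names these goals but not its algorithms; ours are documented stand-ins
   validated against simulator ground truth (silhouette Jaccard ≥ 0.95,
   pectoral Jaccard ≥ 0.7 on synthetic images).  All three operators are
   deterministic and flip-equivariant; masks only shrink.

2. **Dense-area segmentation.**  Three thresholding methods on the 256-bin
   histogram of breast-pixel intensities: Otsu (minimum weighted
   within-class variance), percentile (median by default) and maximum
   entropy (Kapur).  Dense pixels are *strictly above* the threshold —
   this makes the percentile method's ≤ 50% dense-fraction property exact —
   and the histogram is taken over breast pixels only, since the dense area
   is defined within the breast.  Candidate thresholds are upper edges of
   *occupied* bins (empty bins yield the identical class split, so
   restricting candidates makes the lowest-threshold tie-break well
   defined); both optimizing thresholds are tested for exact agreement with
   exhaustive search.  No morphological cleanup: the dense area may be
   disconnected.

3. **Feature bank.**  32 features of the dense area, computed on the tight
   bounding-box crop with non-dense pixels zeroed (the published one-line
   definitions do not say how non-dense pixels are handled; the zero-filled
   crop is reproducible and oracle-testable).  Conventions:

   - moments are population moments (no small-sample correction);
     kurtosis is Pearson m4/m2², skewness m3/m2^1.5;
   - entropies are Shannon entropies in bits, 256 bins over the sample
     range; a constant sample has entropy 0;
   - eccentricity (F21) pools all dense pixels into one second-moment
     ellipse: with eigenvalues λ1 ≥ λ2 of the pixel covariance,
     F21 = √(1 − λ2/λ1) — the focal distance over the major axis;
   - the gradient-skewness feature (F40) uses central differences and
     restricts the sample to interior dense pixels (all four neighbours
     dense).  This makes the statistic measure the texture of the dense
     tissue itself — fatty-streak interspersion — rather than the
     artificial zero-fill edge of the crop, whose fixed heavy tail would
     otherwise dominate (and invert) the streak response;
   - the DFT "max coefficient" excludes the DC bin for F11/F17, where the
     maximum would otherwise trivially be the image sum, and keeps it for
     F3/F14, which transform filtered images whose DC term is informative;
   - unspecified filter parameters are pinned in one config block:
     Daubechies-4 wavelet at depth 3 (periodized, input zero-padded to a
     multiple of 2^depth so every stage has even length; depth capped by
     patch size), 3×3 local-range window, 9×9 local-entropy window,
     co-occurrence quantization to 32 gray levels with symmetrized
     matrices at offsets (0,1)/(0,2)/(8,8), a log-Gabor bank of 2 scales
     (1/6 and 1/12 cycles/pixel, σ/f = 0.65) × 4 orientations with complex
     responses averaged over the bank, unit-scale central-difference
     Hessian.  The original study's exact choices are unrecoverable, so
     the contract is internal consistency plus equivalence with
     independent naive oracles, not bitwise identity with the original
     code;
   - a feature undefined on an input (zero variance, too-small patch, no
     valid pixel pairs) is stored as 0 with an `undefined` flag; the
     statistics stage treats flagged values as missing, mirroring the
     study's exclusion of two images that could not be processed.

4. **Statistics.**  Feature samples are Box-Cox transformed (shift
   max(0, 1−min); λ by profile maximum likelihood on [−3, 3]) and
   standardized, so effects are per SD of a near-normal score.  The 3 × 32
   test battery fits one logistic model per method×feature (IC vs SC on
   the feature plus continuous PD, complete cases per model) and reports
   two-sided Wald p-values.  The global test statistic is the count of the
   96 p-values below 5%; its null distribution comes from permuting IC/SC
   labels jointly across women (features and covariates stay attached, so
   the correlation between features is preserved) with the empirical p the
   fraction of permuted statistics *strictly larger* than the observed one
   (an add-one-corrected variant is available behind a flag).  Features
   are transformed once before permuting: under the null the labels are
   exchangeable given the fixed feature matrix.  Forward selection is
   greedy by AIC over the base model (PD, age, BMI, HRT), with the
   complete-case set frozen at the start so AICs are comparable and ties
   broken in canonical feature order.  The final model reports per-SD odds
   ratios with 95% Wald CIs; a time-from-mammogram-to-diagnosis covariate
   is available as a sensitivity adjustment.  Tumor-size models are
   univariate linear regressions of √size (size is left-skewed) on the
   standardized feature, overall and within detection-mode strata.  The
   summary table uses Welch t-tests for continuous variables and Pearson
   chi-square (no continuity correction) for categorical ones, with
   percentages computed among non-missing values per group and rounded
   half-up, matching the published table's conventions.  No per-test
   multiplicity correction is applied: the family is controlled by the
   global permutation test.

   Internally the battery and the permutation loop use a dedicated batched
   Newton-Raphson logistic solver (one design matrix, many permuted
   outcome vectors); it is validated against `statsmodels.Logit` to
   machine precision in the test suite, and the final model itself is fit
   with statsmodels.

## Synthetic data

The image generator emulates a digitized film mammogram (12-bit range):
a half-elliptical breast silhouette with the chest wall along one edge, a
piecewise-constant intensity layout (background < fat < dense <
pectoral ≤ nametag, chosen so Otsu on the breast region isolates dense
tissue), an off-breast nametag block, a pectoral corner triangle, and a
dense region defined as the superlevel set of an anisotropic Gaussian blob
field.  Quantile thresholding of the field makes the dense-area fraction
essentially exact; the field's generating ellipse gives the requested
eccentricity (a small smooth perturbation keeps the boundary organic —
its amplitude is deliberately tiny because moment eccentricity is very
sensitive: a coherent one-pixel boundary wiggle on a radius-30 disk
already reads as ≈ 0.2).  Fatty streaks are thin sinusoidal curves carved
through the dense region at a relative depth given by `streak_intensity`;
their edges create a right tail in the gradient-magnitude distribution,
so mean |F40| increases monotonically in the knob (saturating at high
depth as the tail mass grows).  Per-image noise is Gaussian, clipped to
the dynamic range; one RNG stream per image/cohort derived from the seed,
no global state.

The cohort generator draws PD lognormal (median ≈ 19%, right-skewed as in
the reference cohort), BMI ~ N(25.5, 4²), age ~ N(60.4, 7²), HRT ~
Bernoulli(0.19), latent standardized features f40/f21 ~ N(0, 1); the IC
indicator follows a logistic model whose default coefficients are the
published per-SD effects (OR 1.32 for f40, 1.20 for f21); √tumor-size
follows stratum-specific linear models (slopes 0.20 on f40 in SC, −0.18
on f21 in IC; residual SD 1.3 chosen to match the published CI widths at
the published sample sizes) squared and floored at 1 mm so the √
transform stays well-defined.  Other characteristics (parity, receptor
status, grade, …) are drawn at the reference cohort's marginal rates,
independent of outcome.

What the simulator does *not* emulate: radiographic physics, 3-D anatomy,
scanner artifacts beyond nametags, intra-breast density gradients, or any
distributional claim about the original films beyond the published
medians.  Passing tests therefore demonstrate correctness and calibration
of the machinery, not clinical performance on real mammograms.

## Problem sizes and numerical choices

The shipped test and acceptance runs use scaled problem sizes chosen as
the smallest that make the statistical properties sharp: global-test
calibration on 100 null cohorts of n = 500 with 200 permutations
(rejection within [0.01, 0.11]); power on 50 cohorts of n = 1500 with
five features at OR 1.5; effect recovery on 100 cohorts of n = 1400 (the
reference sample size); end-to-end sign recovery on a bank of 600
synthetic images (192×160 px) with outcome labels redrawn 100 times from
the image knobs — regenerating the image bank per replicate would add no
information about the estimator's sign behaviour, since the images enter
only through their measured features.

Numerical conventions: 0·log 0 := 0 throughout; thresholds tie-break to
the lowest candidate; a sample whose min equals its max is degenerate
(variance features flagged) regardless of floating-point summation noise;
logistic fits use Newton-Raphson with step halving, declaring
non-convergence on separation (|β| > 30) or a singular Hessian, and
non-converged battery tests are excluded from the global statistic (with
a reported count) rather than imputed.

## Known limitations

- The preprocessing algorithms are validated only against the simulator's
  geometry; real pectoral boundaries are not perfectly straight.
- The percent-density proxy (dense-pixel fraction) stands in for the
  clinical area-based PD measurement only on synthetic runs; in real use
  PD is an input covariate.
- Box-Cox λ is estimated once on the observed data and reused across
  permutations; re-estimating per permutation would be marginally more
  exact but the labels are exchangeable given the fixed features.
- The selection criterion is AIC (the conventional default of stepwise
  selection in R); an alternative penalty can be supplied but is not
  studied here.
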