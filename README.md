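# mammodense

Dense-area image features of screening mammograms, and the case-case
statistics that relate them to how a breast cancer is eventually detected.

## The problem

Interval cancers (IC) — tumors diagnosed between two screening visits —
are on average more aggressive than screen-detected cancers (SC), and the
only established image marker of IC risk in the *normal* breast has been
percent mammographic density (PD): dense tissue can mask a growing tumor.
This package implements a feature-based alternative: from the
pre-diagnostic mammogram of the contralateral (normal) breast it

1. pre-processes the image (artifact/nametag removal, intensity
   normalization, pectoral-muscle removal),
2. segments the *dense area* by three thresholding methods — Otsu
   (minimum within-class variance), percentile (median), and maximum
   entropy (Kapur),
3. computes 32 features of the dense area (first-order histogram
   statistics; shape descriptors such as eccentricity, solidity, Euler
   number; texture and transform features: co-occurrence entropy/energy,
   log-Gabor response entropies, local-entropy and local-range filters,
   DCT/DFT/wavelet coefficients, SVD spectra), and
4. runs the statistical stage: Box-Cox standardization, a 3 × 32 battery
   of PD-adjusted logistic Wald tests, a label-permutation global test
   that respects the correlation between features, AIC forward selection,
   a final multivariate model reporting per-SD odds ratios
   (IC vs SC ~ PD + BMI + HRT + age + features), and linear models of
   √tumor-size per feature within detection-mode strata.

Two features carry the signal of interest: **F40**, the skewness of the
intensity-gradient distribution inside the dense area (fatty-streak
interspersion), and **F21**, the eccentricity of the dense area's
second-moment ellipse (elongation).  In the reference cohort their per-SD
odds ratios for interval versus screen-detected cancer were 1.32 and 1.20.

Because the clinical films are not redistributable, the package ships a
first-class synthetic-data module (`mammodense.simulate`) that generates
mammogram-like phantoms with ground-truth masks — controllable dense-area
fraction, elongation, and fatty-streak depth — and synthetic cohorts whose
IC/SC outcome follows a logistic model at the published effect sizes.
Every pipeline stage is tested against this ground truth and against
independent naive oracles.

## Worked example

```python
import mammodense as md
from mammodense.stats import CaseCaseModel, tumor_size_regression

# a synthetic cohort at the published effect sizes (OR 1.32 / 1.20)
cohort, truth = md.generate_cohort(md.CohortSimParams(n=1400, seed=1))
model = CaseCaseModel.from_cohort(cohort)        # latent F40/F21 scores
res = model.fit_final(features=("F40", "F21"), method="latent")
print(res.summary())
print(tumor_size_regression(cohort, cohort.f40, "SC"))
```

prints

```
Case-case logistic model (IC vs SC), n = 1400, features from latent
covariate                    OR (95% CI) per SD
------------------------------------------------------
pd                            0.99 (0.88 to 1.11)
age_dx                        1.03 (0.92 to 1.16)
bmi                           1.01 (0.90 to 1.13)
hrt                           0.98 (0.72 to 1.32)
F40                           1.26 (1.12 to 1.42)
F21                           1.16 (1.03 to 1.30)
AssociationResult(term='feature[SC]', estimate=0.2223..., se=0.0403...,
    effect=0.2223..., ci_low=0.1431..., ci_high=0.3015..., p=3.7e-08,
    n=999, kind='beta', converged=True)
```

The fitted per-SD odds ratios (1.26 and 1.16 on this seed) estimate the
generative values 1.32 and 1.20; the square-root-scale tumor-size slope in
the screen-detected stratum (0.22, CI 0.14–0.30) estimates its generative
value 0.20.  On images rather than latent scores:

```python
img, gt = md.generate_breast_image(md.ImageSimParams(seed=3))
norm, mask, log = md.preprocess_image(img)
dense = md.dense_mask(norm, mask, "otsu")
fv = md.extract_features(norm, dense)
print(md.percent_density_proxy(dense, mask))   # 27.5 (% of breast area)
print(fv["F40"], fv["F21"])                    # 1.821..., 0.616...
```

A command-line interface wraps the stages
(`mammodense simulate | preprocess | segment | extract | analyze | run`);
`mammodense run --n-images 60 --seed 0 --out runs/demo` executes the whole
chain on synthetic data and writes feature CSVs, a JSON report with the
test battery, global permutation test, selection and final model, and a
reproducibility manifest.

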