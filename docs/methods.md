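# Methods

## Signal model and tensor estimation

The diffusion-weighted signal is modeled as *S* = *S*₀·exp(−*b*·gᵀ**D**g)
with **D** a symmetric positive 3×3 tensor (mm²/s), *b* the diffusion
sensitization (s/mm²) and g a unit gradient direction. Taking logs gives a
linear model in (log *S*₀, D₁₁, D₂₂, D₃₃, D₁₂, D₁₃, D₂₃), solved per voxel
by ordinary least squares over all acquisitions. OLS on log-signals is the
default because it is unbiased at the high SNR of noiseless and
lightly-noised phantoms and exactly reproducible; a weighted variant
(weights ∝ *S*², the first-order correction for log-transformed noise) is
available by flag. All shells in the scheme enter one joint fit by default;
a `shells` argument restricts the fit (e.g. to b = 0 and 800 only) for
studying perfusion contamination of the low-b shell.

Numerical rules:

- Voxels with any non-positive signal among the used acquisitions are
  excluded from fitting and flagged (`excluded`): the log is undefined and
  such voxels are noise-dominated.
- Negative eigenvalues after diagonalization are clamped to 0 and flagged
  (`clamped`); this preserves FA ∈ [0, 1].
- Eigenvalues are stored sorted descending; ties are broken arbitrarily
  (every derived scalar is sort-stable, so the choice is inconsequential).
- FA of the zero tensor is defined as 0.
- Gradient directions are interpreted in the image coordinate frame
  (FSL-dialect bvec: three whitespace-separated rows, one per axis).

The default six-direction set is the dual-gradient scheme
{(1,1,0),(1,0,1),(0,1,1),(1,−1,0),(1,0,−1),(0,1,−1)}/√2. It is balanced
(Σ ggᵀ = 2·I), which makes the 7-parameter design well conditioned and
gives the identity that the geometric mean of the directional images equals
*S*₀·exp(−b·ADC) on noiseless data — the basis of the combined-DWI test.

The independent oracle for the fit in the test suite is a direct nonlinear
least-squares fit of the exponential signal equation
(`scipy.optimize.least_squares`), a genuinely different algorithmic path
from the log-linear solve.

## ROI refinement and lesion features

A lesion seed region (single slice, at the central slice of the lesion) on
the combined b = 800 image is refined by retaining voxels whose intensity
is at least `threshold_fraction` × the in-seed maximum; excluded-voxel
counts and the absolute threshold are recorded. The published description
of this step does not include the numeric threshold, so
`threshold_fraction` defaults to 0.5 and is documented as a calibration
knob. Because the maximum-intensity voxel always survives, an empty refined
ROI cannot arise from thresholding alone; the `empty` flag exists for
defensive handling of degenerate inputs, and summarizing an empty ROI
raises. Lesion features are arithmetic means of each scalar map over the
ROI; mean FA is always the mean of voxel-wise FA (FA of mean eigenvalues
would differ, since FA is nonlinear in the eigenvalues).

## DCE kinetics

Voxel curves are classified by the relative change r from the initial
(120 s) to final (480 s) post-contrast signal: washout r < −0.10,
persistent r > +0.10, plateau otherwise. The boundary cases |r| = 0.10 are
assigned to plateau, following the strict inequalities of the published
definitions. The lesion-level feature is the worst (most suspicious) class
present, washout > plateau > persistent; "washout on delayed phase" is the
binary worst-curve = washout indicator. An optional minimum-enhancement
gate (CAD-software convention) exists and is off by default.

## Synthetic cohort generator

The generator emulates the study population the analysis chain was designed
for, with full ground truth:

- **Clustering**: `n_patients` women with 1/2/3 lesions with probabilities
  (0.809, 0.155, 0.036).
- **Clinical/DCE covariates**: age ~ N(51.5, 11.7²); post-menopausal 52.1%;
  known-cancer indication 64.9%; dense breasts 73.2%; BPE ordinal 1–4 with
  probabilities (0.299, 0.407, 0.191, 0.103); mass type 56.7%; worst-curve
  kinetics (persistent, plateau, washout) = (0.025, 0.143, 0.832); BI-RADS 5
  8.4%; lesion size log-normal with median 1.1 cm and log-SD 1.1 (size is
  right-skewed; the log-SD reproduces a cohort mean near 2 cm).
- **Outcome model**: malignancy ~ Bernoulli(expit(β₀ + Σβⱼxⱼ + u)) with a
  patient-level Gaussian random intercept u ~ N(0, 0.5²) (clustering
  strength is not published; 0.5 gives a modest intra-patient odds
  correlation). Default log-odds are patterned on the published combined
  multivariate model (e.g. washout 2.43, BI-RADS 5 2.36, per-SD log-size
  1.85, per-category BPE 0.66, as ORs). The intercept is calibrated by
  Monte Carlo (fixed internal seed, 2×10⁵ draws) + root finding so that
  overall prevalence is 0.399; calibration is memoized and deterministic.
- **DTI features** are drawn *conditional on the realised class* —
  resolving the apparent circularity of a logistic outcome model plus
  class-conditional feature distributions: the outcome depends on the
  clinical/DCE covariates, then ADC ~ N(1.26, 0.32²) for malignant and
  N(1.55, 0.30²) for benign (×10⁻³ mm²/s), and FA log-normal per
  (type, class) cell with means (mass/malignant 0.31, mass/benign 0.21,
  non-mass/malignant 0.24, non-mass/benign 0.26). A Gaussian copula with
  latent correlation −0.51 ties the ADC and FA draws, reproducing the
  negative ADC–FA rank correlation of real lesions (a Gaussian copula was
  chosen as the simplest dependence structure with the right margins; the
  implied Spearman correlation, (6/π)·asin(ρ/2) ≈ −0.49, is within the
  tolerance of every test that uses it). Axial/radial diffusivity and
  λ₁ − λ₃ are derived from (ADC, FA) assuming an axially symmetric prolate
  tensor: λ₁ = ADC(1 + 2d), λ₂ = λ₃ = ADC(1 − d) with
  d = FA/√(3 − 2FA²); this reproduces the generating ADC and FA exactly and
  induces realistic collinearity among the five DTI features.

What the generator does **not** emulate: spatial structure of real lesions
(cysts, necrosis, fat; ROI placement error), EPI distortion and motion,
Rician noise floors at the cohort level, measurement error in the DTI
lesion means (they are drawn at lesion level, not re-estimated from
phantoms, except in the imaging-demo integration path), and real
correlations between clinical covariates. Passing tests therefore
demonstrate correctness of the estimation and validation machinery under
the stated generative model, not clinical performance on real data.

## Diagnostic models

- **Feature preparation**: right-skewed features (lesion size, FA, λ₁ − λ₃)
  are natural-log transformed; per-feature SDs on the analysis scale are
  recorded, and continuous coefficients/ORs are reported per 1-SD increase
  (OR_scaled = exp(coef_per_unit × SD), an exact identity). Binary features
  pass through untransformed; BPE enters as an ordinal 1–4 score with
  per-category ORs; breast density is dichotomized dense vs non-dense.
- **Univariate models**: logistic regression with independence working
  correlation and a cluster-robust sandwich covariance by patient
  (statsmodels GEE). With independence weighting the point estimates are
  ordinary logistic MLEs, so a single binary predictor reproduces the 2×2
  cross-product OR exactly. Fits with |coefficient| > 15 or non-finite SEs
  are flagged as separated (infinite-OR marker).
- **LASSO**: L1-penalized logistic regression (scikit-learn liblinear;
  `intercept_scaling = 10⁴` keeps the intercept effectively unpenalized,
  matching glmnet to ~4 decimals at matched penalties). Continuous features
  are standardized to unit SD inside the solver so reported ORs are per
  1-SD. The penalty grid is glmnet-style: 100 log-spaced values from
  α_max = max |xⱼ·(y − ȳ)|/n (the smallest penalty with an all-zero
  solution) down to 10⁻⁴·α_max. The penalty minimizes held-out binomial
  deviance accumulated over leave-one-patient-out folds (grouped K-fold by
  patient is available for large cohorts); deviance ties resolve to the
  larger penalty. α = 0 is routed to an exact unpenalized GLM fit. All
  candidates, clinical and imaging, are penalized equally. Grid points
  where the solver fails to converge are skipped with a logged warning.
- **Interactions**: size is dichotomized at 1 cm and type as mass vs
  non-mass (foci grouped with non-mass); interaction columns are products
  of the 0/1 dichotomy with the (scaled) continuous feature, so subgroup
  ORs per 1-SD are exp(main + interaction). The base 11-feature model has
  12 regression parameters; adding the four DTI interactions gives 16.
  Subgroup ORs are compared by a two-sided z-test on the interaction
  coefficient with cluster-robust SE.

## Internal validation

AUC is the rank-based (Mann–Whitney) statistic with ties counted half; for
a binary predictor it equals (sensitivity + specificity)/2. Optimism
adjustment follows Harrell's loop with **patient-level** resampling:
patients are drawn with replacement (each draw keeps its lesions intact
under a fresh cluster id), the full fitting procedure — including penalty
selection — is rerun on each resample, and
optimism_b = AUC(resample fit on resample) − AUC(resample fit on original);
adjusted = apparent − mean optimism. The 95% CI is the percentile interval
of the resampled apparent AUCs. Resamples missing an outcome class are
redrawn and counted. B defaults to 1000; tests run at B = 200. A fast mode
that freezes the penalty at the full-data selection exists for exploratory
pipeline runs and is excluded from the validation claims.

Model AUCs are compared on paired patient resamples: both specifications
are refit per resample and their apparent AUCs differenced; the CI is
percentile-based and the p-value is twice the smaller tail mass of the
bootstrap distribution beyond zero (capped at 1), with a flagged
normal-approximation fallback when a tail is empty.

Known limitation: the regular optimism bootstrap under-corrects heavily
overfit models at small n (e.g. ten candidate predictors on ~100 patients),
leaving the adjusted AUC biased above its true value, and over-corrects
when the selected model is empty (constant scores). The validation suite
measures exactly this behaviour. Relatedly, deviance-*minimizing* penalty
selection over-selects null candidates (a one-SE rule would be sparser but
is not the procedure implemented here); selection-frequency tests document
the realised rates.

## Problem sizes used by the test suite

Simulation-based tests use sizes chosen to make the checks sharp while the
default suite stays quick: Wald-test calibration at 500 null replicates of
150-patient cohorts; OR-CI coverage at 100 replicates of 120 patients;
optimism behaviour at 20 runs of 100 patients with B = 200; LASSO
selection frequency at 20 replicates of 400-patient cohorts with a
20-point grid and grouped 20-fold patient CV; copula and class-mean checks
at ~5000 lesions. The pipeline demo default is 200 patients.

## Out of scope

Pulse-sequence and k-space simulation, eddy-current/motion registration,
BI-RADS interpretation, pharmacokinetic (Tofts) modeling, DeLong analytic
AUC comparison, multi-compartment or kurtosis diffusion models, and
DCE→DWI spatial ROI propagation.
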