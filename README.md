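# breastdti

Diffusion tensor imaging (DTI) characterization of suspicious breast lesions
and quantification of the diagnostic value DTI adds to clinical and dynamic
contrast-enhanced (DCE) MRI assessment.

Breast DCE-MRI is highly sensitive but produces many false positives;
diffusion imaging can help because malignancies restrict water diffusion.
This package implements the full analysis chain a breast-DTI study needs,
end to end, with a synthetic-data generator so every stage is testable
without patient data:

1. **Tensor fitting and scalar maps** — per-voxel log-linear least-squares
   fit of the signal model *S* = *S*₀·exp(−*b*·gᵀ**D**g) on a multi-shell,
   six-direction acquisition (b = 0, 100, 800 s/mm²), eigendecomposition
   λ₁ ≥ λ₂ ≥ λ₃, and the five scalar parameters:

   - ADC (mean diffusivity) = (λ₁ + λ₂ + λ₃)/3
   - FA = √(3/2) · ‖λ − ADC‖ / ‖λ‖ ∈ [0, 1]
   - axial diffusivity λ₁, radial diffusivity (λ₂ + λ₃)/2, and λ₁ − λ₃

   plus the combined diffusion-weighted image (geometric mean of the
   unidirectional b = 800 images).
2. **ROI feature extraction** — refinement of a seed lesion region on the
   combined DWI by low-signal exclusion (threshold at a fraction of the
   in-seed maximum) and per-lesion means of each scalar map.
3. **DCE kinetics** — voxel curve typing from the 120 s → 480 s signal
   change (washout < −10%, persistent > +10%, plateau otherwise) and the
   lesion-level worst-curve feature (washout > plateau > persistent).
4. **Diagnostic modeling** — univariate logistic regression with
   cluster-robust (GEE/sandwich) inference by patient, odds ratios per 1-SD
   increase, Spearman correlation screening, LASSO logistic models with the
   penalty chosen to minimize deviance under leave-one-patient-out
   cross-validation, and lesion-subgroup interaction models (size × ADC,
   type × ADC, size × FA, type × FA) with Wald comparisons of subgroup ORs.
5. **Internal validation** — rank-based AUC, Harrell-style bootstrap
   optimism adjustment with patient-level resampling (the full fitting
   procedure, including penalty selection, is rerun on every resample), and
   paired-bootstrap AUC comparison of nested model specifications.
6. **Synthetic data** — DWI phantoms with known tensors (Gaussian or Rician
   noise), DCE curves with known kinetic class, and clustered lesion cohorts
   (1–3 lesions per patient, ~40% malignancy prevalence, class-conditional
   ADC means 1.26/1.55 ×10⁻³ mm²/s, ADC–FA dependence via a Gaussian
   copula) with full ground truth.

The intended users are imaging scientists prototyping quantitative breast
DWI/DTI analyses and statisticians studying clustered diagnostic-model
validation.

## Worked example

Simulate a lesion phantom mimicking a benign fibroadenoma (eigenvalues
2.20, 2.00, 1.80 ×10⁻³ mm²/s), fit the tensor, and extract the lesion
features:

```python
import numpy as np
from breastdti import (make_gradient_scheme, PhantomConfig, PhantomRegion,
                       simulate_dwi_phantom, DiffusionTensorModel,
                       refine_roi, lesion_summary)

scheme = make_gradient_scheme()                 # 1 b=0 + 6 dirs at b=100, 800
config = PhantomConfig(
    grid_shape=(10, 10, 3),
    regions=(PhantomRegion(slices=((3, 7), (3, 7), (1, 2)),
                           evals=(2.20e-3, 2.00e-3, 1.80e-3),
                           direction=(0.0, 0.6, 0.8)),),
)
dwi, truth = simulate_dwi_phantom(config, scheme)
results = DiffusionTensorModel(dwi).fit()
print(results.summary())

roi = refine_roi(results.combined_dwi(800.0),
                 np.argwhere(truth.labels == "lesion"))
print(lesion_summary(results.scalar_maps, roi))
```

```
Diffusion tensor fit
--------------------
voxels fitted        : 300
voxels excluded      : 0 (non-positive signal)
eigenvalues clamped  : 0
mean ADC  (mm^2/s)   : 2.000e-03
mean FA              : 0.005
DTIFeatures(mean_adc=0.002000000000000001, mean_fa=0.099668324127764, ...,
            n_voxels=16)
```

The lesion ROI mean ADC is 2.00 ×10⁻³ mm²/s and mean FA is 0.10 — exactly
the scalar values implied by the generating eigenvalues (the map-wide mean
FA of 0.005 is low because the background is isotropic).

Cohort-level modeling on a synthetic study population (194 patients, 1–3
lesions each):

```python
from breastdti import (CohortConfig, simulate_cohort, prepare_features,
                       univariate_cluster_logistic)

cohort, truth = simulate_cohort(CohortConfig(n_patients=194, seed=7))
fm = prepare_features(cohort)          # log transforms + per-1-SD scaling
for f in ("mean_adc", "mean_fa", "washout"):
    r = univariate_cluster_logistic(fm, f)
    print(f"{f}: OR={r.odds_ratio:.2f} "
          f"(95% CI {r.ci[0]:.2f}-{r.ci[1]:.2f}), p={r.p:.4f}, AUC={r.auc:.2f}")
```

```
mean_adc: OR=0.41 (95% CI 0.30-0.55), p=0.0000, AUC=0.70
mean_fa: OR=1.72 (95% CI 1.31-2.26), p=0.0001, AUC=0.64
washout: OR=1.82 (95% CI 0.82-4.06), p=0.1436, AUC=0.53
```

Lower ADC and higher FA are associated with malignancy (ORs per 1-SD
increase, robust to within-patient lesion correlation), as built into the
generator.

The full pipeline (simulate → model → validate → report) also runs from the
command line:

```bash
breastdti run --seed 1 --out demo_run          # writes cohort.csv,
                                               # univariate.csv, multivariate.csv,
                                               # validation.csv, roc_*.csv,
                                               # manifest.json
breastdti fit-dti phantom.nii --out maps/      # NIfTI in, scalar maps out
```

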