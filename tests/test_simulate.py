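import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from breastdti.exceptions import ConfigError, InvalidTensorError
from breastdti.simulate import (
    CohortConfig,
    PhantomConfig,
    PhantomRegion,
    eigentriple_from_adc_fa,
    simulate_cohort,
    simulate_dwi_phantom,
    tensor_from_eigensystem,
)
from breastdti.tensor import fa_from_eigenvalues


def test_phantom_deterministic_given_seed(scheme):
    cfg = PhantomConfig(grid_shape=(4, 4, 2), noise_sigma=20.0, seed=9)
    a, _ = simulate_dwi_phantom(cfg, scheme)
    b, _ = simulate_dwi_phantom(cfg, scheme)
    assert np.array_equal(a.data, b.data)


def test_noiseless_signals_in_unit_interval_of_s0(scheme):
    cfg = PhantomConfig(grid_shape=(4, 4, 2))
    dwi, _ = simulate_dwi_phantom(cfg, scheme)
    assert np.all(dwi.data > 0)
    assert np.all(dwi.data <= cfg.s0 + 1e-12)


def test_rician_noise_keeps_signals_nonnegative(scheme):
    cfg = PhantomConfig(grid_shape=(6, 6, 2), noise_sigma=300.0,
                        noise_model="rician", seed=2)
    dwi, _ = simulate_dwi_phantom(cfg, scheme)
    assert np.all(dwi.data >= 0)


def test_invalid_tensor_requests_rejected():
    with pytest.raises(InvalidTensorError):
        tensor_from_eigensystem((1e-3, 2e-3, 0.5e-3), (1, 0, 0))  # unsorted
    with pytest.raises(InvalidTensorError):
        tensor_from_eigensystem((1e-3, 0.5e-3, -1e-4), (1, 0, 0))  # negative
    with pytest.raises(ConfigError):
        PhantomConfig(noise_sigma=-1.0)
    with pytest.raises(ConfigError):
        PhantomConfig(noise_model="poisson")


def test_cohort_deterministic_given_seed():
    cfg = CohortConfig(n_patients=50, seed=21)
    a, ta = simulate_cohort(cfg)
    b, tb = simulate_cohort(cfg)
    assert a.equals(b)
    assert np.array_equal(ta.linear_predictor, tb.linear_predictor)


def test_null_model_prevalence_hits_target():
    """With all slopes zero the calibrated intercept yields 40% malignancy."""
    cfg = CohortConfig(
        n_patients=10_000, outcome_coefficients={}, target_prevalence=0.40, seed=5
    )
    df, _ = simulate_cohort(cfg)
    assert abs(df["malignant"].mean() - 0.40) <= 0.01


def test_degenerate_lesion_count_distribution():
    cfg = CohortConfig(n_patients=40, lesions_per_patient_probs=(1.0, 0.0, 0.0),
                       seed=3)
    df, _ = simulate_cohort(cfg)
    assert (df.groupby("patient_id").size() == 1).all()
    assert len(df) == 40


def test_lesions_per_patient_matches_probabilities():
    cfg = CohortConfig(n_patients=5000, seed=13)
    df, _ = simulate_cohort(cfg)
    frac = df.groupby("patient_id").size().value_counts(normalize=True)
    assert frac[1] == pytest.approx(0.809, abs=0.02)
    assert frac[2] == pytest.approx(0.155, abs=0.02)


def test_class_conditional_adc_means():
    """Group ADC means match 1.26 / 1.55 (x1e-3 mm^2/s) within 2 SE at ~5000 lesions."""
    cfg = CohortConfig(n_patients=4200, seed=17)
    df, _ = simulate_cohort(cfg)
    for target, group in ((1.26, 1), (1.55, 0)):
        sub = df.loc[df.malignant == group, "mean_adc"]
        se = sub.std(ddof=1) / np.sqrt(len(sub))
        assert abs(sub.mean() - target) <= 2 * se


def test_malignant_adc_stochastically_smaller():
    cfg = CohortConfig(n_patients=2500, seed=29)
    df, _ = simulate_cohort(cfg)
    mal = df.loc[df.malignant == 1, "mean_adc"].to_numpy()[:1000]
    ben = df.loc[df.malignant == 0, "mean_adc"].to_numpy()[:1000]
    assert len(mal) == len(ben) == 1000
    p = mannwhitneyu(mal, ben, alternative="less").pvalue
    assert p < 1e-3


def test_unknown_outcome_coefficient_rejected():
    with pytest.raises(ConfigError):
        CohortConfig(outcome_coefficients={"mean_adc": -1.0})
    with pytest.raises(ConfigError):
        CohortConfig(lesions_per_patient_probs=(0.5, 0.4, 0.2))
    with pytest.raises(ConfigError):
        CohortConfig(n_patients=0)


def test_derived_eigentriple_consistent_with_adc_and_fa():
    """The prolate triple reproduces the generating ADC and FA exactly."""
    adc = np.array([1.2, 1.6, 2.0])
    fa = np.array([0.1, 0.3, 0.5])
    axial, radial, lam_diff = eigentriple_from_adc_fa(adc, fa)
    assert np.allclose((axial + 2 * radial) / 3, adc, rtol=1e-12)
    triples = np.stack([axial, radial, radial], axis=-1)
    assert np.allclose(fa_from_eigenvalues(triples), fa, rtol=1e-10)
    assert np.allclose(lam_diff, axial - radial, rtol=1e-12)


def test_cohort_dti_columns_internally_consistent():
    df, _ = simulate_cohort(CohortConfig(n_patients=200, seed=31))
    assert np.allclose(
        (df.mean_axial + 2 * df.mean_radial) / 3, df.mean_adc, rtol=1e-10
    )
    assert (df.mean_lambda_diff >= 0).all()
    assert df.mean_fa.between(0, 1).all()
    assert (df.size_cm > 0).all()
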