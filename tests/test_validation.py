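import numpy as np
import pandas as pd
import pytest

from breastdti.exceptions import UndefinedAUCError
from breastdti.simulate import CohortConfig, simulate_cohort
from breastdti.validation import (
    ConstantSpec,
    LogisticSpec,
    auc,
    bootstrap_auc_diff,
    bootstrap_optimism_auc,
    resample_patients,
    roc_coordinates,
)


def _noise_cohort(n_patients, n_features, seed, prevalence=0.4):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {f"n{i}": rng.normal(size=n_patients) for i in range(n_features)}
    )
    df["patient_id"] = np.arange(n_patients)
    df["malignant"] = (rng.random(n_patients) < prevalence).astype(int)
    if df["malignant"].nunique() < 2:  # pragma: no cover
        df.loc[0, "malignant"] = 1 - df.loc[0, "malignant"]
    return df


def test_perfect_separation_gives_auc_one():
    assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).apparent == 1.0


def test_binary_predictor_auc_is_mean_of_sens_and_spec():
    y = np.r_[np.ones(95), np.zeros(143)]
    x = np.r_[np.ones(87), np.zeros(8), np.ones(111), np.zeros(32)]
    expected = (87 / 95 + 32 / 143) / 2
    assert auc(x, y).apparent == pytest.approx(expected, abs=1e-12)


def test_null_scores_auc_half(rng):
    y = (rng.random(10_000) < 0.4).astype(int)
    s = rng.normal(size=10_000)
    assert abs(auc(s, y).apparent - 0.5) <= 0.02


def test_single_class_auc_undefined():
    with pytest.raises(UndefinedAUCError):
        auc([0.1, 0.2], [1, 1])


def test_roc_coordinates_monotone(rng):
    y = (rng.random(200) < 0.4).astype(int)
    s = rng.normal(size=200) + y
    roc = roc_coordinates(s, y)
    assert (np.diff(roc["sensitivity"]) >= 0).all()
    assert (np.diff(roc["one_minus_specificity"]) >= 0).all()


def test_patient_resample_preserves_lesion_multiplicity():
    df, _ = simulate_cohort(CohortConfig(n_patients=50, seed=3))
    rng = np.random.default_rng(0)
    boot = resample_patients(df, rng)
    assert boot["patient_id"].nunique() == df["patient_id"].nunique()
    # every resampled cluster is an intact copy of some original patient
    orig_sizes = df.groupby("patient_id").size()
    for _, grp in boot.groupby("patient_id"):
        assert len(grp) in set(orig_sizes.values)


def test_constant_score_has_no_optimism():
    df = _noise_cohort(60, 1, seed=1)
    est = bootstrap_optimism_auc(ConstantSpec(), df, B=50, seed=2)
    assert est.apparent == 0.5
    assert est.adjusted == 0.5


def test_optimism_reproducible_bit_for_bit():
    df = _noise_cohort(80, 5, seed=4)
    spec = LogisticSpec(tuple(f"n{i}" for i in range(5)))
    a = bootstrap_optimism_auc(spec, df, B=60, seed=9)
    b = bootstrap_optimism_auc(spec, df, B=60, seed=9)
    assert (a.apparent, a.adjusted, a.ci) == (b.apparent, b.adjusted, b.ci)


def test_optimism_positive_for_overfit_noise_model():
    df = _noise_cohort(100, 10, seed=6)
    spec = LogisticSpec(tuple(f"n{i}" for i in range(10)))
    est = bootstrap_optimism_auc(spec, df, B=100, seed=7)
    assert est.apparent > est.adjusted
    assert est.mean_optimism >= -0.01


def test_clustered_resampling_widens_ci():
    """Duplicating each patient's lesion 5x under one id vs distinct ids:
    patient-level resampling must widen the bootstrap CI under clustering."""
    base = _noise_cohort(60, 2, seed=11)
    clustered = pd.concat([base] * 5, ignore_index=True)
    clustered["patient_id"] = np.tile(base["patient_id"].to_numpy(), 5)
    independent = clustered.copy()
    independent["patient_id"] = np.arange(len(independent))
    spec = LogisticSpec(("n0", "n1"))
    ci_c = bootstrap_optimism_auc(spec, clustered, B=200, seed=13).ci
    ci_i = bootstrap_optimism_auc(spec, independent, B=200, seed=13).ci
    assert (ci_c[1] - ci_c[0]) > (ci_i[1] - ci_i[0])


def test_identical_specs_give_zero_delta():
    df = _noise_cohort(60, 2, seed=21)
    spec = LogisticSpec(("n0", "n1"))
    diff = bootstrap_auc_diff(spec, spec, df, B=40, seed=5)
    assert diff.delta == 0.0
    assert np.all(diff.deltas == 0.0)
    assert diff.p == 1.0


def test_null_extra_feature_delta_ci_covers_zero():
    """Adding a pure-noise feature to a nested spec: the ΔAUC CI covers 0 in
    >=9 of 10 seeded runs."""
    covered = 0
    for s in range(10):
        df, _ = simulate_cohort(CohortConfig(n_patients=150, seed=600 + s))
        rng = np.random.default_rng(s)
        df["noise"] = rng.normal(size=len(df))
        small = LogisticSpec(("mean_adc",))
        big = LogisticSpec(("mean_adc", "noise"))
        diff = bootstrap_auc_diff(big, small, df, B=100, seed=s)
        covered += diff.ci[0] <= 0.0 <= diff.ci[1]
    assert covered >= 9


def test_real_dti_signal_detected_over_clinical():
    """DTI features add real discrimination over clinical features: ΔAUC > 0
    with p < 0.05 in >=8 of 10 seeded runs at n=400 patients."""
    clinical = ("age", "dense", "washout", "birads5")
    wins = 0
    for s in range(10):
        df, _ = simulate_cohort(CohortConfig(n_patients=400, seed=700 + s))
        combined = LogisticSpec(clinical + ("mean_adc",))
        base = LogisticSpec(clinical)
        diff = bootstrap_auc_diff(combined, base, df, B=100, seed=s)
        wins += (diff.delta > 0) and (diff.p < 0.05)
    assert wins >= 8
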