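import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from breastdti.features import build_interactions, prepare_features
from breastdti.gee import (
    ClusterLogit,
    univariate_cluster_logistic,
    univariate_table,
    wald_compare_or,
)
from breastdti.simulate import CohortConfig, DTIClassConditional, simulate_cohort


def _counts_table(a, b, c, d):
    """Lesion table with a/b exposed among malignant/benign, c/d unexposed."""
    rows = []
    pid = 0
    for mal, x, n in ((1, 1, a), (0, 1, b), (1, 0, c), (0, 0, d)):
        for _ in range(n):
            rows.append({"patient_id": pid, "malignant": mal, "x": x})
            pid += 1
    return pd.DataFrame(rows)


@pytest.mark.parametrize("a, b, c, d", [(30, 10, 40, 60), (8, 3, 22, 47)])
def test_binary_or_equals_cross_product_ratio(a, b, c, d):
    df = _counts_table(a, b, c, d)
    res = ClusterLogit(df.malignant.to_numpy(), df[["x"]],
                       df.patient_id.to_numpy()).fit()
    assert res.odds_ratios.iloc[1] == pytest.approx(a * d / (b * c), rel=1e-6)


def test_sandwich_matches_hand_computed_cr0(cohort):
    """Robust SEs equal the hand-computed cluster sandwich on a real fit."""
    fm = prepare_features(cohort)
    X = np.column_stack(
        [np.ones(len(fm.y)), fm.standardized()[["mean_adc", "washout"]].to_numpy()]
    )
    y = fm.y.to_numpy().astype(float)
    groups = fm.groups.to_numpy()
    res = ClusterLogit(y, fm.standardized()[["mean_adc", "washout"]],
                       groups).fit()
    # independent oracle: GLM MLE + CR0 sandwich assembled from scratch
    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    p = glm.fittedvalues
    W = p * (1 - p)
    A = X.T @ (X * W[:, None])
    resid = y - p
    B = np.zeros((3, 3))
    for g in np.unique(groups):
        sg = (X[groups == g] * resid[groups == g, None]).sum(axis=0)
        B += np.outer(sg, sg)
    V = np.linalg.inv(A) @ B @ np.linalg.inv(A)
    assert np.allclose(res.params.to_numpy(), glm.params, atol=1e-6)
    assert np.allclose(res.bse.to_numpy(), np.sqrt(np.diag(V)), rtol=2e-2)


def test_separation_flagged():
    df = _counts_table(40, 0, 0, 40)  # perfectly separating predictor
    res = ClusterLogit(df.malignant.to_numpy(), df[["x"]],
                       df.patient_id.to_numpy()).fit()
    assert res.separation_flag


def test_univariate_result_structure(feature_matrix):
    r = univariate_cluster_logistic(feature_matrix, "mean_adc")
    assert r.per_sd
    assert r.ci[0] <= r.odds_ratio <= r.ci[1]
    assert 0.0 <= r.auc <= 1.0
    assert 0.0 <= r.p <= 1.0


def test_univariate_table_covers_all_features(feature_matrix):
    t = univariate_table(feature_matrix)
    assert set(t.index) == set(feature_matrix.feature_names)
    assert (t["ci_low"] <= t["OR"]).all() and (t["OR"] <= t["ci_high"]).all()


def test_or_ci_coverage_under_null():
    """A zero-coefficient feature's OR CI covers 1.0 in >=93/100 replicates."""
    covered = 0
    for s in range(100):
        df, _ = simulate_cohort(CohortConfig(n_patients=120, seed=9000 + s))
        fm = prepare_features(df, features=("post_menopausal",))
        r = univariate_cluster_logistic(fm, "post_menopausal")
        covered += r.ci[0] <= 1.0 <= r.ci[1]
    assert covered >= 93


def test_interaction_estimate_near_zero_for_identical_subgroups():
    """When FA behaves identically in masses and non-masses the interaction
    coefficient estimate is near zero."""
    dti = DTIClassConditional(
        fa_mass_malignant=(0.28, 0.14),
        fa_mass_benign=(0.23, 0.13),
        fa_nonmass_malignant=(0.28, 0.14),
        fa_nonmass_benign=(0.23, 0.13),
    )
    df, _ = simulate_cohort(CohortConfig(n_patients=2500, dti=dti, seed=77))
    fm = prepare_features(df, features=("mean_adc", "mean_fa", "mass"),
                          log_transform=("mean_fa",))
    fmi = build_interactions(fm, pairs=(("type", "mean_fa"),))
    res = ClusterLogit.from_feature_matrix(fmi).fit()
    w = wald_compare_or(res, "mass_x_mean_fa")
    assert abs(w.estimate) <= 2.5 * w.se
    assert abs(w.estimate) < 0.2


def test_opposite_fa_effects_detected_by_wald():
    """Opposite FA-malignancy associations by type yield a significant
    interaction and subgroup ORs on opposite sides of 1."""
    dti = DTIClassConditional(
        fa_mass_malignant=(0.32, 0.14),
        fa_mass_benign=(0.20, 0.11),
        fa_nonmass_malignant=(0.20, 0.11),
        fa_nonmass_benign=(0.30, 0.14),
    )
    df, _ = simulate_cohort(CohortConfig(n_patients=600, dti=dti, seed=55))
    fm = prepare_features(df, features=("mean_adc", "mean_fa", "mass"),
                          log_transform=("mean_fa",))
    fmi = build_interactions(fm, pairs=(("type", "mean_fa"),))
    res = ClusterLogit.from_feature_matrix(fmi).fit()
    w = wald_compare_or(res, "mass_x_mean_fa")
    assert w.p < 0.05
    or_nonmass = np.exp(res.params["mean_fa"])
    or_mass = np.exp(res.params["mean_fa"] + res.params["mass_x_mean_fa"])
    assert or_nonmass < 1.0 < or_mass


def test_wald_missing_interaction_raises(feature_matrix):
    res = ClusterLogit.from_feature_matrix(
        feature_matrix, features=["mean_adc"]
    ).fit()
    with pytest.raises(KeyError):
        wald_compare_or(res, "mass_x_mean_fa")


def test_predict_matches_fittedvalues(feature_matrix):
    res = ClusterLogit.from_feature_matrix(
        feature_matrix, features=["mean_adc", "washout"]
    ).fit()
    scores = res.predict(feature_matrix.standardized()[["mean_adc", "washout"]])
    assert np.allclose(scores, res.fittedvalues, atol=1e-10)


def test_summary_mentions_or_and_cluster_counts(feature_matrix):
    res = ClusterLogit.from_feature_matrix(feature_matrix,
                                           features=["mean_adc"]).fit()
    text = res.summary()
    assert "OR" in text and "patients" in text
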