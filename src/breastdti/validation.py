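"""ROC/AUC computation and bootstrap internal validation.

Apparent (resubstitution) discrimination of a model fitted and evaluated on
the same cohort is optimistic.  Optimism is estimated Harrell-style:
patients (not lesions) are resampled with replacement, the FULL fitting
procedure — including any penalty selection — is rerun on each resample, and
optimism_b = AUC(resample fit on resample) - AUC(resample fit on original).
The adjusted AUC is the apparent AUC minus the mean optimism.  Patient-level
resampling is also used to compare the AUCs of two model specifications on
paired resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import UndefinedAUCError

__all__ = [
    "AUCEstimate",
    "AUCDifference",
    "auc",
    "roc_coordinates",
    "ModelSpec",
    "LogisticSpec",
    "ConstantSpec",
    "bootstrap_optimism_auc",
    "bootstrap_auc_diff",
    "resample_patients",
]


@dataclass
class AUCEstimate:
    """Apparent and (optionally) optimism-adjusted AUC."""

    apparent: float
    adjusted: float | None = None
    ci: tuple[float, float] | None = None
    B: int | None = None
    seed: int | None = None
    mean_optimism: float | None = None
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.apparent <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        if self.ci is not None and not self.ci[0] <= self.ci[1]:
            raise ValueError("CI bounds must be ordered")


@dataclass
class AUCDifference:
    """Bootstrap comparison of two models' AUCs on paired patient resamples."""

    delta: float
    ci: tuple[float, float]
    p: float
    B: int
    seed: int | None
    normal_fallback: bool = False
    deltas: np.ndarray = field(default=None, repr=False)


def auc(scores, outcome) -> AUCEstimate:
    """Rank-based (Mann-Whitney) AUC with ties counted half.

    For a binary 0/1 predictor this equals (sensitivity + specificity)/2.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome)
    if np.unique(outcome).size < 2:
        raise UndefinedAUCError("AUC undefined with a single outcome class")
    return AUCEstimate(apparent=float(roc_auc_score(outcome, scores)))


def roc_coordinates(scores, outcome) -> pd.DataFrame:
    """ROC curve coordinates: threshold, sensitivity, 1-specificity."""
    fpr, tpr, thr = roc_curve(np.asarray(outcome), np.asarray(scores, dtype=float))
    return pd.DataFrame(
        {"threshold": thr, "sensitivity": tpr, "one_minus_specificity": fpr}
    )


class ModelSpec:
    """A refittable model specification for bootstrap validation.

    Subclasses implement ``fit(cohort) -> fitted`` where ``fitted`` has a
    ``predict_scores(cohort) -> (n,) array`` method.  The spec itself stays
    immutable so it can be refit on every bootstrap resample.
    """

    outcome: str = "malignant"

    def fit(self, cohort: pd.DataFrame):  # pragma: no cover - interface
        raise NotImplementedError


class _GLMFit:
    def __init__(self, spec: "LogisticSpec", params: np.ndarray):
        self.spec = spec
        self.params = params

    def predict_scores(self, cohort: pd.DataFrame) -> np.ndarray:
        X = self.spec.design(cohort)
        return 1.0 / (1.0 + np.exp(-(X @ self.params)))


class LogisticSpec(ModelSpec):
    """Unpenalized logistic model on a fixed feature list.

    Continuous features may be log-transformed via ``log_features``; scaling
    is irrelevant for discrimination so features enter on the analysis scale.
    """

    def __init__(
        self,
        features: tuple[str, ...],
        log_features: tuple[str, ...] = (),
        outcome: str = "malignant",
    ):
        self.features = tuple(features)
        self.log_features = tuple(log_features)
        self.outcome = outcome

    def design(self, cohort: pd.DataFrame) -> np.ndarray:
        X = cohort[list(self.features)].astype(float).copy()
        for name in self.log_features:
            X[name] = np.log(X[name])
        return np.column_stack([np.ones(len(X)), X.to_numpy()])

    def fit(self, cohort: pd.DataFrame) -> _GLMFit:
        X = self.design(cohort)
        y = cohort[self.outcome].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return _GLMFit(self, np.asarray(res.params))


class ConstantSpec(ModelSpec):
    """Deterministic constant score: a model that cannot overfit."""

    def __init__(self, value: float = 0.5, outcome: str = "malignant"):
        self.value = value
        self.outcome = outcome

    def fit(self, cohort: pd.DataFrame):
        value = self.value

        class _Fit:
            @staticmethod
            def predict_scores(c: pd.DataFrame) -> np.ndarray:
                return np.full(len(c), value)

        return _Fit()


def resample_patients(
    cohort: pd.DataFrame, rng: np.random.Generator, cluster: str = "patient_id"
) -> pd.DataFrame:
    """Patient-level bootstrap resample; drawn patients get fresh ids.

    A patient drawn twice contributes all their lesions twice, under two
    distinct new cluster ids, so downstream clustered fits see them as
    independent draws from the patient distribution.
    """
    ids = cohort[cluster].unique()
    draw = rng.choice(ids, size=ids.size, replace=True)
    indices = cohort.groupby(cluster, sort=False).indices
    rows = [indices[pid] for pid in draw]
    out = cohort.take(np.concatenate(rows)).reset_index(drop=True)
    out[cluster] = np.repeat(np.arange(len(draw)), [len(r) for r in rows])
    return out


def _resample_both_classes(
    cohort: pd.DataFrame, rng: np.random.Generator, outcome: str,
    max_redraws: int = 100,
) -> tuple[pd.DataFrame, int]:
    redraws = 0
    while True:
        boot = resample_patients(cohort, rng)
        if boot[outcome].nunique() > 1:
            return boot, redraws
        redraws += 1
        if redraws > max_redraws:  # pragma: no cover - pathological cohorts
            raise RuntimeError("could not draw a resample with both classes")


def bootstrap_optimism_auc(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
) -> AUCEstimate:
    """Harrell-style optimism-adjusted AUC with patient-level resampling.

    The percentile CI is taken from the B resample apparent AUCs.
    Resamples missing an outcome class are redrawn (counted in
    ``n_redrawn``).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    y = cohort[spec.outcome].to_numpy()
    full_fit = spec.fit(cohort)
    apparent = auc(full_fit.predict_scores(cohort), y).apparent

    optimism = np.empty(B)
    boot_apparent = np.empty(B)
    total_redraws = 0
    for b in range(B):
        boot, redraws = _resample_both_classes(cohort, rng, spec.outcome)
        total_redraws += redraws
        fit_b = spec.fit(boot)
        auc_boot = auc(fit_b.predict_scores(boot), boot[spec.outcome].to_numpy()).apparent
        auc_orig = auc(fit_b.predict_scores(cohort), y).apparent
        boot_apparent[b] = auc_boot
        optimism[b] = auc_boot - auc_orig

    mean_opt = float(optimism.mean())
    lo, hi = np.percentile(boot_apparent, [2.5, 97.5])
    return AUCEstimate(
        apparent=apparent,
        adjusted=float(np.clip(apparent - mean_opt, 0.0, 1.0)),
        ci=(float(lo), float(hi)),
        B=B,
        seed=seed,
        mean_optimism=mean_opt,
        n_redrawn=total_redraws,
    )


def bootstrap_auc_diff(
    spec_a: ModelSpec,
    spec_b: ModelSpec,
    cohort: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
) -> AUCDifference:
    """Paired patient-bootstrap comparison of two model AUCs (A minus B).

    Both specs are refit on each patient resample and their apparent AUCs on
    the resample differenced.  The CI is percentile-based; the p-value is
    twice the smaller tail mass of the bootstrap distribution beyond zero,
    capped at 1, with a normal approximation (flagged) when a tail is empty.
    """
    if spec_a.outcome != spec_b.outcome:
        raise ValueError("specs must share an outcome")
    rng = np.random.default_rng(seed)
    y = cohort[spec_a.outcome].to_numpy()
    delta_point = (
        auc(spec_a.fit(cohort).predict_scores(cohort), y).apparent
        - auc(spec_b.fit(cohort).predict_scores(cohort), y).apparent
    )
    deltas = np.empty(B)
    for b in range(B):
        boot, _ = _resample_both_classes(cohort, rng, spec_a.outcome)
        yb = boot[spec_a.outcome].to_numpy()
        a = auc(spec_a.fit(boot).predict_scores(boot), yb).apparent
        d = auc(spec_b.fit(boot).predict_scores(boot), yb).apparent
        deltas[b] = a - d

    lo, hi = np.percentile(deltas, [2.5, 97.5])
    tail_lo = float(np.mean(deltas <= 0))
    tail_hi = float(np.mean(deltas >= 0))
    fallback = False
    if min(tail_lo, tail_hi) == 0.0:
        sd = deltas.std(ddof=1)
        if sd == 0:
            p = 1.0 if delta_point == 0 else 1.0 / B
        else:
            p = float(2 * norm.sf(abs(deltas.mean()) / sd))
            fallback = True
        p = max(min(p, 1.0), np.nextafter(0, 1))
    else:
        p = min(1.0, 2.0 * min(tail_lo, tail_hi))
    return AUCDifference(
        delta=float(delta_point),
        ci=(float(lo), float(hi)),
        p=p,
        B=B,
        seed=seed,
        normal_fallback=fallback,
        deltas=deltas,
    )
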