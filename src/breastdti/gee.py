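"""Cluster-robust logistic regression (GEE with independence working correlation).

Lesions from the same patient are correlated, so univariate and multivariate
logistic models use generalized estimating equations with an independence
working correlation and a robust (sandwich) covariance clustered by patient.
With independence working correlation the point estimates equal ordinary
logistic MLEs — in particular, for a single binary predictor the fitted OR
equals the 2x2 cross-product ratio — while standard errors account for
within-patient correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import FeatureMatrix
from .validation import auc as _auc

__all__ = [
    "ClusterLogit",
    "ClusterLogitResults",
    "UnivariateResult",
    "univariate_cluster_logistic",
    "univariate_table",
    "WaldTest",
    "wald_compare_or",
]

#: |coefficient| beyond which a fit is flagged as (quasi-)separated.
_SEPARATION_COEF = 15.0


class ClusterLogit:
    """Logistic model with cluster-robust inference.

    Parameters
    ----------
    endog : (n,) 0/1 outcomes.
    exog : (n, p) DataFrame or array of predictors (no constant column;
        an intercept is added automatically).
    groups : (n,) cluster labels (patient ids).

    ``fit()`` returns a :class:`ClusterLogitResults`.
    """

    def __init__(self, endog, exog, groups):
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        else:
            exog = np.asarray(exog, dtype=float)
            if exog.ndim == 1:
                exog = exog[:, None]
            self.exog_names = [f"x{i}" for i in range(exog.shape[1])]
        self.endog = np.asarray(endog, dtype=float)
        if set(np.unique(self.endog)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if np.unique(self.endog).size < 2:
            raise ValueError("both outcome classes must be present")
        self.exog = np.column_stack([np.ones(len(self.endog)), exog])
        self.param_names = ["intercept", *self.exog_names]
        self.groups = np.asarray(groups)

    @classmethod
    def from_feature_matrix(
        cls, fm: FeatureMatrix, features: list[str] | None = None,
        standardized: bool = True,
    ) -> "ClusterLogit":
        X = fm.standardized() if standardized else fm.X
        if features is not None:
            X = X[list(features)]
        return cls(fm.y.to_numpy(), X, fm.groups.to_numpy())

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, features: list[str],
        outcome: str = "malignant", cluster: str = "patient_id",
    ) -> "ClusterLogit":
        return cls(df[outcome].to_numpy(), df[list(features)], df[cluster].to_numpy())

    def fit(self) -> "ClusterLogitResults":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(
                self.endog,
                self.exog,
                groups=self.groups,
                family=sm.families.Binomial(),
                cov_struct=sm.cov_struct.Independence(),
            )
            res = model.fit()
        return ClusterLogitResults(self, res)


@dataclass
class ClusterLogitResults:
    """Fitted cluster-robust logistic model."""

    model: ClusterLogit
    _res: object

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.params), index=self.model.param_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.bse), index=self.model.param_names)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.pvalues), index=self.model.param_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = np.asarray(self._res.conf_int(alpha=alpha))
        return pd.DataFrame(ci, index=self.model.param_names, columns=["lower", "upper"])

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def separation_flag(self) -> bool:
        """True when the fit looks (quasi-)separated: ORs are unreliable/infinite."""
        return bool(
            np.any(np.abs(self.params.to_numpy()[1:]) > _SEPARATION_COEF)
            or not np.all(np.isfinite(self.bse.to_numpy()))
        )

    def predict(self, exog: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Predicted malignancy probability for new lesions (no constant column)."""
        if isinstance(exog, pd.DataFrame):
            exog = exog[self.model.exog_names].to_numpy(dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        lp = self.params.to_numpy()[0] + exog @ self.params.to_numpy()[1:]
        return 1.0 / (1.0 + np.exp(-lp))

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._res.fittedvalues)

    def wald_test_term(self, name: str) -> "WaldTest":
        """Two-sided z-test (robust SE) that the named coefficient is zero."""
        if name not in self.model.param_names:
            raise KeyError(f"no term {name!r} in the model")
        est = float(self.params[name])
        se = float(self.bse[name])
        z = est / se
        from scipy.stats import norm

        return WaldTest(term=name, estimate=est, se=se, z=z,
                        p=float(2 * norm.sf(abs(z))))

    def summary(self) -> str:
        df = pd.DataFrame(
            {
                "coef": self.params,
                "robust_se": self.bse,
                "OR": self.odds_ratios,
                "ci_low": np.exp(self.conf_int()["lower"]),
                "ci_high": np.exp(self.conf_int()["upper"]),
                "p": self.pvalues,
            }
        )
        header = "Cluster-robust logistic regression (independence GEE)\n"
        header += f"lesions: {len(self.model.endog)}   patients: {len(np.unique(self.model.groups))}\n"
        if self.separation_flag:
            header += "WARNING: separation suspected; ORs unreliable\n"
        return header + df.to_string(float_format=lambda v: f"{v:.4g}")


@dataclass
class UnivariateResult:
    """One row of the univariate analysis table."""

    feature: str
    odds_ratio: float
    ci: tuple[float, float]
    p: float
    auc: float
    per_sd: bool
    separation: bool = False

    @property
    def infinite_or(self) -> bool:
        return self.separation


def univariate_cluster_logistic(
    fm: FeatureMatrix, feature: str
) -> UnivariateResult:
    """Univariate cluster-robust logistic OR (per 1-SD for continuous) plus AUC."""
    per_sd = fm.sds[feature] != 1.0
    x = (fm.X[feature] / fm.sds[feature]).to_numpy()
    res = ClusterLogit(fm.y.to_numpy(), x[:, None], fm.groups.to_numpy()).fit()
    ci = res.conf_int().iloc[1]
    # rank-based AUC of the raw feature, oriented so AUC >= is not forced
    scores = fm.X[feature].to_numpy()
    if res.params.iloc[1] < 0:
        scores = -scores
    est = _auc(scores, fm.y.to_numpy())
    return UnivariateResult(
        feature=feature,
        odds_ratio=float(res.odds_ratios.iloc[1]),
        ci=(float(np.exp(ci["lower"])), float(np.exp(ci["upper"]))),
        p=float(res.pvalues.iloc[1]),
        auc=est.apparent,
        per_sd=bool(per_sd),
        separation=res.separation_flag,
    )


def univariate_table(fm: FeatureMatrix) -> pd.DataFrame:
    """Univariate OR/AUC table over every feature of a feature matrix."""
    rows = []
    for name in fm.feature_names:
        r = univariate_cluster_logistic(fm, name)
        rows.append(
            {
                "feature": name,
                "OR": r.odds_ratio,
                "ci_low": r.ci[0],
                "ci_high": r.ci[1],
                "p": r.p,
                "AUC": r.auc,
                "per_sd": r.per_sd,
                "separation": r.separation,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class WaldTest:
    """Two-sided Wald test of a single coefficient with cluster-robust SE."""

    term: str
    estimate: float
    se: float
    z: float
    p: float


def wald_compare_or(results: ClusterLogitResults, interaction: str) -> WaldTest:
    """Compare subgroup ORs via the interaction coefficient.

    The difference of subgroup log-odds (e.g. masses vs non-masses for FA)
    equals the interaction coefficient, so a z-test on that coefficient with
    cluster-robust SE compares the two subgroup ORs.
    """
    if interaction not in results.model.param_names:
        raise KeyError(
            f"model has no interaction term {interaction!r}; "
            f"available: {results.model.param_names}"
        )
    return results.wald_test_term(interaction)
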