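"""L1-penalized logistic regression with leave-one-patient-out cross-validation.

The multivariate diagnostic models are LASSO logistic regressions: the L1
penalty simultaneously shrinks coefficients and performs variable selection
("NS" features have exactly-zero coefficients).  The penalty parameter
``alpha`` (glmnet scale: the objective is mean deviance / 2... precisely
``(1/n) sum logloss + alpha * ||beta||_1``) is selected to minimize the
held-out binomial deviance accumulated over leave-one-patient-out folds,
then the model is refit on all data at the selected penalty.

Continuous features are standardized to unit SD before entering the solver
(via :meth:`FeatureMatrix.standardized`), so fitted log-odds for continuous
features are per 1-SD; binary features enter raw.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .features import FeatureMatrix

__all__ = ["LassoLogitCV", "LassoLogitCVResults", "make_penalty_grid", "LassoSpec"]

logger = logging.getLogger(__name__)

_EPS = 1e-12


def make_penalty_grid(
    X: np.ndarray, y: np.ndarray, n_grid: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """glmnet-style penalty grid, descending.

    ``alpha_max = max_j |x_j . (y - ybar)| / n`` is the smallest penalty
    zeroing every coefficient; the grid is log-spaced from there down to
    ``min_ratio * alpha_max``.
    """
    y = np.asarray(y, dtype=float)
    r = y - y.mean()
    alpha_max = np.max(np.abs(X.T @ r)) / len(y)
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.geomspace(alpha_max, alpha_max * min_ratio, n_grid)


def _fit_l1(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """One L1-penalized logistic fit; returns (coef, intercept).

    alpha == 0 is routed to an unpenalized GLM fit (exact MLE).
    """
    if alpha == 0.0:
        Xc = np.column_stack([np.ones(len(y)), X])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
        p = np.asarray(res.params)
        return p[1:], float(p[0])
    C = 1.0 / (len(y) * alpha)
    clf = LogisticRegression(
        solver="liblinear",
        l1_ratio=1.0,
        C=C,
        intercept_scaling=1e4,  # keep the intercept effectively unpenalized
        tol=1e-8,
        max_iter=1000,
        random_state=0,  # liblinear's coordinate order is stochastic
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        clf.fit(X, y)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            raise RuntimeError("liblinear did not converge")
    return clf.coef_.ravel(), float(clf.intercept_[0])


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


class LassoLogitCV:
    """LASSO logistic model with patient-clustered cross-validated penalty.

    Parameters
    ----------
    X : (n, p) standardized design (continuous columns at unit SD).
    y : (n,) 0/1 outcomes.
    groups : (n,) patient ids; cross-validation folds never split a patient.
    penalty_grid : array, optional
        Descending penalties to search; built by :func:`make_penalty_grid`
        when omitted.
    n_grid, min_ratio :
        Grid construction parameters (default 100 points down to 1e-4 of
        the all-zero penalty).
    cv : "lopo" or int
        Leave-one-patient-out (default) or grouped K-fold by patient for
        large cohorts.
    """

    def __init__(
        self,
        X,
        y,
        groups,
        penalty_grid: np.ndarray | None = None,
        n_grid: int = 100,
        min_ratio: float = 1e-4,
        cv: str | int = "lopo",
    ):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = [f"x{i}" for i in range(X.shape[1])]
        self.X = X
        self.y = np.asarray(y, dtype=float)
        self.groups = np.asarray(groups)
        if np.unique(self.groups).size < 2:
            raise ValueError("need >= 2 patients for cross-validation")
        if penalty_grid is None:
            penalty_grid = make_penalty_grid(self.X, self.y, n_grid, min_ratio)
        penalty_grid = np.sort(np.asarray(penalty_grid, dtype=float))[::-1]
        if penalty_grid.size == 0:
            raise ValueError("penalty grid is empty")
        self.penalty_grid = penalty_grid
        self.cv = cv

    @classmethod
    def from_feature_matrix(
        cls, fm: FeatureMatrix, features: list[str] | None = None, **kwargs
    ) -> "LassoLogitCV":
        X = fm.standardized()
        if features is not None:
            X = X[list(features)]
        return cls(X, fm.y.to_numpy(), fm.groups.to_numpy(), **kwargs)

    def _folds(self):
        ids = np.unique(self.groups)
        if self.cv == "lopo":
            for pid in ids:
                yield self.groups != pid
        else:
            k = int(self.cv)
            for part in np.array_split(ids, k):
                yield ~np.isin(self.groups, part)

    def fit(self) -> "LassoLogitCVResults":
        grid = self.penalty_grid
        dev = np.zeros(grid.size)
        failed = np.zeros(grid.size, dtype=bool)
        for train in self._folds():
            test = ~train
            Xtr, ytr = self.X[train], self.y[train]
            if np.unique(ytr).size < 2:
                # a fold may hold out the only case of one class at tiny n;
                # predict the training mean for every penalty
                p = np.full(test.sum(), ytr.mean())
                dev += _deviance(self.y[test], p)
                continue
            for i, alpha in enumerate(grid):
                if failed[i]:
                    continue
                try:
                    coef, b0 = _fit_l1(Xtr, ytr, alpha)
                except RuntimeError:
                    logger.warning("penalty %.3g skipped: solver did not converge", alpha)
                    failed[i] = True
                    dev[i] = np.inf
                    continue
                p = 1.0 / (1.0 + np.exp(-(b0 + self.X[test] @ coef)))
                dev[i] += _deviance(self.y[test], p)
        dev[failed] = np.inf
        best = int(np.argmin(dev))  # grid descending: ties favor larger penalty
        alpha = float(grid[best])
        coef, b0 = _fit_l1(self.X, self.y, alpha)
        return LassoLogitCVResults(
            model=self,
            coef=pd.Series(coef, index=self.feature_names),
            intercept=b0,
            alpha=alpha,
            cv_deviance=pd.Series(dev, index=grid),
        )


@dataclass
class LassoLogitCVResults:
    """Fitted LASSO logistic model at the CV-selected penalty."""

    model: LassoLogitCV
    coef: pd.Series
    intercept: float
    alpha: float
    cv_deviance: pd.Series

    @property
    def selected(self) -> list[str]:
        return list(self.coef.index[np.abs(self.coef.to_numpy()) > _EPS])

    @property
    def not_selected(self) -> list[str]:
        return [f for f in self.coef.index if f not in self.selected]

    @property
    def odds_ratios(self) -> pd.Series:
        """OR per 1-SD for continuous features; exactly 1 for unselected."""
        return np.exp(self.coef)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.model.feature_names].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.intercept + X @ self.coef.to_numpy())))

    def summary(self) -> str:
        rows = []
        for name in self.coef.index:
            if name in self.selected:
                rows.append(f"  {name:<22s} OR = {np.exp(self.coef[name]):.3f}")
            else:
                rows.append(f"  {name:<22s} NS")
        return (
            "LASSO logistic regression (penalty by patient-clustered CV)\n"
            f"selected penalty alpha = {self.alpha:.4g} "
            f"(grid of {self.cv_deviance.size})\n" + "\n".join(rows)
        )


class LassoSpec:
    """Refittable LASSO model spec for bootstrap validation.

    By default the penalty is re-selected by cross-validation inside every
    refit (honest validation).  ``reselect_penalty=False`` is a fast mode
    that fixes the penalty at the value selected on the full data; it is for
    exploratory runs only.
    """

    def __init__(
        self,
        features: tuple[str, ...],
        log_features: tuple[str, ...] = (),
        outcome: str = "malignant",
        cluster: str = "patient_id",
        n_grid: int = 100,
        min_ratio: float = 1e-4,
        cv: str | int = "lopo",
        reselect_penalty: bool = True,
    ):
        from .features import prepare_features  # deferred: features imports nothing back

        self._prepare = prepare_features
        self.features = tuple(features)
        self.log_features = tuple(log_features)
        self.outcome = outcome
        self.cluster = cluster
        self.n_grid = n_grid
        self.min_ratio = min_ratio
        self.cv = cv
        self.reselect_penalty = reselect_penalty
        self._fixed_alpha: float | None = None

    def _feature_matrix(self, cohort: pd.DataFrame) -> FeatureMatrix:
        return self._prepare(
            cohort,
            features=self.features,
            log_transform=self.log_features,
            outcome=self.outcome,
            cluster=self.cluster,
        )

    def fit(self, cohort: pd.DataFrame):
        fm = self._feature_matrix(cohort)
        model = LassoLogitCV.from_feature_matrix(
            fm, n_grid=self.n_grid, min_ratio=self.min_ratio, cv=self.cv
        )
        if not self.reselect_penalty and self._fixed_alpha is not None:
            coef, b0 = _fit_l1(model.X, model.y, self._fixed_alpha)
            res = LassoLogitCVResults(
                model=model,
                coef=pd.Series(coef, index=model.feature_names),
                intercept=b0,
                alpha=self._fixed_alpha,
                cv_deviance=pd.Series(dtype=float),
            )
        else:
            res = model.fit()
            if not self.reselect_penalty:
                self._fixed_alpha = res.alpha
        spec = self

        class _Fit:
            def __init__(self, res, sds):
                self.results = res
                self._sds = sds

            def predict_scores(self, c: pd.DataFrame) -> np.ndarray:
                fm_new = spec._feature_matrix(c)
                # scale new data by the TRAINING SDs, not its own
                X = fm_new.X / self._sds
                return self.results.predict(X)

        return _Fit(res, fm.sds)
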