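"""Feature preparation for the diagnostic models.

Continuous predictors are put on their analysis scale (natural-log transform
for right-skewed variables: lesion size, FA, lambda1-lambda3 by default) and
their SDs recorded so that fitted log-odds can be reported per 1-SD
increase.  Binary predictors pass through untransformed and unscaled; BPE
enters as an ordinal 1-4 score per category.  Interaction terms dichotomize
size at 1 cm and lesion type as mass vs non-mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, TransformError

__all__ = [
    "FeatureMatrix",
    "prepare_features",
    "build_interactions",
    "spearman_matrix",
    "CLINICAL_DCE_FEATURES",
    "DTI_FEATURES",
    "DEFAULT_LOG_FEATURES",
    "INTERACTION_PAIRS",
]

#: Candidate predictor sets of the three primary models.
CLINICAL_DCE_FEATURES = (
    "age",
    "post_menopausal",
    "known_cancer",
    "dense",
    "bpe",
    "size_cm",
    "mass",
    "washout",
    "birads5",
)
DTI_FEATURES = ("mean_adc", "mean_fa")

#: Right-skewed features log-transformed by default.
DEFAULT_LOG_FEATURES = ("size_cm", "mean_fa", "mean_lambda_diff")

#: Features entering per 1-SD (continuous); bpe is per-category, binaries raw.
_PER_SD_FEATURES = (
    "age",
    "size_cm",
    "mean_adc",
    "mean_fa",
    "mean_axial",
    "mean_radial",
    "mean_lambda_diff",
)

#: Supported (dichotomy, continuous) interaction pairs.
INTERACTION_PAIRS = {
    ("size", "mean_adc"),
    ("type", "mean_adc"),
    ("size", "mean_fa"),
    ("type", "mean_fa"),
}


@dataclass
class FeatureMatrix:
    """Analysis-ready design information for the diagnostic models.

    Attributes
    ----------
    X : DataFrame
        Features on the analysis scale (log-transformed where registered),
        unscaled.
    y : Series of 0/1 outcomes.
    groups : Series of patient ids (cluster labels).
    sds : Series
        Per-feature scale divisors: the SD on the analysis scale for
        continuous features, 1.0 for binary/ordinal features.
    transforms : dict
        feature name -> "log" for log-transformed features.
    raw : DataFrame
        The original cohort slice (used e.g. to dichotomize size at 1 cm).
    collinear : list of str
        Interaction columns flagged as collinear with an existing column.
    """

    X: pd.DataFrame
    y: pd.Series
    groups: pd.Series
    sds: pd.Series
    transforms: dict[str, str]
    raw: pd.DataFrame
    collinear: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def standardized(self) -> pd.DataFrame:
        """Features divided by their recorded SDs (per-1-SD coefficient scale)."""
        return self.X / self.sds

    def subset(self, features: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[list(features)],
            y=self.y,
            groups=self.groups,
            sds=self.sds[list(features)],
            transforms={k: v for k, v in self.transforms.items() if k in features},
            raw=self.raw,
            collinear=[c for c in self.collinear if c in features],
        )


def prepare_features(
    cohort: pd.DataFrame,
    features: tuple[str, ...] = CLINICAL_DCE_FEATURES + DTI_FEATURES,
    log_transform: tuple[str, ...] = DEFAULT_LOG_FEATURES,
    outcome: str = "malignant",
    cluster: str = "patient_id",
) -> FeatureMatrix:
    """Assemble the feature matrix for modeling.

    Raises
    ------
    TransformError
        If a feature listed in ``log_transform`` has non-positive values
        (the offending lesions are named).
    """
    missing = [c for c in (*features, outcome, cluster) if c not in cohort.columns]
    if missing:
        raise ConfigError(f"cohort table lacks columns: {missing}")
    X = cohort[list(features)].astype(float).copy()
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ConfigError(f"missing values in features: {bad}")
    transforms: dict[str, str] = {}
    for name in log_transform:
        if name not in X.columns:
            continue
        vals = X[name]
        if (vals <= 0).any():
            lesions = cohort.loc[vals <= 0].index.tolist()
            if "lesion_id" in cohort.columns:
                lesions = cohort.loc[vals <= 0, "lesion_id"].tolist()
            raise TransformError(
                f"cannot log-transform {name!r}: non-positive values at lesions {lesions}"
            )
        X[name] = np.log(vals)
        transforms[name] = "log"

    sds = pd.Series(1.0, index=X.columns)
    for name in X.columns:
        if name in _PER_SD_FEATURES:
            sd = float(X[name].std(ddof=1))
            if not sd > 0:
                raise ConfigError(f"feature {name!r} has zero variance")
            sds[name] = sd

    return FeatureMatrix(
        X=X,
        y=cohort[outcome].astype(int),
        groups=cohort[cluster],
        sds=sds,
        transforms=transforms,
        raw=cohort,
    )


def build_interactions(
    fm: FeatureMatrix,
    pairs: tuple[tuple[str, str], ...] = (
        ("size", "mean_adc"),
        ("type", "mean_adc"),
        ("size", "mean_fa"),
        ("type", "mean_fa"),
    ),
    size_cutoff_cm: float = 1.0,
) -> FeatureMatrix:
    """Append dichotomy x DTI interaction columns to a feature matrix.

    ``size`` dichotomizes lesion size at ``size_cutoff_cm`` on the original
    (cm) scale; ``type`` is mass vs non-mass (foci grouped with non-mass).
    The interaction column is the product of the 0/1 dichotomy and the
    continuous feature, so the subgroup log-odds per 1-SD is the sum of the
    main and interaction coefficients.
    """
    X = fm.X.copy()
    sds = fm.sds.copy()
    collinear = list(fm.collinear)
    for dich, cont in pairs:
        if (dich, cont) not in INTERACTION_PAIRS:
            raise ConfigError(f"unsupported interaction pair {(dich, cont)!r}")
        if cont not in X.columns:
            raise ConfigError(f"interaction references absent feature {cont!r}")
        if dich == "size":
            flag = (fm.raw["size_cm"].astype(float) >= size_cutoff_cm).astype(float)
            colname = f"large_x_{cont}"
        else:
            flag = fm.raw["mass"].astype(float)
            colname = f"mass_x_{cont}"
        col = flag.to_numpy() * X[cont].to_numpy()
        X[colname] = col
        sds[colname] = sds[cont]  # same per-SD scale as the main effect
        if flag.nunique() == 1 or np.allclose(col, X[cont].to_numpy()):
            collinear.append(colname)
            warnings.warn(
                f"interaction {colname} is collinear with {cont} "
                "(degenerate subgroup)",
                stacklevel=2,
            )
    return FeatureMatrix(
        X=X,
        y=fm.y,
        groups=fm.groups,
        sds=sds,
        transforms=dict(fm.transforms),
        raw=fm.raw,
        collinear=collinear,
    )


def spearman_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (constant columns yield NaN)."""
    if len(features) < 3:
        raise ValueError("Spearman correlation needs >= 3 lesions")
    out = features.corr(method="spearman")
    constant = features.columns[features.nunique() <= 1]
    out.loc[constant, :] = np.nan
    out.loc[:, constant] = np.nan
    np.fill_diagonal(out.values, 1.0)
    for c in constant:  # a constant feature has no defined self-correlation
        out.loc[c, c] = np.nan
    return out
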