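"""Synthetic data generators: DWI phantoms, DCE curves, and lesion cohorts.

Every downstream stage of the pipeline is testable without patient data via
three generators with known ground truth:

* :func:`simulate_dwi_phantom` — a voxel grid of known diffusion tensors
  observed through the signal model ``S = S0 exp(-b g^T D g)`` with optional
  Gaussian or Rician noise.
* :func:`simulate_dce_lesion` — enhancement time-courses (pre-contrast plus
  120/300/480 s post-contrast) whose noiseless curves satisfy the defining
  inequality of their kinetic class with margin.
* :func:`simulate_cohort` — a clustered lesion cohort emulating the study
  population: 1-3 lesions per patient, clinical/DCE covariates, malignancy
  drawn from a logistic model with a patient-level Gaussian random intercept,
  and DTI features drawn from class-conditional distributions (benign /
  malignant mean ADC 1.55 / 1.26 x10^-3 mm^2/s) with an ADC-FA Gaussian
  copula inducing their negative correlation.

All generators are deterministic given their config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigError, InvalidTensorError
from .gradients import GradientScheme
from .kinetics import KineticClass
from .tensor import DWIVolume

__all__ = [
    "PhantomRegion",
    "PhantomConfig",
    "PhantomTruth",
    "simulate_dwi_phantom",
    "tensor_from_eigensystem",
    "DCECurveSet",
    "simulate_dce_lesion",
    "CovariateConfig",
    "DTIClassConditional",
    "CohortConfig",
    "CohortTruth",
    "simulate_cohort",
    "calibrate_intercept",
    "eigentriple_from_adc_fa",
    "OUTCOME_FEATURES",
]

# --------------------------------------------------------------------------
# DWI phantom
# --------------------------------------------------------------------------


def tensor_from_eigensystem(evals, direction) -> np.ndarray:
    """Symmetric 3x3 tensor with eigenvalues ``evals`` (descending) and
    principal eigenvector ``direction``.

    Raises :class:`InvalidTensorError` for non-positive or unsorted
    eigenvalue triples.
    """
    lam = np.asarray(evals, dtype=float)
    if lam.shape != (3,):
        raise InvalidTensorError("eigenvalue triple must have length 3")
    if np.any(lam <= 0):
        raise InvalidTensorError(f"eigenvalues must be positive, got {lam}")
    if not (lam[0] >= lam[1] >= lam[2]):
        raise InvalidTensorError(f"eigenvalues must be sorted descending, got {lam}")
    e1 = np.asarray(direction, dtype=float)
    n = np.linalg.norm(e1)
    if n == 0:
        raise InvalidTensorError("principal direction must be non-zero")
    e1 = e1 / n
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    return R @ np.diag(lam) @ R.T


@dataclass(frozen=True)
class PhantomRegion:
    """An axis-aligned box of voxels sharing one diffusion tensor."""

    slices: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    evals: tuple[float, float, float]
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    label: str = "lesion"


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of a DWI phantom.

    ``background_evals`` defaults to isotropic diffusion typical of normal
    fibroglandular tissue (2.0 x10^-3 mm^2/s).  ``noise_sigma`` is the
    additive noise scale in the same units as ``s0``.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 4)
    regions: tuple[PhantomRegion, ...] = ()
    background_evals: tuple[float, float, float] = (2.0e-3, 2.0e-3, 2.0e-3)
    s0: float = 1000.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigError(f"unknown noise model {self.noise_model!r}")


@dataclass
class PhantomTruth:
    """Ground truth of a simulated phantom: per-voxel tensors and labels."""

    tensors: np.ndarray  # (x, y, z, 3, 3)
    evals: np.ndarray  # (x, y, z, 3) descending
    labels: np.ndarray  # (x, y, z) region label strings


def simulate_dwi_phantom(
    config: PhantomConfig, scheme: GradientScheme
) -> tuple[DWIVolume, PhantomTruth]:
    """Forward-simulate DWI from a piecewise-constant tensor field.

    The noiseless signal per voxel and acquisition is
    ``S = s0 * exp(-b g^T D g)``; Gaussian noise adds N(0, sigma) per
    acquisition, Rician noise replaces S with
    ``sqrt((S + n1)^2 + n2^2)`` for independent N(0, sigma) n1, n2
    (magnitude-image realism, always >= 0).
    """
    scheme.check_full_rank()
    shape = tuple(config.grid_shape)
    tensors = np.empty(shape + (3, 3))
    evals = np.empty(shape + (3,))
    labels = np.full(shape, "background", dtype=object)

    bg = tensor_from_eigensystem(np.sort(config.background_evals)[::-1], (1, 0, 0))
    tensors[...] = bg
    evals[...] = np.sort(config.background_evals)[::-1]
    for region in config.regions:
        D = tensor_from_eigensystem(region.evals, region.direction)
        (x0, x1), (y0, y1), (z0, z1) = region.slices
        tensors[x0:x1, y0:y1, z0:z1] = D
        evals[x0:x1, y0:y1, z0:z1] = np.sort(region.evals)[::-1]
        labels[x0:x1, y0:y1, z0:z1] = region.label

    b = scheme.bvals  # (m,)
    g = scheme.bvecs  # (m, 3)
    # quadratic form g^T D g for every voxel/acquisition
    q = np.einsum("mi,...ij,mj->...m", g, tensors, g)
    signal = config.s0 * np.exp(-b * q)

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        if config.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, config.noise_sigma, signal.shape)
        else:  # rician
            n1 = rng.normal(0.0, config.noise_sigma, signal.shape)
            n2 = rng.normal(0.0, config.noise_sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)

    dwi = DWIVolume(signal, scheme)
    return dwi, PhantomTruth(tensors=tensors, evals=evals, labels=labels)


# --------------------------------------------------------------------------
# DCE curves
# --------------------------------------------------------------------------

#: Acquisition times in seconds: pre-contrast, then three post-contrast scans.
DCE_TIMES = (0.0, 120.0, 300.0, 480.0)

# Class-conditional noiseless curve templates as multiples of baseline signal.
# Each satisfies its defining inequality with margin: washout falls 25% from
# 120 s to 480 s, plateau changes +2%, persistent rises 39%.
_DCE_TEMPLATES = {
    KineticClass.WASHOUT: (1.0, 2.50, 2.20, 1.875),
    KineticClass.PLATEAU: (1.0, 2.30, 2.32, 2.35),
    KineticClass.PERSISTENT: (1.0, 1.80, 2.15, 2.50),
}


@dataclass
class DCECurveSet:
    """Per-voxel enhancement curves at the four acquisition times."""

    times: np.ndarray  # (4,)
    signals: np.ndarray  # (n_voxels, 4)
    kinetic_class: KineticClass

    @property
    def s_initial(self) -> np.ndarray:
        return self.signals[:, 1]

    @property
    def s_final(self) -> np.ndarray:
        return self.signals[:, 3]


def simulate_dce_lesion(
    kinetic_class: KineticClass | str,
    n_voxels: int = 1,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    baseline: float = 100.0,
) -> DCECurveSet:
    """Simulate per-voxel DCE time-courses of a given kinetic class."""
    if isinstance(kinetic_class, str):
        kinetic_class = KineticClass[kinetic_class.upper()]
    if n_voxels < 1:
        raise ConfigError("n_voxels must be >= 1")
    if noise_sigma < 0:
        raise ConfigError("noise_sigma must be >= 0")
    template = np.array(_DCE_TEMPLATES[kinetic_class]) * baseline
    signals = np.tile(template, (n_voxels, 1))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signals = signals + rng.normal(0.0, noise_sigma, signals.shape)
    return DCECurveSet(np.array(DCE_TIMES), signals, kinetic_class)


# --------------------------------------------------------------------------
# Lesion cohort
# --------------------------------------------------------------------------

#: Features the outcome logistic model may reference.  Continuous features
#: (age, log_size) enter standardized, bpe enters centered per-category,
#: binaries enter raw 0/1.
OUTCOME_FEATURES = (
    "age",
    "post_menopausal",
    "known_cancer",
    "dense",
    "bpe",
    "log_size",
    "mass",
    "washout",
    "birads5",
)


@dataclass(frozen=True)
class CovariateConfig:
    """Marginal distributions of the clinical/DCE covariates.

    Defaults emulate the study cohort: median age ~51, ~52% post-menopausal,
    ~65% known-cancer indication, ~73% dense breasts, BPE categories
    minimal/mild/moderate/marked, 57% masses, delayed-phase kinetics mostly
    washout, 8.4% BI-RADS 5, log-normal lesion size with median 1.1 cm.
    """

    age_mean: float = 51.5
    age_sd: float = 11.7
    p_postmenopausal: float = 0.521
    p_known_cancer: float = 0.649
    p_dense: float = 0.732
    bpe_probs: tuple[float, ...] = (0.299, 0.407, 0.191, 0.103)
    p_mass: float = 0.567
    kinetic_probs: tuple[float, float, float] = (0.025, 0.143, 0.832)
    p_birads5: float = 0.084
    size_log_mean: float = math.log(1.1)
    size_log_sd: float = 1.1


@dataclass(frozen=True)
class DTIClassConditional:
    """Class-conditional DTI feature distributions (units of 10^-3 mm^2/s).

    ADC is Gaussian given pathology class; FA is log-normal given
    (lesion type, class) with cell means/SDs patterned on the group means of
    the study (mass malignant 0.31, mass benign 0.21, non-mass malignant
    0.24, non-mass benign 0.26).  ``rho`` is the Gaussian-copula correlation
    between the ADC and FA latent normals (default -0.51, matching the
    reported ADC-FA rank correlation).  Axial/radial diffusivity and
    lambda1-lambda3 are derived from (ADC, FA) assuming an axially symmetric
    (prolate) tensor.
    """

    adc_malignant: tuple[float, float] = (1.26, 0.32)
    adc_benign: tuple[float, float] = (1.55, 0.30)
    # keys: (mass: bool, malignant: bool) -> (mean, sd)
    fa_mass_malignant: tuple[float, float] = (0.31, 0.17)
    fa_mass_benign: tuple[float, float] = (0.21, 0.12)
    fa_nonmass_malignant: tuple[float, float] = (0.24, 0.11)
    fa_nonmass_benign: tuple[float, float] = (0.26, 0.14)
    rho: float = -0.51

    def adc_params(self, malignant: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = np.asarray(malignant, dtype=bool)
        mean = np.where(m, self.adc_malignant[0], self.adc_benign[0])
        sd = np.where(m, self.adc_malignant[1], self.adc_benign[1])
        return mean, sd

    def fa_params(
        self, mass: np.ndarray, malignant: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        mass = np.asarray(mass, dtype=bool)
        mal = np.asarray(malignant, dtype=bool)
        mean = np.where(
            mass,
            np.where(mal, self.fa_mass_malignant[0], self.fa_mass_benign[0]),
            np.where(mal, self.fa_nonmass_malignant[0], self.fa_nonmass_benign[0]),
        )
        sd = np.where(
            mass,
            np.where(mal, self.fa_mass_malignant[1], self.fa_mass_benign[1]),
            np.where(mal, self.fa_nonmass_malignant[1], self.fa_nonmass_benign[1]),
        )
        return mean, sd


def _default_outcome_coefficients() -> dict[str, float]:
    # log odds patterned on the combined multivariate model of the study;
    # continuous terms are per-1-SD, bpe per category, binaries raw.
    return {
        "age": math.log(1.17),
        "post_menopausal": 0.0,
        "known_cancer": math.log(1.88),
        "dense": math.log(0.61),
        "bpe": math.log(0.66),
        "log_size": math.log(1.85),
        "mass": math.log(1.89),
        "washout": math.log(2.43),
        "birads5": math.log(2.36),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic clustered lesion cohort."""

    n_patients: int = 194
    lesions_per_patient_probs: tuple[float, float, float] = (0.809, 0.155, 0.036)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    outcome_coefficients: dict[str, float] = field(
        default_factory=_default_outcome_coefficients
    )
    intercept: float | None = None  # None -> calibrated to target_prevalence
    target_prevalence: float = 0.399
    cluster_effect_sd: float = 0.5
    dti: DTIClassConditional = field(default_factory=DTIClassConditional)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.cluster_effect_sd < 0:
            raise ConfigError("cluster_effect_sd must be >= 0")
        for name, probs in (
            ("lesions_per_patient_probs", self.lesions_per_patient_probs),
            ("bpe_probs", self.covariates.bpe_probs),
            ("kinetic_probs", self.covariates.kinetic_probs),
        ):
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        unknown = set(self.outcome_coefficients) - set(OUTCOME_FEATURES)
        if unknown:
            raise ConfigError(
                f"outcome_coefficients reference unknown features: {sorted(unknown)}"
            )


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    linear_predictor: np.ndarray  # per lesion, including random intercept
    random_intercepts: np.ndarray  # per patient
    intercept: float
    config: CohortConfig


def _draw_covariates(
    cov: CovariateConfig, n_lesions: int, patient_rows: np.ndarray, rng
) -> pd.DataFrame:
    """Draw patient- and lesion-level covariates for a cohort."""
    n_patients = patient_rows.max() + 1
    age_p = rng.normal(cov.age_mean, cov.age_sd, n_patients)
    post_p = rng.random(n_patients) < cov.p_postmenopausal
    known_p = rng.random(n_patients) < cov.p_known_cancer
    dense_p = rng.random(n_patients) < cov.p_dense
    bpe_p = rng.choice(np.arange(1, len(cov.bpe_probs) + 1), size=n_patients,
                       p=cov.bpe_probs)
    size = np.exp(rng.normal(cov.size_log_mean, cov.size_log_sd, n_lesions))
    mass = rng.random(n_lesions) < cov.p_mass
    kin = rng.choice(
        [KineticClass.PERSISTENT, KineticClass.PLATEAU, KineticClass.WASHOUT],
        size=n_lesions,
        p=cov.kinetic_probs,
    )
    birads5 = rng.random(n_lesions) < cov.p_birads5
    return pd.DataFrame(
        {
            "age": age_p[patient_rows],
            "post_menopausal": post_p[patient_rows].astype(int),
            "known_cancer": known_p[patient_rows].astype(int),
            "dense": dense_p[patient_rows].astype(int),
            "bpe": bpe_p[patient_rows],
            "size_cm": size,
            "mass": mass.astype(int),
            "kinetic_class": [str(k) for k in kin],
            "washout": (kin == KineticClass.WASHOUT).astype(int),
            "birads5": birads5.astype(int),
        }
    )


def _linear_predictor_terms(df: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """Sum of covariate terms of the outcome model (no intercept, no random effect)."""
    cov = config.covariates
    coefs = config.outcome_coefficients
    bpe_mean = float(np.dot(np.arange(1, len(cov.bpe_probs) + 1), cov.bpe_probs))
    lp = np.zeros(len(df))
    for name, beta in coefs.items():
        if beta == 0.0:
            continue
        if name == "age":
            x = (df["age"].to_numpy() - cov.age_mean) / cov.age_sd
        elif name == "log_size":
            x = (np.log(df["size_cm"].to_numpy()) - cov.size_log_mean) / cov.size_log_sd
        elif name == "bpe":
            x = df["bpe"].to_numpy() - bpe_mean
        else:
            x = df[name].to_numpy().astype(float)
        lp += beta * x
    return lp


#: Internal seed for the intercept-calibration Monte Carlo draws; fixed so
#: calibration is a deterministic function of the config alone.
_CALIBRATION_SEED = 987654321


_calibration_cache: dict[tuple, float] = {}


def _calibration_key(config: CohortConfig, n_mc: int) -> tuple:
    return (
        tuple(sorted(config.outcome_coefficients.items())),
        tuple(
            getattr(config.covariates, f)
            for f in (
                "age_mean", "age_sd", "p_postmenopausal", "p_known_cancer",
                "p_dense", "bpe_probs", "p_mass", "kinetic_probs", "p_birads5",
                "size_log_mean", "size_log_sd",
            )
        ),
        config.cluster_effect_sd,
        config.target_prevalence,
        n_mc,
    )


def calibrate_intercept(
    config: CohortConfig, n_mc: int = 200_000
) -> float:
    """Logistic intercept giving the target malignancy prevalence.

    Solves E[expit(b0 + covariate terms + random intercept)] = target by
    Monte Carlo over the covariate distribution (fixed internal seed) and
    scalar root finding.  The result depends only on the outcome model and
    covariate distributions, so it is memoized per process.
    """
    key = _calibration_key(config, n_mc)
    if key in _calibration_cache:
        return _calibration_cache[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    patient_rows = np.arange(n_mc)  # one lesion per pseudo-patient suffices
    df = _draw_covariates(config.covariates, n_mc, patient_rows, rng)
    lp = _linear_predictor_terms(df, config)
    if config.cluster_effect_sd > 0:
        lp = lp + rng.normal(0.0, config.cluster_effect_sd, n_mc)

    def prevalence(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + lp))))) - config.target_prevalence

    b0 = float(brentq(prevalence, -20.0, 20.0, xtol=1e-10))
    _calibration_cache[key] = b0
    return b0


def eigentriple_from_adc_fa(adc: np.ndarray, fa: np.ndarray):
    """Axially symmetric eigenvalue triple with the given mean diffusivity and FA.

    For a prolate tensor with lambda2 = lambda3, FA = 3 d / sqrt(3 + 6 d^2)
    where lambda1 = ADC (1 + 2d) and lambda2,3 = ADC (1 - d); inverting gives
    d = FA / sqrt(3 - 2 FA^2).

    Returns (axial, radial, lambda1 - lambda3) in the units of ``adc``.
    """
    adc = np.asarray(adc, dtype=float)
    fa = np.asarray(fa, dtype=float)
    d = fa / np.sqrt(3.0 - 2.0 * fa**2)
    axial = adc * (1.0 + 2.0 * d)
    radial = adc * (1.0 - d)
    return axial, radial, 3.0 * adc * d


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a clustered lesion cohort with known effect structure.

    Two-stage generative model: (1) clinical/DCE covariates are drawn from
    their marginals and malignancy from a logistic model on them plus a
    patient-level Gaussian random intercept; (2) DTI features are drawn
    conditional on the realised pathology class, reproducing the
    class-conditional ADC/FA distributions of the study cohort.
    """
    rng = np.random.default_rng(config.seed)
    n_lesions_per = rng.choice([1, 2, 3], size=config.n_patients,
                               p=config.lesions_per_patient_probs)
    patient_rows = np.repeat(np.arange(config.n_patients), n_lesions_per)
    n_lesions = patient_rows.size

    df = _draw_covariates(config.covariates, n_lesions, patient_rows, rng)
    df.insert(0, "patient_id", patient_rows)
    df.insert(1, "lesion_id", np.arange(n_lesions))

    intercept = (
        config.intercept
        if config.intercept is not None
        else calibrate_intercept(config)
    )
    u = rng.normal(0.0, config.cluster_effect_sd, config.n_patients)
    lp = intercept + _linear_predictor_terms(df, config) + u[patient_rows]
    malignant = rng.random(n_lesions) < 1.0 / (1.0 + np.exp(-lp))
    df["malignant"] = malignant.astype(int)

    # DTI features conditional on class, ADC-FA dependence via Gaussian copula
    z1 = rng.standard_normal(n_lesions)
    z2 = config.dti.rho * z1 + np.sqrt(1 - config.dti.rho**2) * rng.standard_normal(
        n_lesions
    )
    adc_mean, adc_sd = config.dti.adc_params(malignant)
    adc = np.clip(adc_mean + adc_sd * z1, 0.15, None)
    fa_mean, fa_sd = config.dti.fa_params(df["mass"].to_numpy(), malignant)
    cv2 = (fa_sd / fa_mean) ** 2
    s = np.sqrt(np.log1p(cv2))
    m = np.log(fa_mean) - 0.5 * s**2
    fa = np.clip(np.exp(m + s * z2), 0.01, 0.95)
    axial, radial, lam_diff = eigentriple_from_adc_fa(adc, fa)

    df["mean_adc"] = adc
    df["mean_fa"] = fa
    df["mean_axial"] = axial
    df["mean_radial"] = radial
    df["mean_lambda_diff"] = lam_diff

    truth = CohortTruth(
        linear_predictor=lp,
        random_intercepts=u,
        intercept=float(intercept),
        config=replace(config, intercept=float(intercept)),
    )
    return df, truth
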