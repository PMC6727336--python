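"""Diffusion tensor estimation and scalar parameter maps.

The diffusion-weighted signal follows the monoexponential tensor model

    S = S0 * exp(-b * g^T D g)

with ``D`` the symmetric 3x3 diffusion tensor.  Taking logs linearises the
model in the six tensor elements plus log S0, which is solved per voxel by
(optionally weighted) least squares.  The tensor is diagonalised and its
eigenvalues, sorted descending (lambda1 >= lambda2 >= lambda3), yield the
standard rotationally invariant scalars:

    ADC (mean diffusivity)   = (l1 + l2 + l3) / 3
    FA                       = sqrt(3/2) * ||lambda - ADC|| / ||lambda||
    axial diffusivity        = l1
    radial diffusivity       = (l2 + l3) / 2
    lambda1 - lambda3        = un-normalised anisotropy

plus the combined diffusion-weighted image, the geometric mean of the
unidirectional images at one b-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDesignError, MissingShellError
from .gradients import GradientScheme

__all__ = [
    "DWIVolume",
    "TensorMap",
    "ScalarMaps",
    "DiffusionTensorModel",
    "TensorFitResults",
    "fit_tensor",
    "scalar_maps",
    "combined_dwi",
    "fa_from_eigenvalues",
]


@dataclass
class DWIVolume:
    """4D diffusion-weighted image plus its acquisition scheme.

    ``data`` has shape (x, y, z, n_acquisitions) with the last axis aligned
    to ``scheme``.  Intensities are arbitrary scanner units, >= 0.
    """

    data: np.ndarray
    scheme: GradientScheme
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 5.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got shape {self.data.shape}")
        if self.data.shape[-1] != len(self.scheme):
            raise ValueError(
                f"acquisition axis ({self.data.shape[-1]}) does not match "
                f"scheme length ({len(self.scheme)})"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class TensorMap:
    """Per-voxel diffusion tensor eigensystem.

    Attributes
    ----------
    tensors : (..., 3, 3) array of the fitted symmetric tensors, mm**2/s.
    evals : (..., 3) eigenvalues sorted descending; negatives clamped to 0.
    evecs : (..., 3, 3) eigenvectors as columns, aligned with ``evals``.
    s0 : (...) fitted non-diffusion-weighted signal.
    mask : (...) bool, True where a fit was performed.
    clamped : (...) bool, True where a negative eigenvalue was clamped.
    excluded : (...) bool, True where non-positive signals precluded a fit.
    """

    tensors: np.ndarray
    evals: np.ndarray
    evecs: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    clamped: np.ndarray
    excluded: np.ndarray


@dataclass
class ScalarMaps:
    """The five scalar DTI parameter maps (diffusivities in mm**2/s, FA unitless)."""

    adc: np.ndarray
    fa: np.ndarray
    axial: np.ndarray
    radial: np.ndarray
    lambda_diff: np.ndarray
    mask: np.ndarray | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "adc": self.adc,
            "fa": self.fa,
            "axial": self.axial,
            "radial": self.radial,
            "lambda_diff": self.lambda_diff,
        }


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues (last axis length 3).

    FA of the zero tensor is defined as 0.
    """
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt(((evals - md) ** 2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(fa, 0.0, 1.0)


def fit_tensor(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    weighted: bool = False,
    shells: tuple[float, ...] | None = None,
) -> TensorMap:
    """Estimate the diffusion tensor per voxel by log-linear least squares.

    Parameters
    ----------
    dwi : DWIVolume
    mask : bool array of grid shape, optional
        Voxels to fit; all voxels by default.  An all-False mask yields an
        empty map (every voxel unfit).
    weighted : bool
        If True, weight the log-linear fit by the squared signal (WLS);
        ordinary least squares by default.
    shells : tuple of b-values, optional
        Restrict the fit to these b-values (b=0 always kept).  By default all
        shells in the scheme enter one joint fit.

    Notes
    -----
    Voxels with any non-positive signal among the used acquisitions are
    excluded from the fit (log undefined; such voxels are noise dominated)
    and flagged in ``excluded``.  Negative eigenvalues are clamped to zero
    and flagged in ``clamped``.
    """
    scheme = dwi.scheme
    use = np.ones(len(scheme), dtype=bool)
    if shells is not None:
        use = scheme.b0_mask.copy()
        for b in shells:
            use |= scheme.shell_mask(b)
    sub = GradientScheme(scheme.bvals[use], scheme.bvecs[use])
    sub.check_full_rank()
    A = sub.design_matrix()  # (m, 7)
    if np.linalg.matrix_rank(A) < 7:
        raise DegenerateDesignError("design matrix rank deficient for tensor fit")

    grid = dwi.grid_shape
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    signals = dwi.data[..., use][mask]  # (nvox, m)
    positive = np.all(signals > 0, axis=-1)

    tensors = np.zeros(grid + (3, 3))
    evals = np.zeros(grid + (3,))
    evecs = np.zeros(grid + (3, 3))
    s0 = np.zeros(grid)
    fitted = np.zeros(grid, dtype=bool)
    clamped = np.zeros(grid, dtype=bool)
    excluded = np.zeros(grid, dtype=bool)

    vox_idx = np.argwhere(mask)
    bad = vox_idx[~positive]
    excluded[tuple(bad.T)] = True

    good_signals = signals[positive]
    if good_signals.shape[0] == 0:
        return TensorMap(tensors, evals, evecs, s0, fitted, clamped, excluded)

    logS = np.log(good_signals)  # (n, m)
    if not weighted:
        coef = logS @ np.linalg.pinv(A).T  # (n, 7)
    else:
        w = good_signals**2  # (n, m)
        AwA = np.einsum("nm,mi,mj->nij", w, A, A)
        Awy = np.einsum("nm,mi,nm->ni", w, A, logS)
        coef = np.linalg.solve(AwA, Awy[..., None])[..., 0]

    n = coef.shape[0]
    D = np.empty((n, 3, 3))
    D[:, 0, 0] = coef[:, 1]
    D[:, 1, 1] = coef[:, 2]
    D[:, 2, 2] = coef[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = coef[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = coef[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = coef[:, 6]

    w_, v_ = np.linalg.eigh(D)  # ascending
    w_ = w_[:, ::-1]
    v_ = v_[:, :, ::-1]
    clamp = np.any(w_ < 0, axis=-1)
    w_ = np.maximum(w_, 0.0)

    good = vox_idx[positive]
    gi = tuple(good.T)
    tensors[gi] = D
    evals[gi] = w_
    evecs[gi] = v_
    s0[gi] = np.exp(coef[:, 0])
    fitted[gi] = True
    clamped[gi] = clamp
    return TensorMap(tensors, evals, evecs, s0, fitted, clamped, excluded)


def scalar_maps(tensors: TensorMap | np.ndarray) -> ScalarMaps:
    """Compute the five scalar maps from sorted eigenvalues.

    Accepts a :class:`TensorMap` or a bare eigenvalue array with last axis 3
    (assumed sorted descending).
    """
    if isinstance(tensors, TensorMap):
        evals = tensors.evals
        mask = tensors.mask
    else:
        evals = np.sort(np.asarray(tensors, dtype=float), axis=-1)[..., ::-1]
        mask = None
    adc = evals.mean(axis=-1)
    axial = evals[..., 0]
    radial = evals[..., 1:].mean(axis=-1)
    lambda_diff = evals[..., 0] - evals[..., 2]
    fa = fa_from_eigenvalues(evals)
    return ScalarMaps(adc=adc, fa=fa, axial=axial, radial=radial,
                      lambda_diff=lambda_diff, mask=mask)


def combined_dwi(dwi: DWIVolume, b_target: float = 800.0) -> np.ndarray:
    """Geometric mean of the unidirectional images at ``b_target``.

    Voxels where any contributing signal is zero (or negative) map to zero.
    """
    sel = dwi.scheme.shell_mask(b_target) & (dwi.scheme.bvals > 0)
    if b_target == 0:
        sel = dwi.scheme.b0_mask
    if not np.any(sel):
        raise MissingShellError(f"no acquisitions at b = {b_target} s/mm^2")
    imgs = dwi.data[..., sel]
    if imgs.shape[-1] == 1:
        return imgs[..., 0].copy()
    nonpos = np.any(imgs <= 0, axis=-1)
    safe = np.where(imgs > 0, imgs, 1.0)
    gm = np.exp(np.log(safe).mean(axis=-1))
    return np.where(nonpos, 0.0, gm)


class DiffusionTensorModel:
    """Statsmodels-style wrapper around the voxel-wise tensor fit.

    Examples
    --------
    >>> model = DiffusionTensorModel(dwi)           # doctest: +SKIP
    >>> res = model.fit()                           # doctest: +SKIP
    >>> res.scalar_maps.adc                          # doctest: +SKIP
    """

    def __init__(
        self,
        dwi: DWIVolume,
        mask: np.ndarray | None = None,
        weighted: bool = False,
        shells: tuple[float, ...] | None = None,
    ):
        self.dwi = dwi
        self.mask = mask
        self.weighted = weighted
        self.shells = shells

    def fit(self) -> "TensorFitResults":
        tmap = fit_tensor(self.dwi, mask=self.mask, weighted=self.weighted,
                          shells=self.shells)
        return TensorFitResults(self, tmap)


@dataclass
class TensorFitResults:
    """Fitted tensor map with derived scalar maps and a diagnostic summary."""

    model: DiffusionTensorModel
    tensor_map: TensorMap
    _scalars: ScalarMaps | None = field(default=None, repr=False)

    @property
    def scalar_maps(self) -> ScalarMaps:
        if self._scalars is None:
            self._scalars = scalar_maps(self.tensor_map)
        return self._scalars

    def combined_dwi(self, b_target: float = 800.0) -> np.ndarray:
        return combined_dwi(self.model.dwi, b_target)

    def summary(self) -> str:
        tm = self.tensor_map
        sm = self.scalar_maps
        m = tm.mask
        lines = [
            "Diffusion tensor fit",
            "--------------------",
            f"voxels fitted        : {int(m.sum())}",
            f"voxels excluded      : {int(tm.excluded.sum())} (non-positive signal)",
            f"eigenvalues clamped  : {int(tm.clamped.sum())}",
        ]
        if m.any():
            lines += [
                f"mean ADC  (mm^2/s)   : {sm.adc[m].mean():.3e}",
                f"mean FA              : {sm.fa[m].mean():.3f}",
            ]
        return "\n".join(lines)
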