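"""Lesion ROI refinement and scalar-map summarization.

A lesion seed region, drawn on the combined diffusion-weighted image at the
central slice of the lesion, is refined by excluding voxels with very low
DWI signal (adipose or normal fibroglandular tissue): voxels are retained
when their combined-DWI intensity is at least ``threshold_fraction`` times
the maximum intensity within the seed region.  The refined ROI is propagated
to every scalar map and each map's arithmetic mean over the ROI voxels
characterises the lesion.

Mean FA is always the mean of voxel-wise FA values, never the FA of mean
eigenvalues: the two differ because FA is a nonlinear function of the
eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyROIError, MultiSliceROIError
from .tensor import ScalarMaps

__all__ = ["LesionROI", "DTIFeatures", "refine_roi", "lesion_summary"]


@dataclass
class LesionROI:
    """A refined single-slice lesion region.

    ``voxels`` is an (n, 3) integer array of voxel indices.  ``empty`` is set
    instead of raising when thresholding removes every seed voxel, mirroring
    how non-evaluable lesions are excluded rather than crash a study run.
    """

    voxels: np.ndarray
    slice_index: int
    threshold: float
    threshold_fraction: float
    n_seed: int
    n_excluded: int
    empty: bool = False

    @property
    def n_voxels(self) -> int:
        return 0 if self.empty else int(self.voxels.shape[0])

    def index_tuple(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.voxels
        return v[:, 0], v[:, 1], v[:, 2]


@dataclass
class DTIFeatures:
    """Lesion-level means of the five scalar maps over the ROI (mm**2/s, FA unitless)."""

    mean_adc: float
    mean_fa: float
    mean_axial: float
    mean_radial: float
    mean_lambda_diff: float
    n_voxels: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_adc": self.mean_adc,
            "mean_fa": self.mean_fa,
            "mean_axial": self.mean_axial,
            "mean_radial": self.mean_radial,
            "mean_lambda_diff": self.mean_lambda_diff,
            "n_voxels": self.n_voxels,
        }


def _as_voxel_array(seed_region: np.ndarray) -> np.ndarray:
    seed = np.asarray(seed_region)
    if seed.dtype == bool:
        seed = np.argwhere(seed)
    seed = seed.reshape(-1, 3).astype(int)
    return seed


def refine_roi(
    combined: np.ndarray,
    seed_region: np.ndarray,
    threshold_fraction: float = 0.5,
) -> LesionROI:
    """Exclude low-signal voxels from a seed region on the combined DWI.

    Parameters
    ----------
    combined : 3D array
        Combined (geometric-mean) diffusion-weighted image.
    seed_region : (n, 3) int array or 3D bool mask
        Manually drawn seed region; must be non-empty and single-slice.
    threshold_fraction : float in [0, 1)
        Voxels with intensity >= ``threshold_fraction * max(in-seed intensity)``
        are retained.  0 keeps the whole seed region.

    Returns
    -------
    LesionROI
        With ``empty=True`` (not an exception) if every voxel was excluded.
    """
    if not 0 <= threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in [0, 1)")
    combined = np.asarray(combined, dtype=float)
    seed = _as_voxel_array(seed_region)
    if seed.shape[0] == 0:
        raise EmptyROIError("seed region is empty")
    if (np.any(seed < 0)
            or np.any(seed >= np.array(combined.shape)[None, :])):
        raise IndexError("seed region voxel outside image bounds")
    slices = np.unique(seed[:, 2])
    if slices.size > 1:
        raise MultiSliceROIError(
            f"seed region spans slices {slices.tolist()}; ROIs are single-slice"
        )
    values = combined[seed[:, 0], seed[:, 1], seed[:, 2]]
    threshold = threshold_fraction * values.max()
    keep = values >= threshold
    n_seed = seed.shape[0]
    kept = seed[keep]
    return LesionROI(
        voxels=kept,
        slice_index=int(slices[0]),
        threshold=float(threshold),
        threshold_fraction=float(threshold_fraction),
        n_seed=n_seed,
        n_excluded=int(n_seed - kept.shape[0]),
        empty=kept.shape[0] == 0,
    )


def lesion_summary(maps: ScalarMaps, roi: LesionROI) -> DTIFeatures:
    """Arithmetic mean of each scalar map over the ROI voxels."""
    if roi.empty or roi.n_voxels == 0:
        raise EmptyROIError("cannot summarize an empty ROI")
    idx = roi.index_tuple()
    return DTIFeatures(
        mean_adc=float(maps.adc[idx].mean()),
        mean_fa=float(maps.fa[idx].mean()),
        mean_axial=float(maps.axial[idx].mean()),
        mean_radial=float(maps.radial[idx].mean()),
        mean_lambda_diff=float(maps.lambda_diff[idx].mean()),
        n_voxels=roi.n_voxels,
    )
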