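"""Reading and writing DWI volumes, scalar maps, gradient tables and cohorts.

DWI volumes are 4D NIfTI files with FSL-dialect sidecars: ``.bval`` is one
whitespace-separated row of b-values, ``.bvec`` is three rows (x, y, z
components), one column per acquisition, directions interpreted in the image
coordinate frame.  Scalar maps are written as 3D NIfTI preserving the input
affine.  Cohorts are plain CSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError
from .gradients import GradientScheme
from .tensor import DWIVolume, ScalarMaps

__all__ = [
    "read_bval_bvec",
    "write_bval_bvec",
    "read_dwi",
    "write_dwi",
    "write_maps",
    "read_seed_csv",
    "COHORT_COLUMNS",
]

#: Column dictionary of the cohort CSV.
COHORT_COLUMNS = {
    "patient_id": "integer patient identifier (cluster label)",
    "lesion_id": "integer lesion identifier, unique per row",
    "age": "patient age, years",
    "post_menopausal": "1 = post-menopausal",
    "known_cancer": "1 = MRI indication was newly diagnosed cancer",
    "dense": "1 = heterogeneously or extremely dense breasts",
    "bpe": "background parenchymal enhancement, ordinal 1-4",
    "size_cm": "largest lesion diameter, cm",
    "mass": "1 = mass, 0 = non-mass enhancement / focus",
    "kinetic_class": "worst delayed-phase curve: persistent/plateau/washout",
    "washout": "1 = washout present on delayed phase",
    "birads5": "1 = BI-RADS category 5 (vs 4)",
    "mean_adc": "ROI mean ADC, 10^-3 mm^2/s",
    "mean_fa": "ROI mean FA, unitless",
    "mean_axial": "ROI mean axial diffusivity, 10^-3 mm^2/s",
    "mean_radial": "ROI mean radial diffusivity, 10^-3 mm^2/s",
    "mean_lambda_diff": "ROI mean lambda1 - lambda3, 10^-3 mm^2/s",
    "malignant": "1 = histopathology malignant",
}


def read_bval_bvec(bval_path, bvec_path) -> GradientScheme:
    """Read an FSL-dialect gradient table.

    Non-unit direction vectors at b > 0 are normalized with a warning.
    """
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: rows are axes
    if bvecs.shape != (bvals.size, 3):
        raise FormatError(
            f"bvec shape {bvecs.shape} incompatible with {bvals.size} b-values "
            "(axis: acquisition)"
        )
    if not np.any(bvals == 0):
        raise FormatError("gradient table has no b=0 volume")
    nz = bvals > 0
    norms = np.linalg.norm(bvecs[nz], axis=1)
    if np.any(np.abs(norms - 1) > 1e-6):
        warnings.warn("non-unit gradient directions in bvec; normalizing",
                      stacklevel=2)
        bvecs = bvecs.copy()
        bvecs[nz] = bvecs[nz] / norms[:, None]
    bvecs[~nz] = 0.0
    return GradientScheme(bvals, bvecs)


def write_bval_bvec(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10g")


def read_dwi(path, bval_path=None, bvec_path=None) -> DWIVolume:
    """Load a 4D DWI NIfTI with its bval/bvec sidecars.

    Sidecar paths default to the NIfTI path with ``.bval``/``.bvec``
    extensions.
    """
    path = Path(path)
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    if bval_path is None:
        bval_path = path.parent / f"{stem}.bval"
    if bvec_path is None:
        bvec_path = path.parent / f"{stem}.bvec"
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise FormatError(f"expected 4D DWI, got shape {data.shape}")
    scheme = read_bval_bvec(bval_path, bvec_path)
    if data.shape[-1] != len(scheme):
        raise FormatError(
            f"acquisition axis length {data.shape[-1]} does not match gradient "
            f"table length {len(scheme)} (axis 3)"
        )
    zooms = img.header.get_zooms()[:3]
    return DWIVolume(data, scheme, voxel_size=tuple(float(z) for z in zooms),
                     affine=np.asarray(img.affine))


def write_dwi(dwi: DWIVolume, path) -> tuple[Path, Path, Path]:
    """Write a DWI volume as NIfTI + bval/bvec; returns the three paths."""
    path = Path(path)
    affine = dwi.affine
    if affine is None:
        affine = np.diag([*dwi.voxel_size, 1.0])
    img = nib.Nifti1Image(dwi.data, affine)
    img.header.set_zooms((*dwi.voxel_size, 1.0))
    nib.save(img, str(path))
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    bval = path.parent / f"{stem}.bval"
    bvec = path.parent / f"{stem}.bvec"
    write_bval_bvec(dwi.scheme, bval, bvec)
    return path, bval, bvec


def write_maps(maps: ScalarMaps, out_dir, affine: np.ndarray | None = None) -> dict[str, Path]:
    """Write each scalar map as a 3D NIfTI; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    paths = {}
    for name, arr in maps.as_dict().items():
        p = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), str(p))
        paths[name] = p
    return paths


def read_seed_csv(path) -> np.ndarray:
    """Read a seed-region voxel list CSV with columns x,y,z -> (n, 3) ints."""
    df = pd.read_csv(path)
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if len(cols) != 3:
        raise FormatError("seed CSV needs integer columns x, y, z")
    return df[["x", "y", "z"]].to_numpy(dtype=int)
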