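"""Diffusion gradient schemes.

A :class:`GradientScheme` pairs diffusion sensitizations (b-values, s/mm**2)
with unit gradient directions, one entry per acquired volume.  The default
clinical protocol modeled here acquires one b=0 volume plus six directions at
each non-zero b-value (b = 100 and 800 s/mm**2), i.e. 13 volumes in total.

The default six-direction set is the dual-gradient scheme

    {(1,1,0), (1,0,1), (0,1,1), (1,-1,0), (1,0,-1), (0,1,-1)} / sqrt(2)

which is balanced: the sum of outer products g g^T equals 2*I, so the
log-linear design matrix for the tensor fit is well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDesignError

__all__ = ["GradientScheme", "make_gradient_scheme", "DUAL_GRADIENT_DIRECTIONS"]

#: Balanced six-direction dual-gradient set (rows are unit vectors).
DUAL_GRADIENT_DIRECTIONS = np.array(
    [
        [1.0, 1.0, 0.0],
        [1.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
        [1.0, -1.0, 0.0],
        [1.0, 0.0, -1.0],
        [0.0, 1.0, -1.0],
    ]
) / np.sqrt(2.0)


@dataclass(frozen=True)
class GradientScheme:
    """b-values and aligned unit gradient directions.

    Parameters
    ----------
    bvals : (n,) array
        Diffusion sensitization per acquisition, s/mm**2.
    bvecs : (n, 3) array
        Gradient direction per acquisition.  Rows for b=0 entries are zero;
        rows for b>0 entries must have unit Euclidean norm.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) differ in length"
            )
        if not np.any(bvals == 0):
            raise ValueError("scheme must include at least one b=0 acquisition")
        norms = np.linalg.norm(bvecs[bvals > 0], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("gradient directions at b>0 must be unit vectors")

    def __len__(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def n_volumes(self) -> int:
        return len(self)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def shell_mask(self, b: float, atol: float = 1e-6) -> np.ndarray:
        """Boolean mask of acquisitions at b-value ``b``."""
        return np.abs(self.bvals - b) <= atol

    @property
    def unique_directions(self) -> np.ndarray:
        """Distinct gradient directions used at b>0 (sign-insensitive)."""
        vecs = self.bvecs[self.bvals > 0]
        if vecs.size == 0:
            return vecs.reshape(0, 3)
        # canonicalise antipodal pairs before deduplication
        canon = np.where(
            (vecs[:, [0]] < 0)
            | ((vecs[:, [0]] == 0) & (vecs[:, [1]] < 0))
            | ((vecs[:, [0]] == 0) & (vecs[:, [1]] == 0) & (vecs[:, [2]] < 0)),
            -vecs,
            vecs,
        )
        return np.unique(np.round(canon, 10), axis=0)

    def design_matrix(self) -> np.ndarray:
        """Design matrix of the log-linearized tensor model.

        Row i is ``[1, -b x^2, -b y^2, -b z^2, -2b xy, -2b xz, -2b yz]`` so
        that ``A @ [log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] = log S``.
        """
        b = self.bvals[:, None]
        g = self.bvecs
        x, y, z = g[:, 0:1], g[:, 1:2], g[:, 2:3]
        return np.hstack(
            [
                np.ones_like(b),
                -b * x * x,
                -b * y * y,
                -b * z * z,
                -2 * b * x * y,
                -2 * b * x * z,
                -2 * b * y * z,
            ]
        )

    def check_full_rank(self) -> None:
        """Raise :class:`DegenerateDesignError` if the 7-parameter fit is rank-deficient."""
        if self.unique_directions.shape[0] < 6:
            raise DegenerateDesignError(
                "tensor fitting needs >= 6 distinct gradient directions; "
                f"scheme has {self.unique_directions.shape[0]}"
            )
        if np.linalg.matrix_rank(self.design_matrix()) < 7:
            raise DegenerateDesignError("gradient scheme design matrix is rank deficient")


def _spiral_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the hemisphere (n > 6)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    # upper hemisphere so antipodal duplicates cannot occur
    cos_t = i / n
    sin_t = np.sqrt(1 - cos_t**2)
    dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def make_gradient_scheme(
    n_directions: int = 6, b_values: tuple[float, ...] = (0.0, 100.0, 800.0)
) -> GradientScheme:
    """Build an acquisition scheme: one b=0 volume plus ``n_directions`` per b>0 shell.

    Parameters
    ----------
    n_directions : int
        Number of diffusion directions per non-zero shell (>= 6 for a
        full-rank tensor fit).  Six yields the balanced dual-gradient set.
    b_values : sequence of float
        b-values in s/mm**2; must include 0.

    Raises
    ------
    DegenerateDesignError
        If ``n_directions`` < 6.
    ValueError
        If no b=0 is requested.
    """
    if n_directions < 6:
        raise DegenerateDesignError(
            f"tensor fitting requires >= 6 directions, got {n_directions}"
        )
    b_values = tuple(float(b) for b in b_values)
    if 0.0 not in b_values:
        raise ValueError("b_values must include 0 (non-diffusion-weighted reference)")
    if n_directions == 6:
        dirs = DUAL_GRADIENT_DIRECTIONS
    else:
        dirs = _spiral_directions(n_directions)

    bvals = [0.0]
    bvecs = [np.zeros(3)]
    for b in b_values:
        if b == 0.0:
            continue
        for d in dirs:
            bvals.append(b)
            bvecs.append(d)
    scheme = GradientScheme(np.array(bvals), np.array(bvecs))
    scheme.check_full_rank()
    return scheme
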