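"""DCE-MRI kinetic curve classification.

Voxel enhancement curves are typed by the relative signal change from the
initial (120 s) to the final (480 s) post-contrast acquisition:

    washout    : > 10% decrease     (r < -0.10)
    persistent : > 10% increase     (r > +0.10)
    plateau    : < 10% change       (|r| <= 0.10, boundaries included)

The lesion-level "worst curve" is the most suspicious class present, with
washout > plateau > persistent.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable

import numpy as np

from .exceptions import UnenhancedVoxelError

__all__ = [
    "KineticClass",
    "classify_voxel_kinetics",
    "classify_curves",
    "worst_curve",
    "lesion_washout",
]

#: Strict relative-change threshold separating the three classes.
KINETIC_THRESHOLD = 0.10


class KineticClass(enum.IntEnum):
    """Enhancement curve type, ordered by suspicion (washout most suspicious)."""

    PERSISTENT = 1
    PLATEAU = 2
    WASHOUT = 3

    @property
    def suspicion_rank(self) -> int:
        return int(self.value)

    def __str__(self) -> str:  # CSV-friendly
        return self.name.lower()


def classify_voxel_kinetics(
    s_initial: float,
    s_final: float,
    min_enhancement: float | None = None,
    s_pre: float | None = None,
) -> KineticClass:
    """Classify one voxel's curve from its 120 s and 480 s signals.

    Parameters
    ----------
    s_initial, s_final : float
        Post-contrast signal at 120 s and 480 s.  ``s_initial`` must be > 0.
    min_enhancement, s_pre : optional
        CAD-style enhancement gate, off by default: when both are given,
        voxels whose initial enhancement (s_initial - s_pre)/s_pre falls
        below ``min_enhancement`` raise :class:`UnenhancedVoxelError`.
    """
    if s_initial <= 0:
        raise UnenhancedVoxelError(
            f"initial post-contrast signal must be positive, got {s_initial}"
        )
    if min_enhancement is not None and s_pre is not None:
        if s_pre <= 0 or (s_initial - s_pre) / s_pre < min_enhancement:
            raise UnenhancedVoxelError(
                "voxel below the minimum-enhancement gate"
            )
    r = (s_final - s_initial) / s_initial
    if r < -KINETIC_THRESHOLD:
        return KineticClass.WASHOUT
    if r > KINETIC_THRESHOLD:
        return KineticClass.PERSISTENT
    return KineticClass.PLATEAU


def classify_curves(s_initial: np.ndarray, s_final: np.ndarray) -> np.ndarray:
    """Vectorised classification; returns an array of :class:`KineticClass`."""
    s_initial = np.asarray(s_initial, dtype=float)
    s_final = np.asarray(s_final, dtype=float)
    if np.any(s_initial <= 0):
        raise UnenhancedVoxelError("all initial signals must be positive")
    r = (s_final - s_initial) / s_initial
    out = np.empty(r.shape, dtype=object)
    out[...] = KineticClass.PLATEAU
    out[r < -KINETIC_THRESHOLD] = KineticClass.WASHOUT
    out[r > KINETIC_THRESHOLD] = KineticClass.PERSISTENT
    return out


def worst_curve(classes: Iterable[KineticClass]) -> KineticClass:
    """Most suspicious kinetic class present (washout > plateau > persistent)."""
    classes = list(classes)
    if not classes:
        raise ValueError("worst_curve requires at least one kinetic class")
    return max(classes, key=lambda c: KineticClass(c).suspicion_rank)


def lesion_washout(classes: Iterable[KineticClass]) -> bool:
    """Lesion-level binary feature: washout present on delayed phase."""
    return worst_curve(classes) == KineticClass.WASHOUT
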