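"""Least-squares rigid-body superposition (proper rotations only)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "UnderdeterminedFitError", "fit_rigid"]

#: Below this ratio of second-to-first singular value the point set is
#: treated as effectively collinear and the rotation is underdetermined.
_COLLINEAR_RTOL = 1e-8


class UnderdeterminedFitError(ValueError):
    """Fewer than 3 points, or points too close to collinear, for a unique fit."""


@dataclass(frozen=True)
class RigidTransform:
    """``x -> rotation @ x + translation``; rotation is always proper."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        pts = np.asarray(coords, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def fit_rigid(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Superpose ``mobile`` onto ``reference`` in the least-squares sense.

    Returns the rigid transform (rotation + translation, reflection never
    allowed) and the post-fit RMSD in the units of the inputs.
    """
    mob = np.atleast_2d(np.asarray(mobile, dtype=float))
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    if mob.shape != ref.shape or mob.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ: {mob.shape} vs {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise UnderdeterminedFitError(f"need >=3 points for a unique fit, got {n}")
    cm_mob = mob.mean(axis=0)
    cm_ref = ref.mean(axis=0)
    mob_c = mob - cm_mob
    ref_c = ref - cm_ref
    sv = np.linalg.svd(mob_c, compute_uv=False)
    if sv[1] <= _COLLINEAR_RTOL * sv[0]:
        raise UnderdeterminedFitError("alignment atoms are (near-)collinear")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rmsd = float(rssd) / np.sqrt(n)
    matrix = rot.as_matrix()
    translation = cm_ref - matrix @ cm_mob
    return RigidTransform(matrix, translation), rmsd
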