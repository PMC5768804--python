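"""Landmark-based rigid registration.

Maps needle-image coordinates into the patient-model frame from paired
landmarks via the closed-form least-squares rigid (Procrustes/Kabsch) fit:
the rotation comes from the SVD of the landmark cross-covariance, with the
standard sign correction so that reflections are never returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import RegistrationError

__all__ = [
    "RigidTransform",
    "fit_rigid",
    "apply_transform",
    "registration_error",
]

@dataclass(frozen=True, eq=False)
class RigidTransform:
    """Proper rigid transform ``p -> R @ p + t`` in mm.

    ``rotation`` must be orthonormal with determinant +1; validated at
    construction to within 1e-9.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise RegistrationError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise RegistrationError("rotation matrix must have determinant +1 (no reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rotation": self.rotation.ravel().tolist(),  # row-major
            "translation": self.translation.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["rotation"]).reshape(3, 3), np.asarray(payload["translation"]))


def apply_transform(transform: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Apply ``p -> R @ p + t`` to one point or an (n, 3) array of points."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = pts @ transform.rotation.T + transform.translation
    return out[0] if single else out


def fit_rigid(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform minimizing sum ||R s_i + t - t_i||^2.

    Closed-form Kabsch solution: SVD of the centered cross-covariance,
    flipping the sign of the smallest singular vector when the determinant
    of ``V U^T`` is negative so the result is a proper rotation (no scaling,
    no reflection).

    Raises
    ------
    RegistrationError
        For fewer than 3 pairs, mismatched list lengths, or (near-)collinear
        source points, all of which leave the rotation under-determined.
    """
    src = np.asarray(source_points, dtype=float)
    tgt = np.asarray(target_points, dtype=float)
    if src.ndim != 2 or src.shape[1] != 3 or src.shape != tgt.shape:
        raise RegistrationError("source and target must be matching (n, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise RegistrationError(f"rigid fit is under-determined with {n} landmark pair(s); need >= 3")

    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)

    # collinear source points leave a free rotation about their axis
    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise RegistrationError("source landmarks are collinear; rotation is under-determined")

    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


def registration_error(transform: RigidTransform, pairs) -> float:
    """Root-mean-square fiducial residual ||R s_i + t - t_i|| over landmark pairs.

    ``pairs`` is a sequence of (source, target) point pairs, or a tuple of two
    (n, 3) arrays.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2:
        src, tgt = (np.asarray(a, dtype=float) for a in pairs)
    else:
        pairs = list(pairs)
        if not pairs:
            raise RegistrationError("registration error undefined for an empty pair list")
        src = np.asarray([p[0] for p in pairs], dtype=float)
        tgt = np.asarray([p[1] for p in pairs], dtype=float)
    if src.size == 0:
        raise RegistrationError("registration error undefined for an empty pair list")
    resid = apply_transform(transform, src) - tgt
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
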