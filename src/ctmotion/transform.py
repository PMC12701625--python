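"""Rigid transforms acting on world points in millimetres.

A :class:`RigidTransform` represents the proper rigid map

    y = R (x - c) + c + t

with rotation matrix ``R``, translation ``t`` (mm) and pivot ``c`` (mm).
Transforms are closed under composition and inversion; as *maps* they are
independent of the pivot used to parameterise them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform"]

_ORTHO_TOL = 1e-9


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    if not np.all(np.isfinite(v)):
        raise ValueError("vector components must be finite")
    return v


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform (rotation + translation) in world mm."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = _as_vec3(self.translation)
        c = _as_vec3(self.center)
        resid = np.abs(R.T @ R - np.eye(3)).max()
        if resid > 1e-6:
            raise ValueError(f"rotation matrix not orthogonal (residual {resid:.3g})")
        if resid > _ORTHO_TOL:
            # re-orthonormalise tiny drift from composition chains
            u, _, vt = np.linalg.svd(R)
            R = u @ vt
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "center", c)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), t)

    @classmethod
    def from_euler_deg(cls, rx: float = 0.0, ry: float = 0.0, rz: float = 0.0,
                       translation=(0.0, 0.0, 0.0), center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from Cardan angles (degrees), fixed-axes sequence x→y→z.

        The rotation matrix is ``Rz(rz) @ Ry(ry) @ Rx(rx)``.
        """
        R = Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()
        return cls(R, translation, center)

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        """From a 4x4 homogeneous matrix."""
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    # -- canonical (pivot-free) form ---------------------------------------
    @property
    def offset(self) -> np.ndarray:
        """Translation ``b`` of the equivalent pivot-free map ``y = R x + b``."""
        return self.translation + self.center - self.rotation @ self.center

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.offset
        return m

    def with_center(self, center) -> "RigidTransform":
        """Re-express the same map about a different pivot."""
        c = _as_vec3(center)
        t = self.offset - c + self.rotation @ c
        return RigidTransform(self.rotation, t, c)

    # -- algebra -----------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.offset

    def __call__(self, points) -> np.ndarray:
        return self.apply(points)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Function composition: ``(self @ other)(x) = self(other(x))``."""
        R = self.rotation @ other.rotation
        b = self.rotation @ other.offset + self.offset
        return RigidTransform(R, b)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.offset)

    # -- descriptors -------------------------------------------------------
    def euler_deg(self) -> np.ndarray:
        """Cardan angles (rx, ry, rz) in degrees, fixed-axes x→y→z."""
        rz, ry, rx = Rotation.from_matrix(self.rotation).as_euler("ZYX", degrees=True)
        return np.array([rx, ry, rz])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the single-axis (screw) rotation in degrees."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (np.abs(self.rotation - np.eye(3)).max() <= tol
                and np.abs(self.offset).max() <= tol)

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return ((self.inverse() @ other).rotation_angle_deg() <= np.degrees(tol)
                and np.abs(self.offset - other.offset).max() <= tol)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "matrix": self.rotation.ravel().tolist(),
            "translation_mm": self.translation.tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["matrix"], dtype=float).reshape(3, 3),
                   d["translation_mm"], d.get("center_mm", (0.0, 0.0, 0.0)))
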