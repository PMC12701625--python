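"""Implant migration parameters from rigid transforms.

Migration of a tibial component relative to the tibia is summarised, per the
RSA convention, as translations (mm) and Cardan rotations (degrees) about the
anatomical axes (+x medial, +y proximal, +z anterior for a right knee),
their 3-D vector magnitudes TT and TR, and the maximum total point motion
(MTPM): the largest Euclidean displacement of any implant surface point under
the measured transform.

Rotations use the fixed-axes Cardan sequence x→y→z (``R = Rz @ Ry @ Rx``);
at the sub-degree magnitudes typical of migration the sequence effect is
second order, and the sequence tag is carried in every serialised result.
Left knees are mirrored about the sagittal plane and re-decomposed, so all
results are reported in the right-knee convention (Tx, Ry, Rz change sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .transform import RigidTransform
from .volume import VoxelMask

__all__ = ["MigrationResult", "ImplantModel", "relative_motion", "decompose", "mtpm"]

CARDAN_SEQUENCE = "fixed-xyz"

_MIRROR = np.diag([-1.0, 1.0, 1.0])  # sagittal-plane reflection


@dataclass(frozen=True)
class MigrationResult:
    """Migration of one implant relative to bone for one scan pair."""

    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float
    tt: float
    tr: float
    mtpm: float
    laterality: str = "right"
    point_count: int = 0

    def to_dict(self) -> dict:
        return {
            "MTPM": self.mtpm, "TT": self.tt, "TR": self.tr,
            "Tx": self.tx, "Ty": self.ty, "Tz": self.tz,
            "Rx": self.rx, "Ry": self.ry, "Rz": self.rz,
            "laterality": self.laterality, "point_count": self.point_count,
            "cardan_sequence": CARDAN_SEQUENCE,
        }

    PARAMETERS = ("MTPM", "TT", "TR", "Tx", "Ty", "Tz", "Rx", "Ry", "Rz")


@dataclass(frozen=True)
class ImplantModel:
    """Implant point model: mask-derived surface points and centre of gravity.

    The point set consists of the boundary voxel centres (6-connectivity
    boundary) of the implant mask; the CoG is the unweighted centroid of all
    implant mask voxel centres. For a rigid motion the maximum point
    displacement is attained on the convex hull, so boundary points suffice
    for MTPM.
    """

    surface_points: np.ndarray
    cog: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.surface_points, dtype=float).reshape(-1, 3)
        if pts.shape[0] == 0:
            raise ValueError("implant model requires a non-empty surface point set")
        object.__setattr__(self, "surface_points", pts)
        object.__setattr__(self, "cog", np.asarray(self.cog, dtype=float).reshape(3))

    @classmethod
    def from_mask(cls, mask: VoxelMask) -> "ImplantModel":
        if mask.voxel_count == 0:
            raise ValueError("cannot build implant model from empty mask")
        core = ndimage.binary_erosion(
            mask.grid, structure=ndimage.generate_binary_structure(3, 1))
        boundary = mask.grid & ~core
        surface = mask.index_to_world(np.argwhere(boundary))
        return cls(surface, mask.centroid())


def relative_motion(bone_t: RigidTransform, implant_t: RigidTransform) -> RigidTransform:
    """Implant motion relative to bone: ``bone_t⁻¹ ∘ implant_t``.

    Both inputs map baseline world points to follow-up world points, as
    returned by registration of each structure. The whole-limb component
    (patient repositioning between scans) cancels, leaving the implant's
    migration expressed in the baseline bone frame.
    """
    return bone_t.inverse() @ implant_t


def mtpm(motion: RigidTransform, points) -> float:
    """Maximum total point motion: ``max_p ||motion(p) - p||`` in mm."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError("MTPM requires a non-empty point set")
    disp = motion.apply(pts) - pts
    return float(np.sqrt((disp ** 2).sum(axis=1)).max())


def _mirror_transform(t: RigidTransform) -> RigidTransform:
    return RigidTransform(_MIRROR @ t.rotation @ _MIRROR, _MIRROR @ t.offset)


def decompose(motion: RigidTransform, model: ImplantModel,
              axes=None, laterality: str = "right") -> MigrationResult:
    """Decompose a relative motion into migration parameters.

    Parameters
    ----------
    motion : RigidTransform
        Implant motion relative to bone (baseline bone frame).
    model : ImplantModel
        Mask-derived implant points; translations are the displacement of its
        CoG, MTPM the maximum displacement over its surface points.
    axes : (3, 3) array, optional
        Columns give the anatomical axis directions (medial, proximal,
        anterior) in the working frame; defaults to the identity (the frame
        is already anatomical).
    laterality : {"right", "left"}
        Left knees are mirrored about the sagittal plane before
        decomposition, yielding right-knee-convention signs.
    """
    if laterality not in ("right", "left"):
        raise ValueError(f"laterality must be 'left' or 'right', got {laterality!r}")
    A = np.eye(3) if axes is None else np.asarray(axes, dtype=float).reshape(3, 3)
    if np.abs(A.T @ A - np.eye(3)).max() > 1e-9:
        raise ValueError("axes must form an orthonormal basis")

    pts = model.surface_points
    cog = model.cog
    if not np.allclose(A, np.eye(3)):
        # express everything in the anatomical basis
        motion = RigidTransform(A.T @ motion.rotation @ A, A.T @ motion.offset)
        pts = pts @ A
        cog = A.T @ cog
    if laterality == "left":
        motion = _mirror_transform(motion)
        pts = pts @ _MIRROR
        cog = _MIRROR @ cog

    t = motion.apply(cog) - cog
    rx, ry, rz = motion.euler_deg()
    max_disp = mtpm(motion, pts)
    tt = float(np.linalg.norm(t))
    tr = float(np.sqrt(rx * rx + ry * ry + rz * rz))
    return MigrationResult(
        tx=float(t[0]), ty=float(t[1]), tz=float(t[2]),
        rx=float(rx), ry=float(ry), rz=float(rz),
        tt=tt, tr=tr, mtpm=max_disp,
        laterality=laterality, point_count=int(pts.shape[0]),
    )
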