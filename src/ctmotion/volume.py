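"""In-memory CT volume and voxel-mask containers.

Voxel arrays are indexed ``[i, j, k]``; index axis ``i`` maps to world axis
x, ``j`` to y, ``k`` to z through the direction-cosine matrix:

    world = origin + direction @ (spacing * index)

All world coordinates are in millimetres, intensities in Hounsfield units.
The anatomical reporting frame used throughout is the RSA convention for a
right knee: +x medial, +y proximal, +z anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "VoxelMask"]


class _Grid:
    """Shared world-geometry behaviour of volumes and masks."""

    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def _check_geometry(self):
        sp = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(sp <= 0):
            raise ValueError("voxel spacing components must be positive")
        og = np.asarray(self.origin, dtype=float).reshape(3)
        D = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.abs(D.T @ D - np.eye(3)).max() > 1e-6:
            raise ValueError("direction matrix must be orthonormal")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", og)
        object.__setattr__(self, "direction", D)

    @property
    def shape(self) -> tuple:
        return self._array().shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * self.spacing @ self.direction.T + self.origin

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.origin) @ self.direction / self.spacing

    def same_geometry(self, other: "_Grid", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.direction, other.direction, atol=tol))

    def _array(self) -> np.ndarray:  # overridden
        raise NotImplementedError


@dataclass(frozen=True)
class CTVolume(_Grid):
    """3-D scalar field in HU with world geometry."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    #: acquisition metadata: slice_thickness (mm), pixel_spacing (mm)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {v.ndim}-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("HU values must be finite")
        object.__setattr__(self, "voxels", v)
        self._check_geometry()
        meta = dict(self.meta)
        # default acquisition metadata from the grid: slices stack along the
        # proximal (y/index-1) axis in the anatomical frame used here
        meta.setdefault("slice_thickness", float(self.spacing[1]))
        meta.setdefault("pixel_spacing", float(self.spacing[0]))
        object.__setattr__(self, "meta", meta)

    def _array(self) -> np.ndarray:
        return self.voxels

    @property
    def slice_thickness(self) -> float:
        return float(self.meta["slice_thickness"])

    @property
    def pixel_spacing(self) -> float:
        return float(self.meta["pixel_spacing"])


@dataclass(frozen=True)
class VoxelMask(_Grid):
    """Boolean voxel field sharing a :class:`CTVolume`'s geometry.

    ``role`` labels what the mask delineates ("bone" or "implant").
    """

    grid: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    role: str = "bone"

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {g.ndim}-D")
        object.__setattr__(self, "grid", g.astype(bool))
        self._check_geometry()
        if self.role not in ("bone", "implant"):
            raise ValueError(f"unknown mask role {self.role!r}")

    def _array(self) -> np.ndarray:
        return self.grid

    @classmethod
    def from_volume(cls, volume: CTVolume, grid: np.ndarray, role: str = "bone") -> "VoxelMask":
        if grid.shape != volume.shape:
            raise ValueError("mask shape must match source volume")
        return cls(grid, volume.spacing, volume.origin, volume.direction, role)

    def replace(self, grid: np.ndarray) -> "VoxelMask":
        return VoxelMask(grid, self.spacing, self.origin, self.direction, self.role)

    @property
    def voxel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def volume_cm3(self) -> float:
        """Mask volume in cm³ (voxel count × voxel volume)."""
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0

    def world_points(self) -> np.ndarray:
        """World coordinates (mm) of the centres of all true voxels."""
        idx = np.argwhere(self.grid)
        return self.index_to_world(idx)

    def centroid(self) -> np.ndarray:
        if self.voxel_count == 0:
            raise ValueError("empty mask has no centroid")
        return self.world_points().mean(axis=0)
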