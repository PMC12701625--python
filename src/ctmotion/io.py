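"""Volume, mask, transform and report I/O plus eligibility checks.

Volumes are read and written through SimpleITK (NIfTI ``.nii``/``.nii.gz``,
MetaImage ``.mha``/``.mhd``; DICOM series directories on read). On read the
world frame is taken from the file header; an ``axis_map`` (a signed
permutation of the scanner axes) can then remap a scanner-frame volume into
the anatomical RSA reporting frame (+x medial, +y proximal, +z anterior).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .transform import RigidTransform
from .volume import CTVolume, VoxelMask

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_mask",
    "read_transform", "write_transform", "check_eligibility",
    "remap_volume", "StudyConfig",
]


@dataclass(frozen=True)
class StudyConfig:
    """Study-level configuration for a migration analysis run."""

    laterality: str = "right"
    #: signed permutation mapping scanner axes to (medial, proximal, anterior);
    #: each entry is e.g. "+x", "-z"; identity means the data are already
    #: in the anatomical frame (as phantom volumes are).
    axis_map: tuple = ("+x", "+y", "+z")
    max_slice_thickness_mm: float = 1.0
    segmentation: dict = field(default_factory=dict)
    registration: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        _signed_permutation_matrix(self.axis_map)  # validates

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "axis_map" in d:
            d["axis_map"] = tuple(d["axis_map"])
        return cls(**d)


def _signed_permutation_matrix(axis_map) -> np.ndarray:
    cols = []
    for entry in axis_map:
        if len(entry) != 2 or entry[0] not in "+-" or entry[1] not in "xyz":
            raise ValueError(f"axis map entries must look like '+x', got {entry!r}")
        v = np.zeros(3)
        v["xyz".index(entry[1])] = 1.0 if entry[0] == "+" else -1.0
        cols.append(v)
    m = np.stack(cols, axis=1)
    if np.abs(np.abs(m).sum(axis=0) - 1).max() > 0 or np.abs(np.abs(m).sum(axis=1) - 1).max() > 0:
        raise ValueError("axis map must be a signed permutation of x, y, z")
    return m


def _from_sitk(img: sitk.Image) -> CTVolume:
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3-D volume, got {img.GetDimension()}-D")
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    meta = {}
    return CTVolume(arr.astype(np.float32), img.GetSpacing(), img.GetOrigin(),
                    direction, meta)


def read_volume(path) -> CTVolume:
    """Read a CT volume from NIfTI/MetaImage file or a DICOM directory."""
    path = os.fspath(path)
    if os.path.isdir(path):
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(path)
        if not files:
            raise ValueError(f"no DICOM series found in {path}")
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        img = sitk.ReadImage(path)
    return _from_sitk(img)


def write_volume(vol: CTVolume, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.transpose(vol.voxels, (2, 1, 0)).astype(np.float32)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(np.asarray(vol.direction, dtype=float).ravel()))
    sitk.WriteImage(img, os.fspath(path), useCompression=True)


def write_mask(mask: VoxelMask, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.transpose(mask.grid, (2, 1, 0)).astype(np.uint8)))
    img.SetSpacing(tuple(float(s) for s in mask.spacing))
    img.SetOrigin(tuple(float(o) for o in mask.origin))
    img.SetDirection(tuple(np.asarray(mask.direction, dtype=float).ravel()))
    sitk.WriteImage(img, os.fspath(path), useCompression=True)


def read_mask(path, role: str = "bone") -> VoxelMask:
    vol = read_volume(path)
    return VoxelMask(vol.voxels > 0.5, vol.spacing, vol.origin, vol.direction, role)


def write_transform(t: RigidTransform, path) -> None:
    with open(path, "w") as fh:
        json.dump(t.to_dict(), fh, indent=2)


def read_transform(path) -> RigidTransform:
    with open(path) as fh:
        return RigidTransform.from_dict(json.load(fh))


def remap_volume(vol: CTVolume, axis_map) -> CTVolume:
    """Reorder/flip voxel axes so the array is in the anatomical frame.

    ``axis_map[i]`` names the scanner axis (with sign) that becomes
    anatomical axis i. The world geometry is updated consistently, so world
    positions of tissue are preserved up to the frame relabelling.
    """
    if not np.allclose(vol.direction, np.eye(3)):
        raise ValueError("axis remapping requires an axis-aligned (identity-direction) volume")
    m = _signed_permutation_matrix(axis_map)
    src = [int(np.flatnonzero(m[:, i])[0]) for i in range(3)]
    signs = [int(m[src[i], i]) for i in range(3)]
    vox = np.transpose(vol.voxels, src)
    spacing = np.asarray(vol.spacing)[src]
    origin = np.empty(3)
    old_origin = np.asarray(vol.origin)
    old_shape = np.asarray(vol.shape)
    for i, (s, sg) in enumerate(zip(src, signs)):
        if sg > 0:
            origin[i] = old_origin[s]
        else:
            vox = np.flip(vox, axis=i)
            origin[i] = -old_origin[s] - vol.spacing[s] * (old_shape[s] - 1)
    return CTVolume(np.ascontiguousarray(vox), spacing, origin, np.eye(3),
                    dict(vol.meta))


def check_eligibility(baseline: CTVolume, followup: CTVolume,
                      cfg: StudyConfig = None) -> dict:
    """Scan-quality eligibility report.

    A pair is eligible when both scans have slice thickness strictly below
    the configured maximum (default 1.0 mm). Report-only: never raises.
    """
    cfg = cfg or StudyConfig()
    thicknesses = (baseline.slice_thickness, followup.slice_thickness)
    eligible = all(t < cfg.max_slice_thickness_mm for t in thicknesses)
    return {
        "eligible": bool(eligible),
        "slice_thickness_baseline_mm": float(thicknesses[0]),
        "slice_thickness_followup_mm": float(thicknesses[1]),
        "max_slice_thickness_mm": float(cfg.max_slice_thickness_mm),
        "pixel_spacing_baseline_mm": float(baseline.pixel_spacing),
        "pixel_spacing_followup_mm": float(followup.pixel_spacing),
    }
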