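"""Bone and implant mask construction from the baseline CT volume.

The segmentation recipe mirrors standard clinical mask workflows: HU
thresholding, region growing from seed points, erosion/dilation cleanup,
removal of the scatter-degraded proximal bone directly under the tibial
baseplate, and subtraction of the implant mask from the bone mask so the two
registration masks are disjoint. Threshold values are observer choices; the
defaults (bone 430 HU, implant 2200 HU) are typical clinical medians.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume, VoxelMask

__all__ = [
    "SegmentationParams", "threshold_mask", "region_grow", "morph",
    "proximal_cut", "subtract_implant", "bone_length", "segmentation_report",
    "segment_bone", "segment_implant", "tray_plane_from_implant",
]

log = logging.getLogger(__name__)

#: bone length below which registration quality becomes doubtful (mm)
MIN_RECOMMENDED_BONE_LENGTH_MM = 70.0

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Observer-chosen segmentation parameters.

    ``threshold_bone``/``threshold_implant`` are lower HU bounds; bone is
    additionally bounded above by ``bone_upper_hu`` (default 1900 HU, below
    any metal) so partial-volume metal voxels never enter the bone mask.
    """

    threshold_bone: float = 430.0
    threshold_implant: float = 2200.0
    bone_upper_hu: float = 1900.0
    seed_points: tuple = ()          # world points, empty = keep largest component
    erosion_radius_vox: int = 1
    dilation_radius_vox: int = 1
    proximal_cut_mm: float = 5.0
    fill_holes: bool = True
    subtract_margin_mm: float = 3.0  # metal exclusion halo width around the implant
    #: voxels at or above this HU are metal partial volume (no bone tissue is
    #: brighter); they and their halo are excluded from the bone mask so no
    #: implant-attached intensity leaks into the bone registration
    metal_exclusion_hu: float = 1000.0

    def __post_init__(self):
        if self.threshold_implant <= self.threshold_bone:
            raise ValueError("implant threshold must exceed bone threshold")
        if self.erosion_radius_vox < 0 or self.dilation_radius_vox < 0:
            raise ValueError("morphology radii must be non-negative")
        if self.proximal_cut_mm < 0:
            raise ValueError("proximal cut must be non-negative")


def _ball(radius: int) -> np.ndarray:
    """Discrete Euclidean ball structuring element in voxel units."""
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    g = np.indices((2 * r + 1,) * 3) - r
    return (g ** 2).sum(axis=0) <= r * r


def threshold_mask(volume: CTVolume, lo: float, hi: float = np.inf,
                   role: str = "bone") -> VoxelMask:
    """Mask of voxels with ``lo <= HU`` (``< hi`` when bounded)."""
    if not lo < hi:
        raise ValueError("lower threshold must be below upper threshold")
    grid = (volume.voxels >= lo)
    if np.isfinite(hi):
        grid &= volume.voxels < hi
    mask = VoxelMask.from_volume(volume, grid, role)
    if mask.voxel_count == 0:
        log.warning("threshold [%s, %s) HU selected no voxels", lo, hi)
    return mask


def region_grow(mask: VoxelMask, seeds) -> VoxelMask:
    """Keep only the 26-connected components containing at least one seed.

    Seeds are world points. A seed outside the grid raises; a seed on a
    false voxel is ignored with a warning.
    """
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 3)
    idx = np.rint(mask.world_to_index(seeds)).astype(int)
    shape = np.asarray(mask.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError("seed point falls outside the image grid")
    labels, _ = ndimage.label(mask.grid, structure=_CONN26)
    keep = set()
    for i, j, k in idx:
        lab = labels[i, j, k]
        if lab == 0:
            warnings.warn(f"seed at index ({i},{j},{k}) lies on background; ignored")
        else:
            keep.add(lab)
    if not keep:
        return mask.replace(np.zeros(mask.shape, dtype=bool))
    return mask.replace(np.isin(labels, sorted(keep)))


def largest_component(mask: VoxelMask) -> VoxelMask:
    """Keep the largest 26-connected component (seedless convention)."""
    labels, n = ndimage.label(mask.grid, structure=_CONN26)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return mask.replace(labels == counts.argmax())


def morph(mask: VoxelMask, op: str, radius_vox: int) -> VoxelMask:
    """Binary erosion or dilation with a voxel-radius Euclidean ball.

    Radius 0 is the identity. Anisotropic spacing is deliberately ignored:
    the element is defined in voxel units, matching common segmentation-tool
    behaviour.
    """
    if radius_vox < 0:
        raise ValueError("radius must be non-negative")
    if radius_vox == 0:
        return mask
    ball = _ball(radius_vox)
    if op == "erode":
        out = ndimage.binary_erosion(mask.grid, structure=ball)
    elif op == "dilate":
        out = ndimage.binary_dilation(mask.grid, structure=ball)
    else:
        raise ValueError(f"morphology op must be 'erode' or 'dilate', got {op!r}")
    return mask.replace(out)


def proximal_cut(bone: VoxelMask, tray_plane, cut_mm: float) -> VoxelMask:
    """Remove scatter-degraded bone near and above the baseplate plane.

    ``tray_plane`` is ``(point, normal)`` in world mm with the normal
    pointing proximally. All bone voxels proximal to the plane, and those
    within ``cut_mm`` distal of it, are removed.
    """
    point, normal = (np.asarray(a, dtype=float).reshape(3) for a in tray_plane)
    n = normal / np.linalg.norm(normal)
    pts = bone.index_to_world(np.argwhere(bone.grid))
    signed = (pts - point) @ n
    remove = signed >= -cut_mm
    out = bone.grid.copy()
    out[tuple(np.argwhere(bone.grid)[remove].T)] = False
    if not out.any():
        raise ValueError("proximal cut removed the entire bone mask (cut too aggressive)")
    return bone.replace(out)


def subtract_implant(bone: VoxelMask, implant: VoxelMask) -> VoxelMask:
    """Bone AND NOT implant; output is disjoint from the implant mask."""
    if not bone.same_geometry(implant):
        raise ValueError("bone and implant masks must share the same geometry")
    return bone.replace(bone.grid & ~implant.grid)


def bone_length(bone: VoxelMask, proximal_axis=(0.0, 1.0, 0.0)) -> float:
    """Extent (mm) of the bone mask projected on the proximal axis.

    Warns when less than 7 cm of tibial bone is available for matching.
    """
    if bone.voxel_count == 0:
        raise ValueError("bone length undefined for an empty mask")
    axis = np.asarray(proximal_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = bone.world_points() @ axis
    # voxel centres span (max - min); add the projected voxel footprint so a
    # single voxel reports one voxel's extent
    voxel_extent = float(np.abs(axis) @ np.abs(bone.direction) @ bone.spacing)
    length = float(proj.max() - proj.min()) + voxel_extent
    if length < MIN_RECOMMENDED_BONE_LENGTH_MM:
        warnings.warn(
            f"bone length {length / 10:.1f} cm is below the recommended 7 cm "
            "of tibial bone for reliable registration")
    return length


def tray_plane_from_implant(implant: VoxelMask, proximal_axis=(0.0, 1.0, 0.0)):
    """Plane through the distal face of the tray slab, normal proximal.

    The tray is identified as the contiguous run of slabs (perpendicular to
    the proximal axis) whose cross-sectional voxel count is at least half the
    maximum; the plane passes through the distal face of that run.
    """
    if implant.voxel_count == 0:
        raise ValueError("cannot derive tray plane from empty implant mask")
    axis = np.asarray(proximal_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pts = implant.world_points()
    proj = pts @ axis
    # histogram voxel counts along the axis in slice-thickness bins
    step = float(np.min(implant.spacing))
    bins = np.arange(proj.min() - step / 2, proj.max() + step, step)
    counts, edges = np.histogram(proj, bins=bins)
    jmax = int(counts.argmax())
    thr = counts[jmax] / 2.0
    j = jmax
    while j > 0 and counts[j - 1] >= thr:
        j -= 1
    plane_level = edges[j]
    centroid = pts.mean(axis=0)
    point = centroid + axis * (plane_level - float(centroid @ axis))
    return point, axis


def segmentation_report(params: SegmentationParams, bone: VoxelMask,
                        implant: VoxelMask, observer: str = "OBS1") -> pd.DataFrame:
    """Per-observer segmentation summary: thresholds (HU), volumes (cm³)."""
    return pd.DataFrame(
        [
            {"quantity": "Threshold_Bone (HU)", "value": params.threshold_bone},
            {"quantity": "Threshold_Implant (HU)", "value": params.threshold_implant},
            {"quantity": "Volume_Bone (cm3)", "value": bone.volume_cm3},
            {"quantity": "Volume_Implant (cm3)", "value": implant.volume_cm3},
            {"quantity": "Bone_Length (mm)", "value": bone_length_safe(bone)},
        ],
        columns=["quantity", "value"],
    ).assign(observer=observer)


def bone_length_safe(bone: VoxelMask) -> float:
    if bone.voxel_count == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bone_length(bone)


def compare_reports(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Two-observer comparison with absolute differences per quantity."""
    merged = a.merge(b, on="quantity", suffixes=("_a", "_b"))
    merged["abs_dif"] = (merged["value_a"] - merged["value_b"]).abs()
    return merged[["quantity", "value_a", "value_b", "abs_dif"]]


# ---------------------------------------------------------------------------
# composite recipes used by the pipeline

def segment_implant(volume: CTVolume, params: SegmentationParams) -> VoxelMask:
    """Threshold + component selection + optional hole fill for the implant."""
    mask = threshold_mask(volume, params.threshold_implant, role="implant")
    mask = _select(mask, params)
    if params.fill_holes:
        mask = mask.replace(ndimage.binary_fill_holes(mask.grid))
    return mask


def segment_bone(volume: CTVolume, params: SegmentationParams,
                 implant: VoxelMask = None) -> VoxelMask:
    """Full bone-mask recipe.

    Threshold into the bone HU window, keep the seeded (or largest)
    component, fill the trabecular interior enclosed by the cortical shell,
    light open (erode/dilate) cleanup, cut the scatter-degraded proximal
    bone below the baseplate, and subtract the (safety-dilated) implant.
    """
    mask = threshold_mask(volume, params.threshold_bone, params.bone_upper_hu, role="bone")
    excl = None
    if implant is not None:
        # exclude the implant plus every metal-partial-volume voxel (and a
        # safety halo) before component search: those intensities move with
        # the implant, not the bone
        metal = implant.grid | (volume.voxels >= params.metal_exclusion_hu)
        margin = int(np.ceil(params.subtract_margin_mm / float(np.min(volume.spacing))))
        excl = morph(implant.replace(metal), "dilate", margin)
        mask = subtract_implant(mask, excl)
    mask = _select(mask, params)
    if params.fill_holes:
        # fill the trabecular interior slice-by-slice perpendicular to the
        # bone axis: robust even where scatter breaks the 3-D shell
        filled = mask.grid.copy()
        for j in range(filled.shape[1]):
            filled[:, j, :] = ndimage.binary_fill_holes(filled[:, j, :])
        mask = mask.replace(filled)
    if params.erosion_radius_vox:
        mask = morph(mask, "erode", params.erosion_radius_vox)
    if params.dilation_radius_vox:
        mask = morph(mask, "dilate", params.dilation_radius_vox)
    if implant is not None:
        plane = tray_plane_from_implant(implant)
        mask = proximal_cut(mask, plane, params.proximal_cut_mm)
        mask = subtract_implant(mask, excl)
    return mask


def _select(mask: VoxelMask, params: SegmentationParams) -> VoxelMask:
    if len(params.seed_points):
        return region_grow(mask, params.seed_points)
    return largest_component(mask)
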