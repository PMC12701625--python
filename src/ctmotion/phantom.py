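"""Digital tibia + tibial-tray phantom with known rigid micromotion.

Generates analytically defined baseline/follow-up CT pairs so that every
downstream stage (segmentation, registration, migration) can be validated
against exact ground truth. The phantom emulates a proximal tibia with a
cemented metal baseplate:

* bone: tapered cylinder along the proximal (+y) axis with a cortical shell,
  closed by a cortical cap distally and a subchondral plate proximally;
* implant: an oval tray plate with a posterior cutout resting on the
  plateau, a central finned stem extending distally into the bone, and two
  peripheral fixation pegs;
* intensities: trabecular / cortical / metal HU levels chosen so that
  clinically typical bone (220–770 HU) and implant (1900–3100 HU)
  thresholds segment both structures;
* artefacts: independent Gaussian HU noise per scan, and a structured
  zero-mean streak band directly distal to the baseplate emulating metal
  scatter (the reason the most proximal bone is cut before registration);
* motion: the follow-up scan applies a whole-limb repositioning transform to
  everything and an additional implant micromotion in the bone frame.

Voxel values are obtained by supersampled analytic evaluation of the
geometry (default 5×5×5 samples per voxel, applied exactly where cells
straddle a material surface), never by resampling the baseline grid, so
sub-voxel motion is encoded through partial-volume fractions as in real CT.

Frames: phantom volumes are emitted directly in the anatomical RSA frame
(+x medial, +y proximal, +z anterior, right knee); slices stack along +y,
so ``spacing[1]`` is the slice thickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .migration import MigrationResult
from .transform import RigidTransform
from .volume import CTVolume

__all__ = [
    "PhantomSpec", "GroundTruthMotion", "generate_pair",
    "analytic_migration", "implant_surface_points", "implant_cog",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and acquisition parameters of the digital phantom.

    All lengths in mm, intensities in HU. The default acquisition grid uses
    0.4 mm slices and 0.5 mm pixels, the median values seen in clinical knee
    protocols; `compact()` provides a coarser, smaller phantom for fast
    testing (0.5 mm slices, 0.8 mm pixels — still within the clinically
    observed 0.3–0.5 / 0.3–0.8 mm ranges).
    """

    # bone: tapered cylinder along +y
    bone_length_mm: float = 80.0
    bone_radius_proximal_mm: float = 20.0
    bone_radius_distal_mm: float = 12.0
    cortical_thickness_mm: float = 3.0
    #: anterior-posterior/medial-lateral radius ratio (tibiae are not round)
    bone_aspect_z: float = 0.8
    #: anterior crest: ridge height as a fraction of the local radius
    bone_crest_frac: float = 0.25
    # implant: tray plate + stem + fins
    tray_radius_mm: float = 22.0
    tray_thickness_mm: float = 4.0
    #: anterior-posterior/medial-lateral tray radius ratio (baseplates are oval)
    tray_aspect_z: float = 0.85
    #: fractional depth of the posterior cutout of the baseplate
    tray_notch_frac: float = 0.45
    stem_radius_mm: float = 6.0
    stem_length_mm: float = 30.0
    fin_count: int = 4
    fin_length_mm: float = 8.0
    fin_thickness_mm: float = 1.6
    #: peripheral fixation pegs under the tray (medial + lateral)
    peg_count: int = 2
    peg_radius_mm: float = 3.5
    peg_length_mm: float = 14.0
    peg_offset_mm: float = 12.0
    # intensities
    hu_trabecular: float = 300.0
    hu_cortical: float = 600.0
    hu_implant: float = 2500.0
    hu_background: float = -50.0
    #: amplitude (HU, SD) of the deterministic trabecular texture field.
    #: Real trabecular bone is not uniform; this geometry-attached pattern
    #: is what makes all six bone degrees of freedom observable, exactly as
    #: trabecular structure does in clinical scans.
    trabecular_texture_sd: float = 60.0
    noise_sd: float = 20.0
    remodeling_sd: float = 0.0
    # scatter band under the baseplate
    scatter_band_mm: float = 5.0
    scatter_amplitude_hu: float = 150.0
    scatter_streaks: int = 12
    #: in-plane/axial reconstruction point-spread sigma (mm): clinical bone
    #: kernels resolve about 1.0 lp/mm, so edges spread over ~2 voxels
    psf_sigma_mm: float = 0.35
    # acquisition grid
    spacing: tuple = (0.5, 0.4, 0.5)
    volume_shape: tuple = (112, 232, 112)
    distal_margin_mm: float = 5.0
    # motion
    repositioning: RigidTransform = field(default_factory=RigidTransform.identity)
    implant_motion: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0
    supersample: int = 5

    def __post_init__(self):
        if not (self.hu_implant > self.hu_cortical > self.hu_trabecular > self.hu_background):
            raise ValueError("HU levels must satisfy implant > cortical > trabecular > background")
        if self.noise_sd < 0 or self.remodeling_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if self.supersample < 1:
            raise ValueError("supersample factor must be >= 1")

    # -- derived geometry --------------------------------------------------
    @property
    def axis_xz(self) -> tuple:
        """Bone axis position in the x–z plane (volume centre)."""
        nx, _, nz = self.volume_shape
        return ((nx - 1) * self.spacing[0] / 2.0, (nz - 1) * self.spacing[2] / 2.0)

    @property
    def bone_base_y(self) -> float:
        return self.distal_margin_mm

    @property
    def plateau_y(self) -> float:
        """y of the tibial plateau = bottom face of the tray plate."""
        return self.bone_base_y + self.bone_length_mm

    @classmethod
    def compact(cls, **overrides) -> "PhantomSpec":
        """Small fast phantom for testing (same structure, coarser grid)."""
        base = dict(
            bone_length_mm=45.0, bone_radius_proximal_mm=13.0,
            bone_radius_distal_mm=9.0, cortical_thickness_mm=2.5,
            tray_radius_mm=16.0, tray_thickness_mm=3.0,
            stem_radius_mm=4.5, stem_length_mm=18.0,
            fin_count=4, fin_length_mm=5.0, fin_thickness_mm=1.6,
            peg_radius_mm=2.5, peg_length_mm=10.0, peg_offset_mm=9.0,
            spacing=(0.8, 0.5, 0.8), volume_shape=(52, 112, 52),
            distal_margin_mm=4.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def desk(cls, **overrides) -> "PhantomSpec":
        """Compact geometry at the clinical-median grid (0.4 mm slices,
        0.5 mm pixels): the resolution used for accuracy studies."""
        base = dict(spacing=(0.5, 0.4, 0.5), volume_shape=(84, 140, 84))
        base.update(overrides)
        return cls.compact(**base)

    def with_motion(self, implant_motion: RigidTransform = None,
                    repositioning: RigidTransform = None, **overrides) -> "PhantomSpec":
        kw = dict(overrides)
        if implant_motion is not None:
            kw["implant_motion"] = implant_motion
        if repositioning is not None:
            kw["repositioning"] = repositioning
        return replace(self, **kw)


@dataclass(frozen=True)
class GroundTruthMotion:
    """Known implant-relative-to-bone migration and its analytic parameters."""

    migration: RigidTransform
    reference: MigrationResult

    def to_dict(self) -> dict:
        return {"migration": self.migration.to_dict(),
                "reference_parameters": self.reference.to_dict()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# analytic geometry

def _peg_angles(spec: PhantomSpec) -> np.ndarray:
    if spec.peg_count <= 0:
        return np.empty(0)
    # pegs on the medial-lateral axis, clear of the posterior notch
    return np.pi * np.arange(spec.peg_count)


def _tray_profile(spec: PhantomSpec, theta) -> np.ndarray:
    """Normalised tray boundary radius vs azimuth.

    An oval plate with a smooth posterior cutout — the asymmetric footprint
    of a real tibial baseplate, which is what makes axial implant rotation
    observable in the images.
    """
    g = np.sqrt(np.cos(theta) ** 2 + (spec.tray_aspect_z * np.sin(theta)) ** 2)
    # posterior notch at theta = -pi/2 (z < 0)
    g = g * (1.0 - spec.tray_notch_frac * np.exp(-((np.asarray(theta) + np.pi / 2) / 0.35) ** 2))
    return g


def _material_code(spec: PhantomSpec, pts_bone: np.ndarray, pts_impl: np.ndarray) -> np.ndarray:
    """Material at sample points: 0 background, 1 trabecular, 2 cortical, 3 metal."""
    cx, cz = spec.axis_xz
    y0, y1 = spec.bone_base_y, spec.plateau_y

    # implant occupancy (implant-frame coordinates)
    xi = pts_impl[:, 0] - cx
    yi = pts_impl[:, 1]
    zi = pts_impl[:, 2] - cz
    rho_i = np.hypot(xi, zi)
    theta_i = np.arctan2(zi, xi)
    tray = (yi >= y1) & (yi <= y1 + spec.tray_thickness_mm) & \
        (rho_i <= spec.tray_radius_mm * _tray_profile(spec, theta_i))
    stem = (yi >= y1 - spec.stem_length_mm) & (yi < y1) & (rho_i <= spec.stem_radius_mm)
    implant = tray | stem
    if spec.fin_count > 0:
        fin_top = y1
        fin_bottom = y1 - 0.7 * spec.stem_length_mm
        fin_band = (yi >= fin_bottom) & (yi < fin_top) & \
                   (rho_i <= spec.stem_radius_mm + spec.fin_length_mm)
        if fin_band.any():
            xb, zb = xi[fin_band], zi[fin_band]
            hit = np.zeros(xb.shape, dtype=bool)
            for k in range(spec.fin_count):
                ang = 2.0 * np.pi * k / spec.fin_count
                d = xb * np.cos(ang) + zb * np.sin(ang)        # radial coord
                s = -xb * np.sin(ang) + zb * np.cos(ang)       # off-plane coord
                hit |= (d >= 0) & (np.abs(s) <= spec.fin_thickness_mm / 2.0)
            fins = np.zeros(implant.shape, dtype=bool)
            fins[fin_band] = hit
            implant |= fins
    for ang in _peg_angles(spec):
        px = spec.peg_offset_mm * np.cos(ang)
        pz = spec.peg_offset_mm * np.sin(ang)
        peg = (yi >= y1 - spec.peg_length_mm) & (yi < y1) & \
            (np.hypot(xi - px, zi - pz) <= spec.peg_radius_mm)
        implant |= peg

    # bone occupancy (bone-frame coordinates)
    xb = pts_bone[:, 0] - cx
    yb = pts_bone[:, 1]
    zb = pts_bone[:, 2] - cz
    frac = np.clip((yb - y0) / spec.bone_length_mm, 0.0, 1.0)
    r_out = spec.bone_radius_distal_mm + \
        (spec.bone_radius_proximal_mm - spec.bone_radius_distal_mm) * frac
    # elliptical cross-section with an anterior crest ridge: the azimuthal
    # asymmetry of a real tibia, which makes axial rotation observable
    theta_b = np.arctan2(zb, xb)
    r_dir = r_out * np.sqrt(
        np.cos(theta_b) ** 2 + (spec.bone_aspect_z * np.sin(theta_b)) ** 2)
    crest = 1.0 + spec.bone_crest_frac * np.exp(-((theta_b - np.pi / 2) / 0.45) ** 2)
    r_dir = r_dir * crest
    rho_b = np.hypot(xb, zb)
    in_bone = (yb >= y0) & (yb <= y1) & (rho_b <= r_dir)
    cortical = in_bone & (
        (rho_b >= r_dir - spec.cortical_thickness_mm)
        | (yb >= y1 - spec.cortical_thickness_mm)   # subchondral plate
        | (yb <= y0 + spec.cortical_thickness_mm)   # distal cap
    )

    code = np.zeros(pts_bone.shape[0], dtype=np.uint8)
    code[in_bone] = 1
    code[cortical] = 2
    code[implant] = 3
    return code


def _occupancy_hu(spec: PhantomSpec, pts_bone: np.ndarray, pts_impl: np.ndarray,
                  texture_atten=None) -> np.ndarray:
    """HU at sample points, given coordinates in the bone and implant frames.

    ``texture_atten`` optionally applies per-wave attenuation factors to the
    trabecular texture (the exact cell-average of each plane wave), used when
    a single centre sample stands in for a full supersample cell.
    """
    code = _material_code(spec, pts_bone, pts_impl)
    lut = np.array([spec.hu_background, spec.hu_trabecular,
                    spec.hu_cortical, spec.hu_implant])
    hu = lut[code]
    if spec.trabecular_texture_sd > 0:
        trab = code == 1
        if trab.any():
            hu[trab] += _trabecular_texture(pts_bone[trab], texture_atten) \
                * spec.trabecular_texture_sd
    return hu


# fixed quasi-random plane-wave bank (geometry constant: identical for every
# phantom and seed, rigidly attached to the bone frame like real trabeculae)
_TEXTURE_RNG = np.random.default_rng(7041776)
_TEXTURE_DIRS = _TEXTURE_RNG.normal(size=(12, 3))
_TEXTURE_DIRS /= np.linalg.norm(_TEXTURE_DIRS, axis=1, keepdims=True)
_TEXTURE_K = (2.0 * np.pi / _TEXTURE_RNG.uniform(3.0, 9.0, size=(12, 1))) * _TEXTURE_DIRS
_TEXTURE_PHI = _TEXTURE_RNG.uniform(0.0, 2.0 * np.pi, size=12)


def _trabecular_texture(points: np.ndarray, atten=None) -> np.ndarray:
    """Unit-SD smooth texture: sum of fixed 3-D plane waves (3–9 mm scale)."""
    phase = points @ _TEXTURE_K.T + _TEXTURE_PHI
    waves = np.sin(phase)
    if atten is not None:
        waves = waves * atten
    return waves.sum(axis=1) / np.sqrt(_TEXTURE_K.shape[0] / 2.0)


def _texture_cell_attenuation(offsets: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Exact per-wave attenuation of the cell-average of each plane wave.

    For a symmetric supersample offset grid, the average of
    ``sin(k·(R(p+o)) + φ)`` over offsets ``o`` equals
    ``sin(k·Rp + φ) · Π_i mean_j cos(k'_i o_ij)`` with ``k' = Rᵀk``.
    """
    kp = _TEXTURE_K @ rotation                      # (n_waves, 3)
    # offsets is a product grid; recover the per-axis offset values
    axes = [np.unique(offsets[:, i]) for i in range(3)]
    att = np.ones(_TEXTURE_K.shape[0])
    for i in range(3):
        att *= np.cos(np.outer(kp[:, i], axes[i])).mean(axis=1)
    return att


def _voxelize(spec: PhantomSpec, bone_map: RigidTransform, impl_map: RigidTransform) -> np.ndarray:
    """Supersampled analytic voxelization.

    ``bone_map`` / ``impl_map`` map scanner-world points into the structure's
    own (baseline) frame — i.e. the inverses of the applied motions.
    """
    nx, ny, nz = spec.volume_shape
    s = spec.supersample
    sp = np.asarray(spec.spacing)
    # supersample offsets in voxel units, centred on the voxel
    off = (np.arange(s) + 0.5) / s - 0.5
    ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1) * sp  # (s^3, 3)

    Rb, bb = bone_map.rotation, bone_map.offset
    Ri, bi = impl_map.rotation, impl_map.offset

    # pass 1: voxel centres only; the trabecular texture is attenuated by the
    # exact cell-average factor of each plane wave, so a uniform-material
    # voxel's centre value equals its full supersample mean
    centres = _voxel_centres(spec)
    pb = centres @ Rb.T + bb
    pi = centres @ Ri.T + bi
    codes = _material_code(spec, pb, pi).reshape(nx, ny, nz)
    atten = _texture_cell_attenuation(offsets, Rb)
    out = _occupancy_hu(spec, pb, pi, texture_atten=atten) \
        .reshape(nx, ny, nz).astype(np.float32)
    if s == 1:
        return out

    # pass 2: full supersampling only for cells that straddle a material
    # surface, detected exactly from the 8 cell-corner materials — everywhere
    # else the centre value is already exact
    corner_idx = np.stack(np.meshgrid(np.arange(nx + 1), np.arange(ny + 1),
                                      np.arange(nz + 1), indexing="ij"),
                          axis=-1).reshape(-1, 3) - 0.5
    cpts = corner_idx * sp
    ccodes = _material_code(spec, cpts @ Rb.T + bb, cpts @ Ri.T + bi) \
        .reshape(nx + 1, ny + 1, nz + 1)
    cmin = np.full((nx, ny, nz), 255, dtype=np.uint8)
    cmax = np.zeros((nx, ny, nz), dtype=np.uint8)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                view = ccodes[di:di + nx, dj:dj + ny, dk:dk + nz]
                np.minimum(cmin, view, out=cmin)
                np.maximum(cmax, view, out=cmax)
    mixed = (cmin != cmax) | (codes != cmin)
    idx = np.argwhere(mixed)
    chunk = max(1, int(4e6 / offsets.shape[0]))
    for k0 in range(0, idx.shape[0], chunk):
        sub = idx[k0:k0 + chunk]
        pts = (sub * sp)[:, None, :] + offsets[None, :, :]
        pts = pts.reshape(-1, 3)
        hu = _occupancy_hu(spec, pts @ Rb.T + bb, pts @ Ri.T + bi)
        out[tuple(sub.T)] = hu.reshape(sub.shape[0], offsets.shape[0]) \
            .mean(axis=1).astype(np.float32)
    return out


def _apply_scatter(spec: PhantomSpec, voxels: np.ndarray, impl_map: RigidTransform) -> None:
    """Structured zero-mean streak corruption directly distal to the tray.

    Modelled as an angular streak modulation of the linear-attenuation scale
    (HU + 1000), confined to a band of ``scatter_band_mm`` below the
    baseplate and fading linearly with depth. The pattern is deterministic
    and rigidly attached to the implant, as physical scatter would be.
    """
    if spec.scatter_band_mm <= 0 or spec.scatter_amplitude_hu == 0:
        return
    nx, ny, nz = spec.volume_shape
    sp = np.asarray(spec.spacing)
    idx = np.indices((nx, ny, nz)).reshape(3, -1).T * sp
    p = idx @ impl_map.rotation.T + impl_map.offset  # implant-frame coords
    cx, cz = spec.axis_xz
    x, y, z = p[:, 0] - cx, p[:, 1], p[:, 2] - cz
    y1 = spec.plateau_y
    depth = y1 - y
    in_band = (depth > 0) & (depth <= spec.scatter_band_mm) & \
              (np.hypot(x, z) <= spec.tray_radius_mm)
    if not in_band.any():
        return
    theta = np.arctan2(z[in_band], x[in_band])
    fade = 1.0 - depth[in_band] / spec.scatter_band_mm
    factor = 1.0 + (spec.scatter_amplitude_hu / 1000.0) * np.sin(spec.scatter_streaks * theta) * fade
    flat = voxels.reshape(-1)
    flat[in_band] = (flat[in_band] + 1000.0) * factor - 1000.0


def _apply_psf(spec: PhantomSpec, voxels) -> None:
    """Reconstruction point-spread: isotropic Gaussian blur in mm."""
    if spec.psf_sigma_mm <= 0:
        return
    from scipy.ndimage import gaussian_filter
    sig = [spec.psf_sigma_mm / s for s in spec.spacing]
    voxels[...] = gaussian_filter(voxels, sigma=sig)


def _check_inside(spec: PhantomSpec, name: str, pts: np.ndarray) -> None:
    sp = np.asarray(spec.spacing)
    hi = (np.asarray(spec.volume_shape) - 1) * sp
    if np.any(pts < -sp / 2) or np.any(pts > hi + sp / 2):
        raise ValueError(f"{name} geometry extends outside the phantom volume")


def implant_surface_points(spec: PhantomSpec, step_mm: float = 1.5) -> np.ndarray:
    """Analytic sampling of the implant surface (baseline frame, world mm)."""
    cx, cz = spec.axis_xz
    y1 = spec.plateau_y
    pts = []

    def ring(radius, y, n):
        a = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.stack([cx + radius * np.cos(a),
                         np.full(n, y),
                         cz + radius * np.sin(a)], axis=1)

    def tray_ring(scale, y, n):
        a = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = scale * spec.tray_radius_mm * _tray_profile(spec, a)
        return np.stack([cx + r * np.cos(a), np.full(n, y), cz + r * np.sin(a)], axis=1)

    n_ang = 72
    for y in (y1, y1 + spec.tray_thickness_mm):          # tray rim + faces
        pts.append(tray_ring(1.0, y, n_ang))
        for s in np.arange(step_mm / spec.tray_radius_mm, 1.0, step_mm / spec.tray_radius_mm):
            pts.append(tray_ring(s, y, max(8, int(2 * np.pi * s * spec.tray_radius_mm / step_mm))))
    for y in np.arange(y1, y1 + spec.tray_thickness_mm + 1e-9, step_mm / 2):
        pts.append(tray_ring(1.0, y, n_ang))             # tray lateral band
    y_bot = y1 - spec.stem_length_mm
    pts.append(ring(spec.stem_radius_mm, y_bot, 36))     # stem bottom rim
    for r in np.arange(0, spec.stem_radius_mm, step_mm):
        pts.append(ring(r, y_bot, max(6, int(2 * np.pi * max(r, 0.5) / step_mm))))
    for y in np.arange(y_bot, y1, step_mm):
        pts.append(ring(spec.stem_radius_mm, y, 36))     # stem lateral
    for ang in _peg_angles(spec):                        # peg surfaces
        px, pz = cx + spec.peg_offset_mm * np.cos(ang), cz + spec.peg_offset_mm * np.sin(ang)
        yb_peg = y1 - spec.peg_length_mm
        a = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        pts.append(np.stack([px + spec.peg_radius_mm * np.cos(a),
                             np.full(24, yb_peg),
                             pz + spec.peg_radius_mm * np.sin(a)], axis=1))
        for y in np.arange(yb_peg, y1, step_mm):
            pts.append(np.stack([px + spec.peg_radius_mm * np.cos(a),
                                 np.full(24, y),
                                 pz + spec.peg_radius_mm * np.sin(a)], axis=1))
    if spec.fin_count > 0:                               # fin outer edges
        r_fin = spec.stem_radius_mm + spec.fin_length_mm
        ys = np.arange(y1 - 0.7 * spec.stem_length_mm, y1, step_mm / 2)
        for k in range(spec.fin_count):
            ang = 2 * np.pi * k / spec.fin_count
            edge = np.stack([cx + r_fin * np.cos(ang) * np.ones_like(ys),
                             ys,
                             cz + r_fin * np.sin(ang) * np.ones_like(ys)], axis=1)
            pts.append(edge)
    return np.concatenate(pts, axis=0)


def implant_cog(spec: PhantomSpec) -> np.ndarray:
    """Analytic centre of gravity of the implant solid (uniform density).

    The tray footprint is asymmetric, so its in-plane centroid is computed
    by quadrature over the boundary profile.
    """
    cx, cz = spec.axis_xz
    y1 = spec.plateau_y
    theta = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    r = spec.tray_radius_mm * _tray_profile(spec, theta)
    dth = theta[1] - theta[0]
    area = float((r ** 2).sum() / 2.0 * dth)
    x_bar = float((r ** 3 * np.cos(theta)).sum() / 3.0 * dth / area)
    z_bar = float((r ** 3 * np.sin(theta)).sum() / 3.0 * dth / area)
    v_tray = area * spec.tray_thickness_mm
    y_tray = y1 + spec.tray_thickness_mm / 2
    v_stem = np.pi * spec.stem_radius_mm ** 2 * spec.stem_length_mm
    y_stem = y1 - spec.stem_length_mm / 2
    fin_span = 0.7 * spec.stem_length_mm
    v_fins = spec.fin_count * spec.fin_length_mm * spec.fin_thickness_mm * fin_span
    y_fins = y1 - fin_span / 2
    v_peg = spec.peg_count * np.pi * spec.peg_radius_mm ** 2 * spec.peg_length_mm
    y_peg = y1 - spec.peg_length_mm / 2
    # peg x/z first moments (pegs are symmetric for even counts)
    px = sum(np.cos(a) for a in _peg_angles(spec)) * spec.peg_offset_mm
    pz = sum(np.sin(a) for a in _peg_angles(spec)) * spec.peg_offset_mm
    v_one_peg = np.pi * spec.peg_radius_mm ** 2 * spec.peg_length_mm
    v = v_tray + v_stem + v_fins + v_peg
    y_cog = (v_tray * y_tray + v_stem * y_stem + v_fins * y_fins + v_peg * y_peg) / v
    x_cog = cx + (v_tray * x_bar + v_one_peg * px) / v
    z_cog = cz + (v_tray * z_bar + v_one_peg * pz) / v
    return np.array([x_cog, y_cog, z_cog])


def analytic_migration(motion: RigidTransform, implant_points, cog,
                       laterality: str = "right") -> MigrationResult:
    """Migration parameters computed directly from a transform (no imaging).

    Independent oracle for the `migration` module: MTPM by exhaustive
    per-point displacement maximum, translations from the CoG displacement,
    Cardan angles by closed-form ``atan2``/``asin`` extraction.
    """
    pts = np.asarray(implant_points, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError("analytic migration requires a non-empty point set")
    cog = np.asarray(cog, dtype=float).reshape(3)
    R = motion.rotation.copy()
    b = motion.offset.copy()
    if laterality == "left":
        M = np.diag([-1.0, 1.0, 1.0])
        R = M @ R @ M
        b = M @ b
        pts = pts @ M
        cog = M @ cog

    disp = pts @ R.T + b - pts
    max_disp = float(np.sqrt((disp ** 2).sum(axis=1)).max())
    t = R @ cog + b - cog
    # R = Rz(rz) @ Ry(ry) @ Rx(rx)  =>  closed-form extraction
    ry = np.degrees(np.arcsin(np.clip(-R[2, 0], -1.0, 1.0)))
    rx = np.degrees(np.arctan2(R[2, 1], R[2, 2]))
    rz = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
    return MigrationResult(
        tx=float(t[0]), ty=float(t[1]), tz=float(t[2]),
        rx=float(rx), ry=float(ry), rz=float(rz),
        tt=float(np.linalg.norm(t)),
        tr=float(np.sqrt(rx * rx + ry * ry + rz * rz)),
        mtpm=max_disp, laterality=laterality, point_count=int(pts.shape[0]),
    )


def generate_pair(spec: PhantomSpec):
    """Generate (baseline, follow-up, ground truth) for a phantom spec.

    The follow-up geometry is ``repositioning ∘ (bone; implant_motion ∘
    implant)``: the implant micromotion is applied in the bone frame, then
    the whole limb is repositioned. Both volumes are voxelized analytically;
    noise is drawn independently per volume from ``spec.seed``.
    """
    surf = implant_surface_points(spec)
    _check_inside(spec, "implant", surf)
    _check_inside(spec, "implant", spec.repositioning.apply(spec.implant_motion.apply(surf)))

    identity = RigidTransform.identity()
    baseline_vox = _voxelize(spec, identity, identity)
    _apply_scatter(spec, baseline_vox, identity)
    _apply_psf(spec, baseline_vox)

    bone_map = spec.repositioning.inverse()
    impl_map = (spec.repositioning @ spec.implant_motion).inverse()
    followup_vox = _voxelize(spec, bone_map, impl_map)
    _apply_scatter(spec, followup_vox, impl_map)
    _apply_psf(spec, followup_vox)

    ss = np.random.SeedSequence(spec.seed)
    rng_b, rng_f, rng_m = (np.random.default_rng(s) for s in ss.spawn(3))
    if spec.remodeling_sd > 0:
        # smooth intensity perturbation of follow-up bone (remodeling proxy)
        fieldv = rng_m.standard_normal(followup_vox.shape)
        fieldv = ndimage.gaussian_filter(fieldv, sigma=2.0)
        fieldv *= spec.remodeling_sd / fieldv.std()
        in_bone = _occupancy_hu(
            spec,
            bone_map.apply(_voxel_centres(spec)), impl_map.apply(_voxel_centres(spec)),
        ).reshape(spec.volume_shape)
        bone_sel = (in_bone == spec.hu_trabecular) | (in_bone == spec.hu_cortical)
        followup_vox[bone_sel] += fieldv[bone_sel].astype(np.float32)
    if spec.noise_sd > 0:
        baseline_vox += rng_b.normal(0.0, spec.noise_sd, baseline_vox.shape).astype(np.float32)
        followup_vox += rng_f.normal(0.0, spec.noise_sd, followup_vox.shape).astype(np.float32)

    meta = {"slice_thickness": float(spec.spacing[1]),
            "pixel_spacing": float(spec.spacing[0])}
    baseline = CTVolume(baseline_vox, spec.spacing, meta=dict(meta))
    followup = CTVolume(followup_vox, spec.spacing, meta=dict(meta))
    reference = analytic_migration(spec.implant_motion, surf, implant_cog(spec))
    return baseline, followup, GroundTruthMotion(spec.implant_motion, reference)


def _voxel_centres(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.volume_shape).reshape(3, -1).T
    return idx * np.asarray(spec.spacing)
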