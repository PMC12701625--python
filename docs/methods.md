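# Methods

`ctmotion` measures micro-scale migration of a tibial knee implant relative
to the tibia between two CT scans, and provides the agreement statistics used
to validate such measurements against radiostereometric analysis (RSA). This
note documents the model, the defaults, the synthetic data, and the numerical
choices, so results can be interpreted and reproduced.

## Measurement model

Two CT volumes of the same knee, baseline and follow-up, are given in
Hounsfield units on (possibly different) regular grids. The patient moves
freely between scans, so each structure's apparent motion is

    implant_t = repositioning ∘ migration ,   bone_t = repositioning ,

where `repositioning` is the whole-limb rigid displacement between scans and
`migration` the implant's rigid motion in the bone frame — the quantity of
clinical interest. The pipeline estimates `bone_t` and `implant_t`
independently by masked intensity registration and cancels the repositioning
exactly:

    migration = bone_t⁻¹ ∘ implant_t .

The migration transform is decomposed in the anatomical RSA frame
(+x medial, +y proximal, +z anterior, right-knee convention) into:

* `Tx, Ty, Tz` — displacement of the implant centre of gravity (mm), the CoG
  being the unweighted centroid of the implant-mask voxel centres (intensity
  weighting is deliberately not used: metal HU values are scanner-saturated
  and carry no density information);
* `Rx, Ry, Rz` — Cardan angles (degrees) of the rotation part, fixed-axes
  sequence x→y→z (`R = Rz·Ry·Rx`). At sub-2° migration magnitudes the
  sequence effect is second order; the sequence tag is written into every
  serialised result;
* `TT = ‖(Tx,Ty,Tz)‖`, `TR = ‖(Rx,Ry,Rz)‖`;
* `MTPM` — maximum total point motion: the largest displacement
  `max_p ‖migration(p) − p‖` over the implant surface points (6-connectivity
  boundary voxel centres of the implant mask). For a rigid map the maximum is
  attained on the convex hull, so boundary points suffice.

Left knees are mirrored about the sagittal plane before decomposition
(exactly: the motion is conjugated with `diag(−1,1,1)`), which negates
`Tx, Ry, Rz` and leaves `Ty, Tz, Rx, TT, TR, MTPM` unchanged — the standard
convention for reporting all results "for a right-sided knee".

## Segmentation

Masks are built on the baseline scan only; they select which voxels drive
each registration and are never warped.

* implant: threshold at `threshold_implant` (default 2200 HU), keep the
  seeded/largest 26-connected component, fill holes;
* bone: threshold into `[threshold_bone, 1900)` HU (default lower bound
  430 HU; 1900 HU is below any metal), keep the seeded/largest component,
  fill the trabecular interior slice-wise perpendicular to the bone axis
  (robust even where scatter interrupts the cortical shell in 3-D), light
  erosion/dilation cleanup (defaults 1/1), remove all bone proximal to the
  baseplate plane and within `proximal_cut_mm` (default 5 mm) distal of it —
  the scatter-degraded region — and finally exclude the implant with a
  metal halo.

The metal halo is a deliberate addition: *every* voxel ≥ 1000 HU (no bone
tissue is brighter) plus a 3 mm margin is removed from the bone mask.
Thin implant features (fin edges) produce partial-volume voxels whose HU
falls inside the bone window; such voxels move with the implant, and leaving
them in the bone mask measurably biases the bone transform toward the
implant motion.

The baseplate plane is derived automatically as the distal face of the tray
slab: the contiguous run of cross-sections (perpendicular to the proximal
axis) whose voxel count is at least half the maximum.

Bone length — the extent of the final bone mask along the proximal axis —
is reported and a warning is emitted below 7 cm, the practical minimum for
reliable matching.

## Registration

Each structure is registered baseline→follow-up with SimpleITK:
normalised cross-correlation (invariant to affine HU drift, hence robust to
slow bone remodeling), evaluated over the structure's baseline mask only,
with a three-level multi-resolution schedule (shrink 4/2/1, Gaussian
smoothing 2/1/0 voxels), B-spline metric interpolation, a regular-step
gradient-descent optimiser (step 0.5 → 1e-4 in physical-shift-scaled
parameters, ≤ 600 iterations), rotation pivot at the mask centroid, and a
deterministic intensity-centroid initialisation (no random sampling, no
restarts: identical inputs always give identical transforms). Mattes mutual
information and linear interpolation are available as options.

Two measures keep the two structures' estimates independent:

* registration masks: the bone mask as built above; for the implant, the
  implant mask dilated by ≈1.6 mm so the high-gradient metal edge is inside
  the mask;
* HU clamping: the bone registration sees both volumes clamped to
  ≤ 1000 HU (metal flattened), the implant registration to ≥ 1000 HU (bone
  texture flattened). Without clamping, stationary bone texture inside the
  implant rim drags the implant transform toward zero motion, and vice
  versa.

B-spline metric interpolation halves the residual rotation bias relative to
linear interpolation at rotated poses; the internal similarity diagnostics
use the same interpolation family as the optimiser so that
`similarity_final ≥ similarity_initial` is meaningful. The public
`similarity()` function keeps its linear-interpolation contract.

Convergence is reported honestly: hitting the iteration budget flags the
result as non-converged, and the pipeline aborts unless forced.

## Digital phantom

No clinical scans are distributed, so every stage is validated on an
analytically defined tibia + baseplate phantom with exactly known motion.

Geometry (defaults in mm): a tapered bone shaft (radius 20→12 over 80 mm)
with a 3 mm cortical shell, closed by a distal cap and a proximal
subchondral plate; an oval cross-section (AP/ML ratio 0.8) with an anterior
crest ridge — tibiae are not rotationally symmetric, and without this
asymmetry axial bone rotation is genuinely unobservable; a metal baseplate
(oval footprint, aspect 0.85, with a posterior cutout), central stem with
four fins, and two peripheral fixation pegs — the asymmetric features real
baseplates have, and the ones that make axial implant rotation measurable.

Intensities: background −50, trabecular 300, cortical 600, metal 2500 HU,
consistent with clinically used thresholds (bone 220–770 HU, implant
1900–3100 HU). The trabecular interior carries a deterministic texture
field (sum of fixed 3–9 mm plane waves, 60 HU SD) rigidly attached to the
bone — the role trabecular structure plays in real registration. Artefacts:
a reconstruction PSF (Gaussian, σ 0.35 mm ≈ 1.0 lp/mm bone-kernel
resolution), independent Gaussian HU noise per scan (default 20 HU), a
zero-mean angular streak band multiplying the attenuation scale (HU+1000)
in the 5 mm directly distal to the baseplate (amplitude 150 HU at water,
rigidly attached to the implant) — the scatter that motivates the proximal
cut — and an optional smooth remodeling perturbation of follow-up bone.

Voxelization is by supersampled analytic evaluation — never by resampling
the baseline grid — so sub-voxel motion is encoded in partial-volume
fractions as in real CT. The follow-up geometry is
`repositioning ∘ (bone; migration ∘ implant)`. Supersampling is 5×5×5 per
voxel: at 3×3×3 the partial-volume staircase left deterministic registration
biases up to ~0.1 mm/0.1°, comparable to the tolerances being tested.
Full supersampling is applied only to cells that straddle a material
surface (detected exactly from the 8 cell-corner materials); uniform cells
take the centre value, with the trabecular texture attenuated analytically
by each plane wave's exact cell-average factor, so the two-pass result is
identical to dense supersampling at a fraction of the cost.

Grids: the default phantom uses 0.4 mm slices and 0.5 mm pixels (clinical
medians). `PhantomSpec.compact()` is a smaller, coarser variant
(0.5/0.8 mm) for fast tests; `PhantomSpec.desk()` uses the compact geometry
at the clinical-median grid and is the configuration used for accuracy
studies; their bone is shorter than the 7 cm guideline (a warning the
pipeline rightly emits). All spacings stay inside the clinically observed
ranges (slices 0.3–0.5 mm, pixels 0.3–0.8 mm).

What the phantom does not model: beam hardening and photon starvation
physics (the streak band is a stand-in, not a physical scatter simulation),
polyethylene/femoral components, cement, anatomical shape variation, and
patient motion artefacts. Passing phantom tests therefore demonstrates the
correctness and precision of the measurement chain under controlled,
realistic-intensity conditions, not clinical accuracy on arbitrary scans.

## Agreement statistics

For paired per-subject migration series (two software methods or two
observers):

* Bland–Altman: differences `d = a − b`, `sd` with the n−1 denominator,
  limits of agreement = mean ± 1.96·sd (multiplier exactly 1.96); 95% CI of
  the mean difference `t₀.₉₇₅,ₙ₋₁ · sd/√n` (t, not z — the only choice
  consistent with published CI half-widths when back-computed from printed
  LOA at n = 24); LOA CIs use the Bland–Altman `√(3/n)` standard-error
  approximation; Shapiro–Wilk (Royston approximation, via scipy) on the
  differences.
* ICC: two-way random-effects, absolute-agreement, single-measurement
  ICC(2,1) from the two-way ANOVA mean squares, F-based 95% CI (McGraw &
  Wong); ICC(3,1) available for sensitivity. Agreement (not consistency) is
  the right question for method validation; the model tag is written into
  the output. Zero between-subject variance is an explicit error.
* No multiple-testing adjustment across the nine parameters.

## Problem sizes and tolerances used in validation

* MTPM oracle: 1000 random rigid transforms (|t| ≤ 2 mm, |θ| ≤ 2°), point
  clouds up to 10⁴ points, agreement with the exhaustive per-point maximum
  to 1e-12 mm.
* Parameter recovery: desk phantoms (0.4 mm slices, 20 HU noise), a set of
  pure-translation, pure-rotation and mixed motions plus a zero-motion
  pair; ≥ 95% of recovered translation/rotation parameters within
  0.1 mm/0.1°, zero-motion MTPM < 0.05 mm.
* Interobserver rehearsal: the same pair analysed with bone/implant
  thresholds 430/2200 vs 360/2300 HU; MTPM difference < 0.05 mm.
* Repositioning invariance: a moderate whole-limb repositioning (≈1–1.5°,
  2–2.5 mm) added to the follow-up. Translations shift < 0.02 mm; MTPM
  shifts by ~0.02 mm and rotations by 0.03–0.17° — the level set by each
  run's own measurement noise, since the two runs see independent noise
  realisations. The cancellation of repositioning in
  `bone_t⁻¹ ∘ implant_t` itself is exact and is tested separately at the
  transform level.

## Known limitations

* Rotation about the bone/implant long axis is the least-constrained degree
  of freedom; its precision (~0.03–0.1° per registration at clinical voxel
  sizes and noise) dominates the error budget.
* Morphology uses voxel-unit structuring elements; strongly anisotropic
  grids make the effective element anisotropic in mm (matching common
  segmentation-tool behaviour, but worth knowing).
* The automatic baseplate-plane derivation assumes the tray is the widest
  axial slab of the implant; unusual hardware may need the plane overridden.
* Similarity diagnostics are descriptive; no statistical quality metric of
  registration confidence is computed.
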