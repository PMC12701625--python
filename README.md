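# ctmotion

CT-based radiostereometric analysis (CT-RSA): measuring micro-scale
migration of a joint implant relative to its host bone from two ordinary
clinical CT scans, by masked voxel-intensity rigid registration.

Early and continuous migration of a tibial knee replacement predicts later
aseptic loosening, so migration measurement is a standard endpoint in
implant research. The gold standard, radiostereometric analysis (RSA),
needs stereo radiographs, a calibration cage and implanted markers. CT-RSA
replaces all of that with two CT scans: segment the bone and the implant in
the baseline scan, register each structure independently to the follow-up
scan using the voxel intensities inside its mask, and take the implant's
motion *relative to the bone*,

    migration = bone_t⁻¹ ∘ implant_t ,

so the patient's repositioning between scans cancels. The migration is
reported in the RSA convention (+x medial, +y proximal, +z anterior, right
knee) as translations Tx, Ty, Tz (mm), Cardan rotations Rx, Ry, Rz
(degrees, fixed-axes x→y→z), their vector magnitudes TT and TR, and the
maximum total point motion

    MTPM = max_p ‖ migration(p) − p ‖

over the implant surface points — the main clinical outcome parameter.

The package is aimed at implant-migration researchers who want a fully
scripted, deterministic CT-RSA pipeline plus the statistics used to
validate one measurement route against another (Bland–Altman limits of
agreement with t-based confidence intervals, ICC(2,1) with F-based CI,
Shapiro–Wilk). Because clinical CT pairs cannot be distributed, the package
includes a digital tibia + tibial-baseplate phantom with exactly known
micromotion, so the whole chain is testable against ground truth; see
`docs/methods.md` for the model and its limitations.

## Worked example

Simulate a phantom pair with a known micromotion, run the full pipeline,
and compare with the ground truth:

```python
import numpy as np
from ctmotion import PhantomSpec, RigidTransform, generate_pair, run_pipeline

motion = RigidTransform.from_euler_deg(
    0.4, -0.6, 0.3, translation=[0.6, -0.4, 0.3], center=[20.9, 53.0, 20.9])
spec = PhantomSpec.desk(noise_sd=20.0, seed=42, implant_motion=motion)
baseline, followup, truth = generate_pair(spec)

out = run_pipeline(baseline, followup)
print("measured:", {k: round(v, 3) for k, v in out.result.to_dict().items()
                    if isinstance(v, float)})
print("truth   :", {k: round(v, 3) for k, v in truth.reference.to_dict().items()
                    if isinstance(v, float)})
```

prints (identical up to the phantom's noise level):

```
measured: {'MTPM': 0.879, 'TT': 0.811, 'TR': 0.733, 'Tx': 0.641, 'Ty': -0.43,
           'Tz': 0.247, 'Rx': 0.383, 'Ry': -0.537, 'Rz': 0.32}
truth   : {'MTPM': 0.875, 'TT': 0.793, 'TR': 0.781, 'Tx': 0.638, 'Ty': -0.399,
           'Tz': 0.25, 'Rx': 0.4, 'Ry': -0.6, 'Rz': 0.3}
```

The measured MTPM of 0.879 mm recovers the true 0.875 mm maximum surface
displacement to a few thousandths of a millimetre; translations and
rotations are recovered to ~0.03 mm / ~0.06°, i.e. an order of magnitude
below the voxel size (0.5 mm pixels, 0.4 mm slices) thanks to sub-voxel
intensity registration.

The same steps are available from the shell:

```bash
ctmotion simulate --preset desk --seed 42 --out pair/
ctmotion run --baseline pair/baseline.nii.gz --followup pair/followup.nii.gz --out result/
ctmotion agree --a obs1.csv --b obs2.csv --out report/   # Bland-Altman + ICC
```

`ctmotion run` writes the masks, both rigid transforms, the relative
motion, a `migration.csv` row and a manifest with every parameter that an
observer could have chosen — so two observers' runs can be diffed exactly.

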