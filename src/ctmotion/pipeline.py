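"""End-to-end migration analysis: segment → register → decompose.

The pipeline reproduces the full CT-based micromotion measurement on a
baseline/follow-up pair: build bone and implant masks on the baseline scan,
register each structure independently to the follow-up scan by masked
intensity registration, take the implant motion relative to the bone, and
decompose it into migration parameters about the implant's centre of
gravity. Execution is fully deterministic; every stage's diagnostics are
collected so two runs (e.g. two observers' parameter choices) can be
compared field by field.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import masks as M
from .io import StudyConfig, write_mask, write_transform
from .migration import ImplantModel, MigrationResult, decompose, relative_motion
from .registration import RegistrationOptions, RegistrationResult, register_rigid
from .volume import CTVolume, VoxelMask

__all__ = ["PipelineOutput", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineOutput:
    result: MigrationResult
    bone_registration: RegistrationResult
    implant_registration: RegistrationResult
    bone_mask: VoxelMask
    implant_mask: VoxelMask
    diagnostics: dict

    def result_frame(self, subject: str = "subject") -> pd.DataFrame:
        row = {"subject": subject}
        row.update(self.result.to_dict())
        return pd.DataFrame([row])


def run_pipeline(baseline: CTVolume, followup: CTVolume, cfg: StudyConfig = None,
                 params: M.SegmentationParams = None,
                 reg_opts: RegistrationOptions = None,
                 out_dir=None, force: bool = False) -> PipelineOutput:
    """Measure implant migration relative to bone for one scan pair.

    Raises on ineligible input (slice thickness) unless ``force``; a
    non-converged registration likewise aborts unless ``force``. When
    ``out_dir`` is given, all intermediates (masks, transforms, manifest)
    are written there.
    """
    from .io import check_eligibility  # local to avoid cycle at import time

    cfg = cfg or StudyConfig()
    params = params or M.SegmentationParams(**(cfg.segmentation or {}))
    reg_opts = reg_opts or RegistrationOptions(**(cfg.registration or {}))

    eligibility = check_eligibility(baseline, followup, cfg)
    if not eligibility["eligible"] and not force:
        raise ValueError(
            "stage eligibility: scan pair ineligible "
            f"(slice thicknesses {eligibility['slice_thickness_baseline_mm']}, "
            f"{eligibility['slice_thickness_followup_mm']} mm; "
            f"required < {eligibility['max_slice_thickness_mm']} mm)")

    log.info("segmenting implant (threshold %.0f HU)", params.threshold_implant)
    implant_mask = M.segment_implant(baseline, params)
    if implant_mask.voxel_count == 0:
        raise ValueError("stage segmentation: implant mask is empty")
    log.info("segmenting bone (threshold %.0f HU, cut %.1f mm)",
             params.threshold_bone, params.proximal_cut_mm)
    bone_mask = M.segment_bone(baseline, params, implant=implant_mask)
    bone_len = M.bone_length(bone_mask)
    log.info("mask volumes: bone %.1f cm3, implant %.1f cm3; bone length %.1f mm",
             bone_mask.volume_cm3, implant_mask.volume_cm3, bone_len)

    # implant registration mask: implant plus its high-gradient edge rim
    rim_vox = int(np.ceil(1.6 / float(np.min(baseline.spacing))))
    implant_reg_mask = M.morph(implant_mask, "dilate", rim_vox)

    # each structure is matched within its own HU range so the other,
    # independently moving structure cannot bias the transform
    bone_opts = replace(reg_opts, clamp_hu=(-2000.0, params.metal_exclusion_hu)) \
        if reg_opts.clamp_hu is None else reg_opts
    implant_opts = replace(reg_opts, clamp_hu=(params.metal_exclusion_hu, 10000.0)) \
        if reg_opts.clamp_hu is None else reg_opts

    log.info("registering bone")
    bone_reg = register_rigid(baseline, followup, bone_mask, bone_opts)
    log.info("registering implant")
    implant_reg = register_rigid(baseline, followup, implant_reg_mask, implant_opts)
    for name, reg in (("bone", bone_reg), ("implant", implant_reg)):
        log.info("%s registration: similarity %.4f -> %.4f, %d iterations, %s",
                 name, reg.similarity_initial, reg.similarity_final,
                 reg.iterations, reg.stop_condition)
        if not reg.converged and not force:
            raise RuntimeError(f"stage registration: {name} registration did not converge")

    motion = relative_motion(bone_reg.transform, implant_reg.transform)
    model = ImplantModel.from_mask(implant_mask)
    result = decompose(motion, model, laterality=cfg.laterality)

    diagnostics = {
        "eligibility": eligibility,
        "threshold_bone_hu": params.threshold_bone,
        "threshold_implant_hu": params.threshold_implant,
        "bone_volume_cm3": bone_mask.volume_cm3,
        "implant_volume_cm3": implant_mask.volume_cm3,
        "bone_length_mm": bone_len,
        "bone_similarity_final": bone_reg.similarity_final,
        "implant_similarity_final": implant_reg.similarity_final,
        "bone_iterations": bone_reg.iterations,
        "implant_iterations": implant_reg.iterations,
        "laterality": cfg.laterality,
    }

    out = PipelineOutput(result, bone_reg, implant_reg, bone_mask, implant_mask,
                         diagnostics)
    if out_dir is not None:
        _write_run(out, motion, params, out_dir)
    return out


def _write_run(out: PipelineOutput, motion, params, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_mask(out.bone_mask, os.path.join(out_dir, "bone_mask.nii.gz"))
    write_mask(out.implant_mask, os.path.join(out_dir, "implant_mask.nii.gz"))
    write_transform(out.bone_registration.transform,
                    os.path.join(out_dir, "bone_transform.json"))
    write_transform(out.implant_registration.transform,
                    os.path.join(out_dir, "implant_transform.json"))
    write_transform(motion, os.path.join(out_dir, "relative_motion.json"))
    out.result_frame().to_csv(os.path.join(out_dir, "migration.csv"), index=False)
    manifest = {
        "software": "ctmotion",
        "segmentation_params": {
            "threshold_bone": params.threshold_bone,
            "threshold_implant": params.threshold_implant,
            "bone_upper_hu": params.bone_upper_hu,
            "erosion_radius_vox": params.erosion_radius_vox,
            "dilation_radius_vox": params.dilation_radius_vox,
            "proximal_cut_mm": params.proximal_cut_mm,
        },
        "diagnostics": out.diagnostics,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
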