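"""End-to-end ablation-outcome pipeline.

Chains the stages of the workflow on one case: rigid + biomechanical
deformable registration of pre-treatment onto post-ablation imaging, tumor
contour propagation, 3D minimum-margin computation, and — when a follow-up
(recurrence) time point is available — vessel segmentation, vessel-focused
rigid registration and cone tracing of the recurrence against the
uncovered-margin region.  Inputs are either files on disk or a synthetic
phantom specification; all intermediate artifacts and a JSON report are
written to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .cone import ConeResult, build_direction_set, cone_overlap, mask_centroid
from .elastic import ElasticParams
from .grid import ImageVolume, LabelMask
from .margin import MarginParams, MarginResult, min_margin
from .meshing import MeshingParams
from .phantom import PhantomSpec, generate_phantom
from .registration import biomech_register, propagate_contour
from .transforms import RigidTransform
from .vesselness import (
    FocusedRegParams,
    InsufficientVasculatureError,
    VesselnessParams,
    focused_vessel_registration,
    segment_vessels,
)

log = logging.getLogger("ablamargin")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Exactly one of ``paths`` (files on disk) or ``phantom`` must be set.

    ``paths`` keys: pre_volume, pre_liver, pre_gtv, post_volume, post_liver,
    post_ablation; optional recur_volume, recur_liver, recur_ablation,
    recur_recurrence.  ``manual_rigid_post_to_recur`` supplies the fallback
    transform used when focused vessel registration reports insufficient
    vasculature.
    """

    paths: dict[str, str] | None = None
    phantom: PhantomSpec | None = None
    meshing: MeshingParams = field(default_factory=MeshingParams)
    elastic: ElasticParams = field(default_factory=ElasticParams)
    margin: MarginParams = field(default_factory=MarginParams)
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    focused: FocusedRegParams = field(default_factory=FocusedRegParams)
    cone_bin_deg: float = 2.0
    cone_dilation_deg: float = 0.0
    manual_rigid_post_to_recur: RigidTransform | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.paths is None) == (self.phantom is None):
            raise ValueError("set exactly one of paths= or phantom=")


@dataclass
class PipelineReport:
    margin: MarginResult
    rigid_pre_to_post: RigidTransform
    cone: ConeResult | None = None
    rigid_post_to_recur: RigidTransform | None = None
    used_manual_rigid: bool = False
    insufficient_vasculature: bool = False
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        out = {
            "min_margin_mm": round(self.margin.min_margin_mm, 2),
            "pct_gtv_outside": self.margin.pct_gtv_outside,
            "cc_gtv_outside": self.margin.cc_gtv_outside,
            "uncovered_region_cc": round(self.margin.uncovered_region.volume_cc, 2),
            "insufficient_vasculature": self.insufficient_vasculature,
            "used_manual_rigid": self.used_manual_rigid,
            "stage_seconds": {k: round(v, 2) for k, v in self.stage_seconds.items()},
        }
        if self.cone is not None:
            out["cone_overlap"] = self.cone.overlap
            out["cone_overlap_cc"] = round(self.cone.overlap_volume_cc, 3)
        return out


def _load_case(config: PipelineConfig) -> dict:
    if config.phantom is not None:
        case = generate_phantom(config.phantom)
        d = {
            "pre_volume": case.pre_volume,
            "pre_liver": case.pre_masks["liver"],
            "pre_gtv": case.pre_masks["gtv"],
            "post_volume": case.post_volume,
            "post_liver": case.post_masks["liver"],
            "post_ablation": case.post_masks["ablation"],
            "recur_volume": case.recur_volume,
            "recur_liver": case.recur_masks["liver"],
            "recur_ablation": case.recur_masks["ablation_shrunk"],
            "recur_recurrence": case.recur_masks["recurrence"],
        }
        return d
    out: dict = {}
    for key, path in config.paths.items():
        reader = _io.read_volume if key.endswith("volume") else _io.read_mask
        out[key] = reader(path)
    for frame in ("pre", "post", "recur"):
        vol = out.get(f"{frame}_volume")
        if vol is None:
            continue
        for key, item in out.items():
            if key.startswith(frame) and isinstance(item, LabelMask):
                _io.check_paired_geometry(vol, item)
    return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run registration, margin assessment and (optionally) cone tracing."""
    timings: dict[str, float] = {}

    def timed(name: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0
                log.info("stage %-22s %6.2f s", name, timings[name])
                return False

        return _T()

    log.info("pipeline start (seed %d)", config.seed)
    with timed("load inputs"):
        case = _load_case(config)

    with timed("biomechanical registration"):
        rigid, dvf = biomech_register(
            case["pre_volume"], case["pre_liver"],
            case["post_volume"], case["post_liver"],
            meshing=config.meshing, elastic=config.elastic,
        )

    with timed("GTV propagation"):
        gtv_mapped = propagate_contour(
            case["pre_gtv"], dvf, direction="forward",
            target_grid=case["post_liver"].grid,
        )

    with timed("margin computation"):
        margin_result = min_margin(
            gtv_mapped, case["post_ablation"], case["post_liver"], config.margin
        )

    report = PipelineReport(
        margin=margin_result, rigid_pre_to_post=rigid, stage_seconds=timings
    )

    has_recur = "recur_volume" in case and "recur_ablation" in case
    if has_recur and "recur_recurrence" in case:
        with timed("vessel segmentation"):
            post_vessels = segment_vessels(
                case["post_volume"], case["post_liver"], config.vesselness
            )
            recur_vessels = segment_vessels(
                case["recur_volume"], case["recur_liver"], config.vesselness
            )
        with timed("focused rigid registration"):
            try:
                t_p2r = focused_vessel_registration(
                    post_vessels, recur_vessels,
                    case["post_ablation"], case["recur_ablation"],
                    config.focused,
                )
            except InsufficientVasculatureError as exc:
                report.insufficient_vasculature = True
                log.warning("%s", exc)
                if config.manual_rigid_post_to_recur is None:
                    t_p2r = None
                else:
                    t_p2r = config.manual_rigid_post_to_recur
                    report.used_manual_rigid = True
        if t_p2r is not None:
            with timed("cone tracing"):
                recur_centroid = mask_centroid(case["recur_ablation"])
                directions = build_direction_set(
                    recur_centroid, case["recur_recurrence"],
                    bin_deg=config.cone_bin_deg,
                    dilation_deg=config.cone_dilation_deg,
                )
                post_centroid = mask_centroid(case["post_ablation"])
                report.cone = cone_overlap(
                    directions, post_centroid,
                    margin_result.uncovered_region, t_p2r,
                )
            report.rigid_post_to_recur = t_p2r

    if config.out_dir is not None:
        _write_artifacts(config, case, dvf, gtv_mapped, report)
    return report


def _write_artifacts(config, case, dvf, gtv_mapped, report: PipelineReport) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_dvf(out / "dvf_pre_to_post.nii.gz", dvf)
    _io.write_volume(out / "gtv_mapped.nii.gz", gtv_mapped)
    _io.write_volume(out / "uncovered_region.nii.gz", report.margin.uncovered_region)
    _io.write_volume(out / "adjusted_ablation.nii.gz", report.margin.adjusted_ablation)
    report.rigid_pre_to_post.save(out / "rigid_pre_to_post.json")
    if report.rigid_post_to_recur is not None:
        report.rigid_post_to_recur.save(out / "rigid_post_to_recur.json")
    if report.cone is not None:
        _io.write_volume(out / "cone_overlap.nii.gz", report.cone.overlap_mask)
    resolved = {
        "seed": config.seed,
        "meshing": dataclasses.asdict(config.meshing),
        "elastic": dataclasses.asdict(config.elastic),
        "margin": dataclasses.asdict(config.margin),
        "vesselness": dataclasses.asdict(config.vesselness),
        "focused": dataclasses.asdict(config.focused),
        "cone_bin_deg": config.cone_bin_deg,
        "cone_dilation_deg": config.cone_dilation_deg,
        "phantom": config.phantom is not None,
        "paths": config.paths,
    }
    (out / "config_resolved.json").write_text(json.dumps(resolved, indent=2, default=list))
    (out / "report.json").write_text(json.dumps(report.summary(), indent=2))
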