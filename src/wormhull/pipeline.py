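"""End-to-end orchestration: stack in, mesh + IoU report + metrics out.

``run_pipeline`` executes enhance -> segment -> estimate_period ->
align -> assign_angles -> carve -> mesh -> validate -> phenotype on an
in-memory stack and returns every intermediate product; ``run_config``
is the file-based wrapper the CLI uses.  Given the same inputs and seed
the run is bit-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import hull, imaging, kinematics
from . import validate as val
from .phenotype import MorphometricRecord, append_csv
from .phenotype import phenotype as _compute_phenotype
from .imaging import ImageStack, SilhouetteStack

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_config", "simulate_stack"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnhanceConfig(_Block):
    upsample_factor: int = 2
    denoise_weight: float = 0.08
    unsharp_amount: float = 0.5


class SegmentConfig(_Block):
    dark_specimen: bool = True
    closing_radius: int = 2
    min_area_px: int = 64
    c_min: float = 0.3


class PeriodConfig(_Block):
    min_lag: int = 8
    max_lag: int | None = None
    s_min: float = 0.6
    use_roi: bool = True


class CarveConfig(_Block):
    feature_completion: bool = True
    n_min: int = 12
    reference_frame: int = 0


class MeshConfig(_Block):
    smooth_iters: int = 10
    gaussian_sigma: float | None = None  # default: one mask pixel


class ValidateConfig(_Block):
    viewpoints_deg: list[float] = list(val.DEFAULT_VIEWPOINTS_DEG)


class PhenotypeConfig(_Block):
    enabled: bool = True
    end_exclusion: float = 0.05


class RunConfig(_Block):
    """Full pipeline configuration; unknown keys are rejected."""

    input_path: str | None = None
    pixel_size_um: float | None = None
    frame_interval_s: float = 1.0
    output_dir: str | None = None
    sample_id: str = "specimen"
    strain: str = "N2"
    stage: Literal["adult", "embryo"] = "adult"
    seed: int = 0
    log_level: str = "INFO"
    enhance: EnhanceConfig = EnhanceConfig()
    segment: SegmentConfig = SegmentConfig()
    period: PeriodConfig = PeriodConfig()
    carve: CarveConfig = CarveConfig()
    mesh: MeshConfig = MeshConfig()
    validation: ValidateConfig = ValidateConfig()
    phenotype: PhenotypeConfig = PhenotypeConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class PipelineResult:
    enhanced: ImageStack
    silhouettes: SilhouetteStack  # full aligned stack
    window: SilhouetteStack  # one period, angle-stamped
    estimate: kinematics.RotationEstimate
    volume: hull.VoxelVolume
    mesh: hull.SurfaceMesh | None
    iou_report: val.IoUReport
    record: MorphometricRecord | None
    timings_s: dict[str, float] = field(default_factory=dict)

    def report_dict(self) -> dict:
        return {
            "period_frames": self.estimate.period_frames,
            "peak_score": self.estimate.peak_score,
            "n_window_frames": len(self.window),
            "mean_iou": self.iou_report.mean,
            "sd_iou": self.iou_report.sd,
            "iou_per_viewpoint": dict(zip(
                self.iou_report.viewpoints_deg, self.iou_report.ious)),
            "metrics": self.record.as_dict() if self.record else None,
            "timings_s": self.timings_s,
        }


def _mask_roi(sils: SilhouetteStack, pad: int = 4) -> tuple[int, int, int, int]:
    m = sils.masks[sils.ok].any(axis=0)
    r, c = np.nonzero(m)
    rows, cols = m.shape
    return (
        max(int(r.min()) - pad, 0), min(int(r.max()) + pad + 1, rows),
        max(int(c.min()) - pad, 0), min(int(c.max()) + pad + 1, cols),
    )


def run_pipeline(stack: ImageStack, config: RunConfig | None = None) -> PipelineResult:
    """Run the full reconstruction on an in-memory stack."""
    cfg = config or RunConfig()
    timings: dict[str, float] = {}

    def tic(name):
        timings[name] = time.perf_counter()

    def toc(name):
        timings[name] = time.perf_counter() - timings[name]

    tic("enhance")
    enhanced = imaging.enhance(
        stack,
        upsample_factor=cfg.enhance.upsample_factor,
        denoise_weight=cfg.enhance.denoise_weight,
        unsharp_amount=cfg.enhance.unsharp_amount,
    )
    toc("enhance")

    tic("segment")
    sils = imaging.segment(
        enhanced,
        dark_specimen=cfg.segment.dark_specimen,
        closing_radius=cfg.segment.closing_radius,
        min_area_px=cfg.segment.min_area_px,
        c_min=cfg.segment.c_min,
    )
    toc("segment")

    tic("period")
    roi = _mask_roi(sils) if cfg.period.use_roi else None
    est = kinematics.estimate_period(
        enhanced,
        min_lag=cfg.period.min_lag,
        max_lag=cfg.period.max_lag,
        roi=roi,
        s_min=cfg.period.s_min,
    )
    toc("period")

    tic("align")
    aligned = kinematics.align_frames(sils, period_frames=est.period_frames)
    window = kinematics.assign_angles(
        est, aligned, reference_frame=cfg.carve.reference_frame, n_min=cfg.carve.n_min)
    toc("align")

    tic("carve")
    volume = hull.carve_slicewise(
        window, feature_completion=cfg.carve.feature_completion)
    toc("carve")

    tic("mesh")
    mesh = hull.extract_mesh(
        volume, smooth_iters=cfg.mesh.smooth_iters,
        gaussian_sigma=cfg.mesh.gaussian_sigma)
    toc("mesh")

    tic("validate")
    report = val.validate_reconstruction(
        volume, window, viewpoints_deg=tuple(cfg.validation.viewpoints_deg))
    toc("validate")

    record = None
    if cfg.phenotype.enabled:
        tic("phenotype")
        record = _compute_phenotype(
            volume, mesh,
            sample_id=cfg.sample_id, strain=cfg.strain, stage=cfg.stage,
            mean_iou=report.mean,
        )
        toc("phenotype")

    return PipelineResult(
        enhanced=enhanced, silhouettes=aligned, window=window, estimate=est,
        volume=volume, mesh=mesh, iou_report=report, record=record,
        timings_s=timings,
    )


def run_config(cfg: RunConfig) -> PipelineResult:
    """File-based entry point: read the stack, run, write artifacts."""
    if cfg.input_path is None or cfg.pixel_size_um is None:
        raise ValueError("config must provide input_path and pixel_size_um "
                         "(calibration) before any compute")
    stack = imaging.read_stack(cfg.input_path, cfg.pixel_size_um, cfg.frame_interval_s)
    result = run_pipeline(stack, cfg)
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if result.mesh is not None:
            result.mesh.save(out / "mesh.ply")
            result.mesh.save(out / "mesh.stl")
        result.window.write_tiff(out / "masks.tif")
        result.iou_report.save_json(out / "iou.json")
        result.iou_report.save_csv(out / "iou.csv")
        result.estimate.save_csv(out / "similarity.csv")
        if result.record is not None:
            append_csv(result.record, out / "metrics.csv")
        (out / "report.json").write_text(json.dumps(result.report_dict(), indent=2))
    return result


def simulate_stack(phantom_yaml: str | Path, render_yaml: str | Path,
                   out_tiff: str | Path, truth_json: str | Path | None = None):
    """Render a phantom recording from YAML specs (the CLI's `simulate`)."""
    from . import phantom as ph

    spec = ph.PhantomSpec.from_yaml(phantom_yaml)
    rspec = ph.RenderSpec.from_yaml(render_yaml)
    voxel = rspec.pixel_size_um
    built = ph.build_phantom(spec, voxel_um=min(voxel, spec.reference_radius_um / 4))
    res = ph.render_stack(built, rspec)
    res.stack.write_tiff(out_tiff)
    if truth_json is not None:
        gt = built.ground_truth
        gt.angles_rad = res.angles_rad
        gt.drift_px = res.drift_px
        gt.save_json(truth_json)
    return res
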