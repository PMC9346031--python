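"""End-to-end orchestration: image + fiducials -> lumen, mesh, fly-through.

Stage order follows the segmentation scheme: vesselness enhancement at
the original resolution, minimal-path centerline through the fiducials,
ROI crop + super-resolution around the centerline, seed map, geodesic
label propagation, lumen mask (super-resolved and majority-downsampled),
surface + curvature, camera path. Every stage is deterministic, so two
runs with the same config produce bitwise-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .centerline import CenterlineCurve, PathGraphParams, extract_centerline
from .core import FiducialSet, ScalarVolume
from .evaluate import EvalReport, centerline_distance, dice_coefficient
from .lumen import SeedConfig, SeedLabelMap, build_seed_map, lumen_mask, propagate_labels
from .superres import SuperResConfig, crop_and_upsample
from .surface import CameraPath, camera_path, extract_surface, gaussian_curvature_map
from .vesselness import VesselnessParams, compute_vesselness

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved parameters of every stage (all defaults are usable as-is)."""

    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    path_graph: PathGraphParams = field(default_factory=PathGraphParams)
    superres: SuperResConfig = field(default_factory=SuperResConfig)
    seeds: SeedConfig = field(default_factory=SeedConfig)
    surface_smooth_subvoxels: float = 1.0
    camera_step_mm: float = 1.0
    largest_component: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        for fld, typ in (
            ("vesselness", VesselnessParams),
            ("path_graph", PathGraphParams),
            ("superres", SuperResConfig),
            ("seeds", SeedConfig),
        ):
            if fld in data:
                sub = dict(data[fld])
                if "scales_mm" in sub:
                    sub["scales_mm"] = tuple(sub["scales_mm"])
                kwargs[fld] = typ(**sub)
        for fld in ("surface_smooth_subvoxels", "camera_step_mm", "largest_component"):
            if fld in data:
                kwargs[fld] = data[fld]
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything a run produces."""

    lumen_highres: ScalarVolume
    lumen_original: ScalarVolume
    centerline: CenterlineCurve
    vesselness: ScalarVolume
    labels: SeedLabelMap
    mesh: trimesh.Trimesh
    camera: CameraPath
    report: EvalReport


def run_pipeline(
    image: ScalarVolume,
    fiducials: FiducialSet,
    config: PipelineConfig | None = None,
    truth_mask: ScalarVolume | None = None,
    truth_centerline: CenterlineCurve | None = None,
) -> PipelineResult:
    """Run the full segmentation + visualization-geometry pipeline.

    When ``truth_mask`` / ``truth_centerline`` are supplied (e.g. from
    the phantom generator) the report carries Dice (on the original
    grid, against the majority-downsampled mask) and symmetric
    centerline distances. Any stage failure is re-raised with the stage
    name and resolved parameters attached.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    stage = "vesselness"
    try:
        t0 = time.perf_counter()
        vess = compute_vesselness(image, config.vesselness)
        timings[stage] = time.perf_counter() - t0
        logger.info("vesselness done in %.2fs", timings[stage])

        stage = "centerline"
        t0 = time.perf_counter()
        cl = extract_centerline(vess, fiducials, config.path_graph)
        timings[stage] = time.perf_counter() - t0
        logger.info("centerline: %d vertices, cost %.4f (%.2fs)", len(cl), cl.cost, timings[stage])

        stage = "superres"
        t0 = time.perf_counter()
        roi = crop_and_upsample(image, cl, config.superres)
        timings[stage] = time.perf_counter() - t0
        logger.info("ROI %s at factor %d (%.2fs)", roi.volume.shape, roi.factor, timings[stage])

        stage = "seeds"
        t0 = time.perf_counter()
        seeds = build_seed_map(roi, cl, config.seeds)
        timings[stage] = time.perf_counter() - t0

        stage = "propagate"
        t0 = time.perf_counter()
        labels = propagate_labels(roi, seeds)
        timings[stage] = time.perf_counter() - t0
        logger.info("propagation done (%.2fs); counts %s", timings[stage], labels.counts)

        stage = "mask"
        t0 = time.perf_counter()
        hi, lo = lumen_mask(
            labels, roi, largest_component=config.largest_component, downsample=True
        )
        # re-embed the cropped original-resolution mask into the full grid
        full = np.zeros(image.shape, dtype=np.uint8)
        o = roi.index_offset
        s = lo.values.shape
        full[o[0] : o[0] + s[0], o[1] : o[1] + s[1], o[2] : o[2] + s[2]] = lo.values
        lo = ScalarVolume(full, image.spacing.copy(), image.origin.copy(), image.direction.copy())
        timings[stage] = time.perf_counter() - t0

        stage = "surface"
        t0 = time.perf_counter()
        sigma_mm = config.surface_smooth_subvoxels * float(min(hi.spacing))
        mesh = extract_surface(hi, smooth_sigma_mm=sigma_mm)
        mesh = gaussian_curvature_map(mesh)
        cam = camera_path(cl, config.camera_step_mm)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage '{stage}' failed with parameters {config.to_dict()}: {exc}"
        ) from exc

    report = EvalReport(runtime_s=timings, parameters=config.to_dict())
    if truth_mask is not None:
        report.dice = dice_coefficient(lo, truth_mask)
    if truth_centerline is not None:
        mean_d, max_d = centerline_distance(cl, truth_centerline)
        report.mean_centerline_distance_mm = mean_d
        report.hausdorff_mm = max_d
    return PipelineResult(
        lumen_highres=hi,
        lumen_original=lo,
        centerline=cl,
        vesselness=vess,
        labels=labels,
        mesh=mesh,
        camera=cam,
        report=report,
    )
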