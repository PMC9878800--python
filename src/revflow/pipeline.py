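"""End-to-end reverse-flow mapping pipeline.

Chains preprocessing, geometry and the core computation on a
:class:`~revflow.io.FlowDataset`:

1. venc unwrapping, static-tissue detection, eddy-current correction,
   noise masking;
2. 1 mm isotropic resampling of velocity (trilinear) and mask (nearest);
3. centerline extraction between the two seeds, orthogonal planes every
   1 mm, branch exclusion, nearest-plane voxel assignment, segment
   labelling from the four landmark planes;
4. projection onto plane normals, end-systole detection from the
   whole-aorta mean net-flow curve, 600 ms truncation, per-voxel
   forward/reverse integration, per-segment statistics and sagittal MIPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import core, geometry, preprocess, reporting
from .geometry import AAO, Centerline, LandmarkSet, PlaneSet
from .io import FlowDataset, VelocityField4D


@dataclass
class PipelineConfig:
    """Everything the semi-automated pipeline needs beyond the images:
    centerline endpoint seeds (voxel indices on the acquisition grid),
    landmark plane arc-length positions (mm), and the preprocessing /
    timing parameters."""

    seed_valve: tuple[int, int, int]
    seed_distal: tuple[int, int, int]
    landmarks: LandmarkSet
    eddy_order: int = 1
    mag_quantile: float = 0.6
    noise_quantile: float = 0.1
    std_threshold_mms: float = 20.0
    window_ms: float = 600.0
    smooth_sigma_mm: float = 2.0
    target_spacing_mm: float = 1.0
    exclusion_boxes: list = field(default_factory=list)
    es_from_aao: bool = False  # end systole from the AAo-only curve (comparison flag)
    skip_preprocess: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = {
            "seed_valve": list(self.seed_valve),
            "seed_distal": list(self.seed_distal),
            "landmarks_mm": list(self.landmarks.as_tuple()),
            "eddy_order": self.eddy_order,
            "mag_quantile": self.mag_quantile,
            "noise_quantile": self.noise_quantile,
            "std_threshold_mms": self.std_threshold_mms,
            "window_ms": self.window_ms,
            "smooth_sigma_mm": self.smooth_sigma_mm,
            "target_spacing_mm": self.target_spacing_mm,
            "exclusion_boxes": [list(b) for b in self.exclusion_boxes],
            "es_from_aao": self.es_from_aao,
            "skip_preprocess": self.skip_preprocess,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        lm = d["landmarks_mm"]
        return cls(
            seed_valve=tuple(d["seed_valve"]),
            seed_distal=tuple(d["seed_distal"]),
            landmarks=LandmarkSet(*lm),
            **{
                k: d[k]
                for k in (
                    "eddy_order",
                    "mag_quantile",
                    "noise_quantile",
                    "std_threshold_mms",
                    "window_ms",
                    "smooth_sigma_mm",
                    "target_spacing_mm",
                    "es_from_aao",
                    "skip_preprocess",
                )
                if k in d
            },
            exclusion_boxes=[tuple(b) for b in d.get("exclusion_boxes", [])],
        )


@dataclass
class RunResult:
    """Everything a pipeline run produces."""

    stats: Any  # per-segment DataFrame
    maps: core.ReverseFlowMap
    labels: np.ndarray
    assignment: np.ndarray
    centerline: Centerline
    planes: PlaneSet
    mask: np.ndarray  # analysis-grid mask after exclusions
    window: core.CardiacWindow
    net_flow: np.ndarray
    mips: dict
    info: dict


def _scale_seed(seed, spacing, target):
    return tuple(int(round(i * s / target)) for i, s in zip(seed, spacing))


def run_pipeline(dataset: FlowDataset, config: PipelineConfig) -> RunResult:
    """Run the full analysis on one dataset; see the module docstring."""
    velocity = dataset.velocity
    info: dict[str, Any] = {}

    if config.skip_preprocess:
        corrected = velocity
        noise = np.zeros(velocity.grid_shape, dtype=bool)
    else:
        corrected, pinfo = preprocess.preprocess_field(
            velocity,
            dataset.magnitude,
            eddy_order=config.eddy_order,
            mag_quantile=config.mag_quantile,
            std_threshold_mms=config.std_threshold_mms,
            noise_quantile=config.noise_quantile,
        )
        noise = pinfo["noise_mask"]
        info["eddy_fit"] = pinfo["eddy_fit"]
        info["n_static"] = int(pinfo["static_mask"].sum())

    # isotropic analysis grid
    target = config.target_spacing_mm
    vals, _ = geometry.resample_isotropic(
        corrected.values, corrected.spacing_mm, target, order=1
    )
    mask_iso, _ = geometry.resample_isotropic(
        dataset.mask.astype(np.uint8), corrected.spacing_mm, target, order=0
    )
    mask_iso = mask_iso > 0
    noise_iso, _ = geometry.resample_isotropic(
        noise.astype(np.uint8), corrected.spacing_mm, target, order=0
    )
    mask_iso &= ~(noise_iso > 0)
    field_iso = VelocityField4D(vals, (target,) * 3, corrected.dt_ms, corrected.venc_cms)

    if config.exclusion_boxes:
        roi = geometry.boxes_to_roi(config.exclusion_boxes, mask_iso.shape)
        mask_iso = geometry.exclude_branches(mask_iso, roi)

    seed_valve = _scale_seed(config.seed_valve, velocity.spacing_mm, target)
    seed_distal = _scale_seed(config.seed_distal, velocity.spacing_mm, target)
    centerline = geometry.extract_centerline(
        mask_iso,
        field_iso.spacing_mm,
        seed_valve,
        seed_distal,
        smooth_sigma_mm=config.smooth_sigma_mm,
    )
    planes = geometry.build_planes(centerline)
    assignment = geometry.assign_voxels(mask_iso, centerline, field_iso.spacing_mm)
    labels = geometry.label_segments(assignment, centerline, config.landmarks)

    s = core.project_velocities(field_iso.values, assignment, planes)
    es_mask = (labels == AAO) if config.es_from_aao else mask_iso
    n_inc = core.truncate_window(field_iso.n_frames, field_iso.dt_ms, config.window_ms)
    q = core.net_flow_curve(s, es_mask)
    k_es = core.detect_end_systole(q[:n_inc])
    window = core.CardiacWindow(n_inc=n_inc, k_es=k_es, dt_ms=field_iso.dt_ms)
    maps = core.integrate_flow(s, window)
    stats = core.segment_statistics(maps, labels)

    included = labels > 0
    mips = {
        f"{wname}_{direction}": reporting.mip_sagittal(maps[(wname, direction)], included)
        for (wname, direction) in maps.maps
    }
    return RunResult(
        stats=stats,
        maps=maps,
        labels=labels,
        assignment=assignment,
        centerline=centerline,
        planes=planes,
        mask=mask_iso,
        window=window,
        net_flow=q,
        mips=mips,
        info=info,
    )


def segment_window_mean(result: RunResult, segment: str, window: str, direction: str = "reverse"):
    """Convenience accessor: mean mL per voxel for one segment/window."""
    df = result.stats
    row = df[
        (df.segment == segment) & (df.window == window) & (df.direction == direction)
    ]
    return float(row["mean_mL"].iloc[0])
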