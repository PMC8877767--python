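"""End-to-end measurement pipeline: align -> repair -> zoom-in -> measure.

The colour image drives detection (optionally through the zoom-in loop);
the depth map is aligned to the colour frame, spatially filtered and
hole-filled once, and then queried at the *reverted* centre-keypoint
coordinates — the depth map itself is never zoomed, so size estimates are
invariant to the chosen magnification for an exact detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .depth import (
    DepthMap,
    PinholeProjection,
    RigidTransform,
    align_depth_to_color,
    hole_fill,
    query_depth,
    spatial_filter,
)
from .geometry import CameraIntrinsics, SizeEstimate, measure
from .zoomin import Detector, ZoomResult, zoomin_search

__all__ = ["MeasuredObject", "PipelineResult", "measure_image"]


@dataclass
class MeasuredObject:
    """A detection together with its metric size estimate."""

    class_label: str
    score: float
    estimate: SizeEstimate
    detection: object

    def as_dict(self) -> dict:
        e = self.estimate
        return {
            "class": self.class_label,
            "score": round(self.score, 4),
            "diameter_mm": round(e.diameter_mm, 2),
            "length_mm": round(e.length_mm, 2),
            "depth_mm": round(e.depth_used_mm, 1),
            "depth_from_fallback": e.depth_from_fallback,
        }


@dataclass
class PipelineResult:
    objects: list[MeasuredObject]
    zoom: ZoomResult


def _center_depth(depth: DepthMap, det) -> tuple[float, bool]:
    """Depth at the Center keypoint; if invalid after repair, fall back to
    the median of valid depths inside the detection box (flagged)."""
    d = query_depth(depth, det.keypoints.center)
    if d > 0:
        return d, False
    x0, y0, x1, y1 = det.box
    H, W = depth.shape
    sl = depth.data[
        max(int(y0), 0) : min(int(np.ceil(y1)) + 1, H),
        max(int(x0), 0) : min(int(np.ceil(x1)) + 1, W),
    ]
    valid = sl[sl > 0]
    if valid.size == 0:
        return 0.0, True
    return float(np.median(valid)), True


def measure_image(
    color: np.ndarray,
    depth: DepthMap,
    cam: CameraIntrinsics,
    detector: Detector,
    alpha: float = 1.2,
    cap: float = 5.0,
    filter_alpha: float = 0.5,
    filter_delta_mm: float = 20.0,
    filter_iterations: int = 2,
    depth_proj: PinholeProjection | None = None,
    depth_to_color: RigidTransform | None = None,
) -> PipelineResult:
    """Measure every vegetable in an RGB-D frame.

    When ``depth_proj``/``depth_to_color`` are given the depth map is first
    rewarped into the colour frame; it is then repaired (edge-preserving
    smoothing + directional hole fill) and queried at each detection's
    centre keypoint.  Objects whose centre depth cannot be recovered at all
    are skipped.
    """
    if depth_proj is not None and depth_to_color is not None:
        color_proj = PinholeProjection.from_intrinsics(cam)
        depth = align_depth_to_color(
            depth, depth_proj, color_proj, depth_to_color,
            color_shape=(cam.height_px, cam.width_px),
        )
    repaired = hole_fill(
        spatial_filter(depth, alpha=filter_alpha, delta=filter_delta_mm,
                       iterations=filter_iterations)
    )
    zoom = zoomin_search(np.asarray(color), detector, alpha=alpha, cap=cap)
    objects = []
    for det in zoom.detections:
        d, fallback = _center_depth(repaired, det)
        if d <= 0:
            continue
        est = measure(det.keypoints, d, cam, depth_from_fallback=fallback)
        objects.append(
            MeasuredObject(
                class_label=det.class_label,
                score=det.score,
                estimate=est,
                detection=det,
            )
        )
    return PipelineResult(objects=objects, zoom=zoom)
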