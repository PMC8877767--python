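"""Multi-scale "zoom-in" detection loop.

Keypoint detectors lose small, distant objects when most of the frame is
background.  The zoom-in strategy magnifies the central field of view by a
growing factor M (bilinear interpolation, central crop back to the original
frame size), re-runs the detector at each M, keeps the magnification whose
detections have the highest *total* score, and maps the winning boxes and
keypoints back to original-image coordinates.

Depth maps are never zoomed: depth is queried on the original map at the
reverted coordinates, so metric measurements are invariant to the chosen
magnification for an exact detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .errors import DetectorError, InvalidInputError, InvalidMagnificationError
from .geometry import KeypointSet, PixelPoint

__all__ = [
    "Detection",
    "ZoomResult",
    "CLASS_LABELS",
    "SCORE_THRESHOLD",
    "zoom",
    "revert_points",
    "revert_detection",
    "zoomin_search",
]

#: The four vegetable classes the detector contract recognises.
CLASS_LABELS = ("cucumber", "eggplant", "tomato", "pepper")

#: Detections below this classification score are discarded by contract.
SCORE_THRESHOLD = 0.6

#: A detector: takes an H x W x 3 image, returns detections already filtered
#: at SCORE_THRESHOLD, deterministically for a fixed image (and seed).
Detector = Callable[[np.ndarray], "list[Detection]"]


@dataclass
class Detection:
    """One detected vegetable: class, score, box and six keypoints."""

    class_label: str
    score: float
    box: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    keypoints: KeypointSet

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise InvalidInputError(f"unknown class {self.class_label!r}")
        if not 0.0 <= self.score <= 1.0:
            raise InvalidInputError(f"score must be in [0, 1], got {self.score!r}")
        x0, y0, x1, y1 = self.box
        if x0 > x1 or y0 > y1:
            raise InvalidInputError(f"malformed box {self.box!r}")

    @property
    def box_area(self) -> float:
        x0, y0, x1, y1 = self.box
        return (x1 - x0) * (y1 - y0)


@dataclass
class ZoomResult:
    """Outcome of a zoom-in search, in original-image coordinates."""

    detections: list[Detection]
    best_magnification: float
    best_total_score: float
    trace: list[tuple[float, float]] = field(default_factory=list)  # (M, total score)


def _image_center(shape) -> tuple[float, float]:
    H, W = shape[:2]
    return ((W - 1) / 2.0, (H - 1) / 2.0)


def zoom(image: np.ndarray, M: float) -> np.ndarray:
    """Magnify the central field of view by M, keeping the frame size.

    Output pixel (x, y) samples the input bilinearly at
    ``center + (p - center) / M``; M = 1 is the identity.
    """
    if not M >= 1:
        raise InvalidMagnificationError(f"magnification must be >= 1, got {M!r}")
    image = np.asarray(image)
    if M == 1:
        return image.copy()
    H, W = image.shape[:2]
    cx, cy = _image_center(image.shape)
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    src_x = cx + (xs - cx) / M
    src_y = cy + (ys - cy) / M
    coords = np.stack([src_y, src_x])
    if image.ndim == 2:
        return ndimage.map_coordinates(image.astype(float), coords, order=1, mode="nearest")
    out = np.stack(
        [
            ndimage.map_coordinates(image[..., c].astype(float), coords, order=1, mode="nearest")
            for c in range(image.shape[2])
        ],
        axis=-1,
    )
    if np.issubdtype(image.dtype, np.integer):
        out = np.rint(out).clip(0, np.iinfo(image.dtype).max).astype(image.dtype)
    return out


def revert_points(
    points: Sequence[PixelPoint | tuple],
    M: float,
    image_size: tuple[int, int],
) -> list[PixelPoint]:
    """Map points detected on a zoomed frame back to original coordinates.

    ``p_orig = center + (p_zoomed - center) / M`` with the centre at
    ``((W-1)/2, (H-1)/2)`` — the exact inverse of the coordinate map used by
    :func:`zoom`.
    """
    if not M >= 1:
        raise InvalidMagnificationError(f"magnification must be >= 1, got {M!r}")
    W, H = image_size
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    return [PixelPoint(cx + (x - cx) / M, cy + (y - cy) / M) for x, y in points]


def revert_detection(det: Detection, M: float, image_size: tuple[int, int]) -> Detection:
    """Revert a detection's box corners and keypoints to original coordinates."""
    (x0, y0), (x1, y1) = revert_points([det.box[:2], det.box[2:]], M, image_size)
    arr = det.keypoints.as_array()
    pts = revert_points([(x, y) for x, y, _ in arr], M, image_size)
    new_arr = np.column_stack([[p.x for p in pts], [p.y for p in pts], arr[:, 2]])
    return replace(
        det,
        box=(x0, y0, x1, y1),
        keypoints=KeypointSet.from_array(new_arr),
    )


def zoomin_search(
    image: np.ndarray,
    detector: Detector,
    alpha: float = 1.2,
    cap: float = 5.0,
) -> ZoomResult:
    """Run the detector at magnifications 1, alpha, alpha^2, ... <= cap.

    The magnification whose detections sum to the strictly highest total
    score wins; ties keep the smaller M (less interpolation blur).  The
    winning detections are returned reverted to original-image coordinates.
    With the defaults alpha = 1.2 and cap = 5, nine magnifications
    1.2^0 ... 1.2^8 are evaluated.
    """
    if not alpha > 1:
        raise InvalidInputError(f"alpha must be > 1, got {alpha!r}")
    if not cap >= 1:
        raise InvalidInputError(f"cap must be >= 1, got {cap!r}")
    image = np.asarray(image)
    H, W = image.shape[:2]
    trace: list[tuple[float, float]] = []
    best_m, best_score, best_dets = 1.0, -np.inf, []
    k = 0
    while True:
        M = alpha**k
        if M > cap:
            break
        frame = image if k == 0 else zoom(image, M)
        try:
            dets = detector(frame)
        except Exception as exc:  # contract: attach the failing M
            raise DetectorError(M, exc) from exc
        total = float(sum(d.score for d in dets))
        trace.append((M, total))
        if total > best_score:  # strict: ties keep the smaller M
            best_m, best_score, best_dets = M, total, dets
        k += 1
    reverted = [revert_detection(d, best_m, (W, H)) for d in best_dets]
    return ZoomResult(
        detections=reverted,
        best_magnification=best_m,
        best_total_score=max(best_score, 0.0),
        trace=trace,
    )
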