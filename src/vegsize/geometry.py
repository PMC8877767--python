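"""Pinhole-camera conversions and radius-corrected size estimation.

The measurement model turns a pixel distance between two keypoints into a
metric length in three steps: Euclidean pixel distance, projection onto the
physical image sensor (via the pixel pitch), and similar-triangle scaling by
the object's depth.  Because the left/right keypoints sit on the object's
silhouette while the queried depth belongs to the *front* surface at the
object centre, the gourd/solanaceous cross-section is modelled as circular:
the widest section lies half a diameter behind the centre-point depth, which
turns the naive scaling ``lr = ls * d / f`` into

    D = d * Ds / (f - Ds / 2)        (diameter, Left-Right keypoints)
    L = d * Ls / (f - Ds / 2)        (length,   Top-Bottom keypoints)

where ``f`` is the focal length, ``d`` the centre-point depth and ``Ds``,
``Ls`` the on-sensor distances of the diameter and length chords.  The
length denominator uses ``Ds`` (not ``Ls``) because the depth offset of the
widest section is set by the cross-section radius ``D/2``; this is
algebraically exact given ``L / Ls = (d + D/2) / f``.

Lengths measured between Top and Bottom are chords: a curved cucumber is
under-measured by design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import yaml

from .errors import (
    DegenerateGeometryError,
    IncompleteDetectionError,
    InvalidDepthError,
    InvalidInputError,
)

__all__ = [
    "CameraIntrinsics",
    "PixelPoint",
    "KeypointSet",
    "SizeEstimate",
    "KEYPOINT_NAMES",
    "INTRINSICS_PROFILES",
    "pixel_distance",
    "pixel_to_sensor",
    "active_sensor_size",
    "sensor_to_world",
    "estimate_diameter",
    "estimate_length",
    "measure",
]

#: Canonical keypoint order, shared with the COCO dialect.
KEYPOINT_NAMES = ("peduncle", "top", "left", "bottom", "right", "center")


class PixelPoint(NamedTuple):
    """A real-valued image position: 0-based, origin top-left, x rightward
    (column), y downward (row).  Pixel centres sit at integer coordinates."""

    x: float
    y: float


@dataclass(frozen=True)
class CameraIntrinsics:
    """Physical camera parameters linking pixels to millimetres.

    The pixel pitch is derived from the sensor height and the row count
    (``sensor_height_mm / height_px``); pixels are assumed square, so the
    active sensor width is ``pitch * width_px`` and must fit on the die.
    """

    focal_length_mm: float
    sensor_width_mm: float
    sensor_height_mm: float
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        for name in (
            "focal_length_mm",
            "sensor_width_mm",
            "sensor_height_mm",
            "width_px",
            "height_px",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name} must be strictly positive, got {v!r}")
        if self.active_width_mm > self.sensor_width_mm * (1 + 1e-9):
            raise InvalidInputError(
                f"active width {self.active_width_mm:.4f} mm exceeds the die "
                f"width {self.sensor_width_mm:.4f} mm: the {self.width_px}x"
                f"{self.height_px} crop does not fit the sensor"
            )
        # Square-pixel sanity: if the crop spans (nearly) the full die, the
        # width-derived pitch must agree with the height-derived one.
        pitch_w = self.sensor_width_mm / self.width_px
        spans_die = self.active_width_mm > 0.98 * self.sensor_width_mm
        if spans_die and abs(pitch_w - self.pixel_pitch_mm) > 0.02 * self.pixel_pitch_mm:
            warnings.warn(
                "pixel pitch implied by sensor width differs from the "
                "height-derived pitch by more than 2%: pixels may not be square",
                stacklevel=2,
            )

    @property
    def pixel_pitch_mm(self) -> float:
        """Physical size of one (square) pixel, mm."""
        return self.sensor_height_mm / self.height_px

    @property
    def active_width_mm(self) -> float:
        return self.pixel_pitch_mm * self.width_px

    @property
    def focal_px(self) -> float:
        """Focal length expressed in pixels (f / pitch)."""
        return self.focal_length_mm / self.pixel_pitch_mm

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "CameraIntrinsics":
        return cls(
            focal_length_mm=float(d["focal_length_mm"]),
            sensor_width_mm=float(d["sensor_width_mm"]),
            sensor_height_mm=float(d["sensor_height_mm"]),
            width_px=int(d["width_px"]),
            height_px=int(d["height_px"]),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "CameraIntrinsics":
        """Load intrinsics from a small key-value YAML config."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "focal_length_mm": self.focal_length_mm,
            "sensor_width_mm": self.sensor_width_mm,
            "sensor_height_mm": self.sensor_height_mm,
            "width_px": self.width_px,
            "height_px": self.height_px,
        }


#: Built-in profiles.  ``d415-vga`` is the RealSense D415 RGB camera at
#: 640x480: f = 1.88 mm on a 2.73 x 1.55 mm sensor (active area 2.07 x 1.55).
INTRINSICS_PROFILES: dict[str, CameraIntrinsics] = {
    "d415-vga": CameraIntrinsics(
        focal_length_mm=1.88,
        sensor_width_mm=2.73,
        sensor_height_mm=1.55,
        width_px=640,
        height_px=480,
    ),
}


def _all2() -> dict:
    return {name: 2 for name in KEYPOINT_NAMES}


@dataclass
class KeypointSet:
    """The six named keypoints of one vegetable.

    Visibility follows the COCO convention: 0 = not labeled, 1 = labeled but
    occluded, 2 = labeled and visible.  Measurement requires a labeled point
    (v >= 1): an occluded-but-annotated keypoint still carries coordinates.
    """

    peduncle: PixelPoint
    top: PixelPoint
    left: PixelPoint
    bottom: PixelPoint
    right: PixelPoint
    center: PixelPoint
    visibility: dict = field(default_factory=_all2)

    def __post_init__(self) -> None:
        for name in KEYPOINT_NAMES:
            p = getattr(self, name)
            if not isinstance(p, PixelPoint):
                setattr(self, name, PixelPoint(*p))
        missing = set(KEYPOINT_NAMES) - set(self.visibility)
        if missing:
            self.visibility = {**_all2(), **self.visibility}

    def point(self, name: str) -> PixelPoint:
        return getattr(self, name)

    def is_labeled(self, name: str) -> bool:
        return int(self.visibility.get(name, 0)) >= 1

    def items(self) -> Iterator[tuple[str, PixelPoint]]:
        for name in KEYPOINT_NAMES:
            yield name, getattr(self, name)

    def is_orientation_consistent(self) -> bool:
        """False when the detector swapped the lateral keypoints
        (left.x > right.x).  Measurement is unaffected (distances are
        symmetric) but the flag is useful for QC."""
        return self.left.x <= self.right.x

    def as_array(self) -> np.ndarray:
        """(6, 3) array of (x, y, v) rows in canonical keypoint order."""
        return np.array(
            [(p.x, p.y, self.visibility.get(n, 0)) for n, p in self.items()],
            dtype=float,
        )

    @classmethod
    def from_array(cls, arr) -> "KeypointSet":
        arr = np.asarray(arr, dtype=float).reshape(6, 3)
        pts = {n: PixelPoint(float(x), float(y)) for n, (x, y, _) in zip(KEYPOINT_NAMES, arr)}
        vis = {n: int(v) for n, (_, _, v) in zip(KEYPOINT_NAMES, arr)}
        return cls(visibility=vis, **pts)

    def translated(self, dx: float, dy: float) -> "KeypointSet":
        pts = {n: PixelPoint(p.x + dx, p.y + dy) for n, p in self.items()}
        return KeypointSet(visibility=dict(self.visibility), **pts)


@dataclass(frozen=True)
class SizeEstimate:
    """A size measurement with its intermediates.

    ``sensor_diameter_mm``/``sensor_length_mm`` are the keypoint chord
    lengths projected on the physical sensor (the quantities the radius
    correction acts on); ``depth_used_mm`` is the centre-point depth that
    scaled them into world units.
    """

    diameter_mm: float
    length_mm: float
    depth_used_mm: float
    sensor_diameter_mm: float
    sensor_length_mm: float
    depth_from_fallback: bool = False

    def __post_init__(self) -> None:
        if self.diameter_mm < 0 or self.length_mm < 0:
            raise InvalidInputError("estimated sizes must be non-negative")
        if self.depth_used_mm <= 0:
            raise InvalidDepthError("depth_used_mm must be positive")


# ---------------------------------------------------------------------------
# conversions


def pixel_distance(a: PixelPoint | tuple, b: PixelPoint | tuple) -> float:
    """Euclidean distance between two image points, in pixels."""
    ax, ay = a
    bx, by = b
    if not all(map(math.isfinite, (ax, ay, bx, by))):
        raise InvalidInputError("pixel coordinates must be finite")
    return math.hypot(ax - bx, ay - by)


def pixel_to_sensor(lp: float, cam: CameraIntrinsics) -> float:
    """Map a pixel distance to millimetres on the physical sensor.

    ``ls = sensor_height_mm * lp / height_px`` — with the d415-vga profile
    this is the familiar ``1.55 * lp / 480``.
    """
    if not (np.isfinite(lp) and lp >= 0):
        raise InvalidInputError(f"pixel distance must be >= 0, got {lp!r}")
    return cam.pixel_pitch_mm * lp


def active_sensor_size(cam: CameraIntrinsics) -> tuple[float, float]:
    """(width, height) in mm of the sensor area the image actually covers."""
    return (cam.active_width_mm, cam.sensor_height_mm)


def sensor_to_world(ls: float, d: float, cam: CameraIntrinsics) -> float:
    """Uncorrected similar-triangle scaling: ``lr = ls * d / f``.

    Valid for flat objects whose keypoints all lie at depth ``d``.
    """
    if not (np.isfinite(ls) and ls >= 0):
        raise InvalidInputError(f"sensor distance must be >= 0, got {ls!r}")
    if not (np.isfinite(d) and d > 0):
        raise InvalidDepthError(f"depth must be positive, got {d!r}")
    return ls * d / cam.focal_length_mm


def _corrected(numerator_mm: float, Ds: float, d: float, cam: CameraIntrinsics) -> float:
    f = cam.focal_length_mm
    if not (np.isfinite(d) and d > 0):
        raise InvalidDepthError(f"depth must be positive, got {d!r}")
    if not (np.isfinite(Ds) and Ds >= 0):
        raise InvalidInputError(f"sensor distance must be >= 0, got {Ds!r}")
    if Ds >= 2 * f:
        raise DegenerateGeometryError(
            f"sensor extent Ds={Ds:g} mm >= 2f={2 * f:g} mm: the circular "
            "cross-section correction is undefined for such a wide subtense"
        )
    return d * numerator_mm / (f - Ds / 2)


def estimate_diameter(Ds: float, d: float, cam: CameraIntrinsics) -> float:
    """Radius-corrected diameter ``D = d * Ds / (f - Ds/2)``.

    Solves ``D / Ds = (d + D/2) / f``: the widest (circular) cross-section
    lies ``D/2`` behind the centre-point depth ``d``.
    """
    return _corrected(Ds, Ds, d, cam)


def estimate_length(Ls: float, Ds: float, d: float, cam: CameraIntrinsics) -> float:
    """Radius-corrected length ``L = d * Ls / (f - Ds/2)``.

    The denominator uses the diameter chord ``Ds`` because the depth offset
    of the measured section is the cross-section radius, regardless of the
    chord being measured; equal to ``Ls * (d + D/2) / f`` with D from
    :func:`estimate_diameter`.
    """
    return _corrected(Ls, Ds, d, cam)


_REQUIRED_FOR_MEASURE = ("left", "right", "top", "bottom", "center")


def measure(
    kp: KeypointSet,
    d_center: float,
    cam: CameraIntrinsics,
    *,
    depth_from_fallback: bool = False,
) -> SizeEstimate:
    """Measure one vegetable from its keypoints and centre-point depth.

    Diameter comes from the Left-Right chord, length from the Top-Bottom
    chord, both radius-corrected with the depth queried at the Center
    keypoint.  The peduncle is never used.
    """
    for name in _REQUIRED_FOR_MEASURE:
        if not kp.is_labeled(name):
            raise IncompleteDetectionError(
                f"keypoint {name!r} is required for measurement but not labeled"
            )
    if not (np.isfinite(d_center) and d_center > 0):
        raise InvalidDepthError(f"centre depth must be positive, got {d_center!r}")
    lp_d = pixel_distance(kp.left, kp.right)
    lp_l = pixel_distance(kp.top, kp.bottom)
    Ds = pixel_to_sensor(lp_d, cam)
    Ls = pixel_to_sensor(lp_l, cam)
    return SizeEstimate(
        diameter_mm=estimate_diameter(Ds, d_center, cam),
        length_mm=estimate_length(Ls, Ds, d_center, cam),
        depth_used_mm=float(d_center),
        sensor_diameter_mm=Ds,
        sensor_length_mm=Ls,
        depth_from_fallback=depth_from_fallback,
    )
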