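"""Depth-map alignment and repair.

An active-stereo depth camera computes depth in its own (left-IR) frame, so
the raw depth map and the colour image disagree about where objects are.
Alignment deprojects every valid depth pixel to 3D, moves it through the
depth-to-colour rigid transform, and reprojects it into the colour camera;
colliding samples keep the nearest surface (z-buffer).

Stereo matching also loses depth along an object's *left* edge (seen by the
left camera only), returning 0 there.  Repair mirrors the usual SDK recipe:
an edge-preserving exponential smoothing pass (``spatial_filter``) plus a
directional hole fill that copies the first valid value to the right — which
belongs to the occluding object surface, exactly what the centre-depth
measurement wants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import BehindCameraError, BoundsError, InvalidDepthError, InvalidInputError
from .geometry import CameraIntrinsics, PixelPoint

__all__ = [
    "DepthMap",
    "PinholeProjection",
    "RigidTransform",
    "deproject",
    "project",
    "align_depth_to_color",
    "spatial_filter",
    "hole_fill",
    "query_depth",
]


@dataclass
class DepthMap:
    """H x W grid of camera-to-surface distances in millimetres.

    0 encodes an invalid pixel (a hole).  The grid is stored as float64 so
    filtered values keep sub-millimetre precision; PNG I/O rounds to the
    nearest integer millimetre (16-bit).
    """

    data: np.ndarray
    warning: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError(f"depth grid must be 2-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise InvalidInputError("depth values must be finite and >= 0")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def hole_count(self) -> int:
        return int(np.count_nonzero(self.data == 0))

    def copy(self) -> "DepthMap":
        return DepthMap(self.data.copy(), warning=self.warning)

    # -- I/O: 16-bit single-channel PNG (mm) and raw NumPy grids -----------

    def to_png(self, path: str | Path) -> None:
        iio.imwrite(Path(path), np.rint(self.data).clip(0, 65535).astype(np.uint16))

    @classmethod
    def from_png(cls, path: str | Path) -> "DepthMap":
        return cls(iio.imread(Path(path)).astype(float))

    def to_npy(self, path: str | Path) -> None:
        np.save(Path(path), self.data)

    @classmethod
    def from_npy(cls, path: str | Path) -> "DepthMap":
        return cls(np.load(Path(path)))


@dataclass(frozen=True)
class PinholeProjection:
    """Pixel-unit intrinsics (fx, fy in px; principal point cx, cy)."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidInputError("focal lengths must be positive")

    @classmethod
    def from_intrinsics(cls, cam: CameraIntrinsics) -> "PinholeProjection":
        """Square pixels, principal point at the image centre."""
        f_px = cam.focal_px
        return cls(fx=f_px, fy=f_px, cx=(cam.width_px - 1) / 2, cy=(cam.height_px - 1) / 2)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation (mm) between two camera frames."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise InvalidInputError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise InvalidInputError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation.T + self.translation


def deproject(p: PixelPoint | tuple, d: float, proj: PinholeProjection) -> np.ndarray:
    """Lift a pixel with known depth to a 3D camera-frame point (mm)."""
    if not d > 0:
        raise InvalidDepthError(f"depth must be positive, got {d!r}")
    x, y = p
    return np.array([(x - proj.cx) * d / proj.fx, (y - proj.cy) * d / proj.fy, d])


def project(P, proj: PinholeProjection) -> PixelPoint:
    """Project a 3D camera-frame point (mm) onto the image plane."""
    X, Y, Z = np.asarray(P, dtype=float)
    if not Z > 0:
        raise BehindCameraError(f"cannot project point with Z={Z!r} <= 0")
    return PixelPoint(proj.fx * X / Z + proj.cx, proj.fy * Y / Z + proj.cy)


def align_depth_to_color(
    depth: DepthMap,
    depth_proj: PinholeProjection,
    color_proj: PinholeProjection,
    T: RigidTransform,
    color_shape: tuple[int, int] | None = None,
) -> DepthMap:
    """Rewarp a depth map into the colour camera's pixel frame.

    Every valid source pixel is deprojected, moved through ``T`` (depth
    frame -> colour frame) and reprojected; when several sources land in one
    target cell the smallest depth wins (the nearer surface occludes).
    Untouched cells stay 0.
    """
    H, W = depth.shape if color_shape is None else color_shape
    src = depth.data
    ys, xs = np.nonzero(src > 0)
    out = np.full((H, W), np.inf)
    if xs.size:
        d = src[ys, xs]
        X = (xs - depth_proj.cx) * d / depth_proj.fx
        Y = (ys - depth_proj.cy) * d / depth_proj.fy
        pts = T.apply(np.column_stack([X, Y, d]))
        Z = pts[:, 2]
        front = Z > 0
        u = np.rint(color_proj.fx * pts[front, 0] / Z[front] + color_proj.cx).astype(int)
        v = np.rint(color_proj.fy * pts[front, 1] / Z[front] + color_proj.cy).astype(int)
        ok = (u >= 0) & (u < W) & (v >= 0) & (v < H)
        np.minimum.at(out, (v[ok], u[ok]), Z[front][ok])
    out[~np.isfinite(out)] = 0.0
    return DepthMap(out)


def _directional_pass(grid: np.ndarray, alpha: float, delta: float) -> None:
    """One left-to-right smoothing sweep, in place.  Columns are visited in
    order; each pixel blends with the already-filtered pixel to its left
    when both are valid and within ``delta``.  Transpose/flip the grid to
    get the other three directions."""
    for j in range(1, grid.shape[1]):
        cur = grid[:, j]
        prev = grid[:, j - 1]
        gate = (cur > 0) & (prev > 0) & (np.abs(prev - cur) < delta)
        cur[gate] = alpha * cur[gate] + (1.0 - alpha) * prev[gate]


def spatial_filter(
    depth: DepthMap,
    alpha: float = 0.5,
    delta: float = 20.0,
    iterations: int = 2,
) -> DepthMap:
    """Edge-preserving exponential smoothing of a depth map.

    Each iteration sweeps the grid horizontally (both directions) then
    vertically (both directions).  A neighbour contributes only if it is
    valid and within ``delta`` mm of the current value, so steps taller than
    ``delta`` survive exactly and holes neither spread nor close.  ``alpha``
    is the weight kept by the current pixel (1 = no smoothing).
    """
    if not 0 < alpha <= 1:
        raise InvalidInputError(f"alpha must be in (0, 1], got {alpha!r}")
    if delta <= 0:
        raise InvalidInputError(f"delta must be positive, got {delta!r}")
    if iterations < 1:
        raise InvalidInputError(f"iterations must be >= 1, got {iterations!r}")
    g = depth.data.copy()
    for _ in range(iterations):
        _directional_pass(g, alpha, delta)              # left -> right
        _directional_pass(g[:, ::-1], alpha, delta)     # right -> left
        _directional_pass(g.T, alpha, delta)            # top -> bottom
        _directional_pass(g.T[:, ::-1], alpha, delta)   # bottom -> top
    return DepthMap(g)


def hole_fill(depth: DepthMap) -> DepthMap:
    """Fill holes with the nearest valid value to the *right* on the row.

    Stereo holes hug an object's left edge, so the first valid pixel to the
    right lies on the occluding object surface.  Holes with no valid pixel
    to their right take the nearest valid value to the left; rows with no
    valid pixel at all fall back to the nearest valid pixel in full-image
    scan order.  An all-zero map is returned unchanged with a warning flag.
    """
    g = depth.data.copy()
    valid = g > 0
    if not valid.any():
        warnings.warn("hole_fill: depth map contains no valid pixels", stacklevel=2)
        return DepthMap(g, warning="all-invalid depth map; holes not filled")
    W = g.shape[1]
    # right-to-left sweep carrying the next valid value on the row
    carry = np.zeros(g.shape[0])
    for j in range(W - 1, -1, -1):
        col = g[:, j]
        carry = np.where(col > 0, col, carry)
        col[col == 0] = carry[col == 0]
    # remaining holes (nothing valid to the right): nearest valid to the left
    carry = np.zeros(g.shape[0])
    for j in range(W):
        col = g[:, j]
        carry = np.where(col > 0, col, carry)
        col[col == 0] = carry[col == 0]
    # rows with no valid pixel at all: nearest valid in flat scan order
    if np.any(g == 0):
        flat = g.ravel()
        holes = np.nonzero(flat == 0)[0]
        filled = np.nonzero(flat > 0)[0]
        pos = np.searchsorted(filled, holes)
        left = filled[np.clip(pos - 1, 0, filled.size - 1)]
        right = filled[np.clip(pos, 0, filled.size - 1)]
        nearest = np.where(np.abs(holes - left) <= np.abs(right - holes), left, right)
        flat[holes] = flat[nearest]
    return DepthMap(g)


def query_depth(depth: DepthMap, p: PixelPoint | tuple) -> float:
    """Depth at the nearest integer cell; 0 signals an unfilled hole.

    Nearest-cell (not bilinear) lookup on purpose: interpolating across an
    object/background discontinuity would bias the centre depth.
    """
    x, y = p
    H, W = depth.shape
    if not (-0.5 <= x <= W - 0.5 and -0.5 <= y <= H - 0.5):
        raise BoundsError(f"point ({x}, {y}) outside a {W}x{H} image")
    j = min(int(np.rint(x)), W - 1)
    i = min(int(np.rint(y)), H - 1)
    return float(depth.data[i, j])
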