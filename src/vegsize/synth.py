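"""Synthetic RGB-D scene generator: the test oracle for the pipeline.

Parametric vegetables of known diameter and length are posed in the camera
frame and ray-cast through the pinhole model into a colour image and a
depth map.  Tomatoes and peppers are ellipsoids, cucumbers and eggplants
are capsules — the simplest solids with the circular cross-section the
radius-corrected measurement model assumes.  The renderer also emits
analytic ground-truth keypoints:

* Left/Right: endpoints of the widest section perpendicular to the axis,
  i.e. the chord a human annotator marks;
* Top/Bottom: the axis endpoints;
* Center: the object centre, whose queried depth is the front-surface
  depth (centre Z minus the cross-section radius);
* Peduncle: a decorative point beyond Top along the axis (never measured).

Realism knobs emulate the failure modes of real captures: per-keypoint
pixel jitter, depth noise, stereo-occlusion holes hugging each object's
left edge, a leafy green background with dark shadow clutter, and a
detector whose score degrades with on-image object size (so small, distant
objects drop below the 0.6 score threshold until the zoom-in loop rescues
them).  The backdrop is procedural noise in green hues; no photorealism is
claimed, and occlusion between vegetables is flagged, not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .depth import DepthMap, PinholeProjection, RigidTransform
from .errors import InvalidInputError, RenderError
from .geometry import (
    KEYPOINT_NAMES,
    CameraIntrinsics,
    INTRINSICS_PROFILES,
    KeypointSet,
    PixelPoint,
)
from .zoomin import CLASS_LABELS, SCORE_THRESHOLD, Detection

__all__ = [
    "VegetableModel",
    "NoiseSpec",
    "SceneSpec",
    "RenderedScene",
    "STANDARD_MODELS",
    "CLASS_SHAPES",
    "CLASS_COLORS",
    "DEFAULT_SCORE_AREA",
    "MIN_WORKING_DEPTH_MM",
    "axis_from_angle",
    "ground_truth_keypoints",
    "ground_truth_detection",
    "center_surface_depth",
    "render",
    "render_depth_frame",
    "perturb_detection",
    "make_color_detector",
    "DETECTOR_FACTORIES",
]

#: Stereo depth is unavailable closer than this at VGA resolution.
MIN_WORKING_DEPTH_MM = 310.0

#: Shape family per class: circular cross-section solids.
CLASS_SHAPES = {
    "cucumber": "capsule",
    "eggplant": "capsule",
    "tomato": "ellipsoid",
    "pepper": "ellipsoid",
}

#: Flat silhouette colours (RGB).  Cucumber and pepper are deliberately
#: green-on-green against the leafy backdrop — the classic hard case for
#: colour-threshold segmentation baselines; tomato red is the easy one.
CLASS_COLORS = {
    "cucumber": (80, 150, 60),
    "eggplant": (90, 40, 120),
    "tomato": (200, 45, 40),
    "pepper": (50, 165, 70),
}

#: Reported sizes (diameter, length in mm) of the twelve standard vegetable
#: models used to benchmark the measurement method.
STANDARD_MODELS: dict[str, tuple[str, float, float]] = {
    "cucumber1": ("cucumber", 34.53, 263.54),
    "cucumber2": ("cucumber", 29.03, 236.96),
    "cucumber3": ("cucumber", 27.36, 245.13),
    "eggplant1": ("eggplant", 50.28, 179.22),
    "eggplant2": ("eggplant", 77.37, 140.64),
    "eggplant3": ("eggplant", 41.31, 229.05),
    "tomato1": ("tomato", 84.36, 65.17),
    "tomato2": ("tomato", 78.10, 54.28),
    "tomato3": ("tomato", 83.79, 65.81),
    "pepper1": ("pepper", 76.41, 80.34),
    "pepper2": ("pepper", 75.84, 79.49),
    "pepper3": ("pepper", 75.55, 80.17),
}

#: Box area (px^2) at which the emulated detector reaches full confidence:
#: score(a) = min(1, a / DEFAULT_SCORE_AREA).  Objects whose box is smaller
#: than 0.6 * this fall below the contract threshold, exercising zoom-in.
DEFAULT_SCORE_AREA = 6000.0


def axis_from_angle(angle_deg: float) -> np.ndarray:
    """In-image-plane axis direction, ``angle_deg`` away from vertical
    (0 = pointing up in the image, positive = clockwise)."""
    th = np.deg2rad(angle_deg)
    return np.array([np.sin(th), -np.cos(th), 0.0])


@dataclass
class VegetableModel:
    """Ground-truth parametric vegetable in the colour-camera frame (mm)."""

    class_label: str
    diameter_mm: float
    length_mm: float
    position: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 600.0]))
    axis: np.ndarray = field(default_factory=lambda: axis_from_angle(0.0))
    shape: str | None = None  # default derived from class

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise InvalidInputError(f"unknown class {self.class_label!r}")
        if self.shape is None:
            self.shape = CLASS_SHAPES[self.class_label]
        if self.shape not in ("ellipsoid", "capsule"):
            raise InvalidInputError(f"unknown shape {self.shape!r}")
        if not (self.diameter_mm > 0 and self.length_mm > 0):
            raise InvalidInputError("diameter and length must be positive")
        if self.shape == "capsule" and self.length_mm < self.diameter_mm:
            raise InvalidInputError("a capsule needs length >= diameter")
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.position[2] < MIN_WORKING_DEPTH_MM:
            raise InvalidInputError(
                f"object depth {self.position[2]:.0f} mm is below the "
                f"{MIN_WORKING_DEPTH_MM:.0f} mm minimum working depth"
            )
        a = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(a)
        if n == 0:
            raise InvalidInputError("axis must be a non-zero vector")
        self.axis = a / n

    @classmethod
    def standard(
        cls,
        name: str,
        position=(0.0, 0.0, 600.0),
        axis_angle_deg: float = 0.0,
    ) -> "VegetableModel":
        """Instantiate one of the twelve standard benchmark models."""
        label, D, L = STANDARD_MODELS[name]
        return cls(label, D, L, position=np.asarray(position, float),
                   axis=axis_from_angle(axis_angle_deg))


@dataclass
class NoiseSpec:
    """Detector/sensor imperfection levels for a synthetic scene."""

    keypoint_jitter_px: float = 0.0
    depth_noise_mm: float = 0.0
    hole_width_px: int = 0

    def __post_init__(self) -> None:
        if self.keypoint_jitter_px < 0 or self.depth_noise_mm < 0 or self.hole_width_px < 0:
            raise InvalidInputError("noise levels must be >= 0")


@dataclass
class SceneSpec:
    """Full description of a synthetic scene; the seed fixes all randomness."""

    objects: list[VegetableModel]
    camera: CameraIntrinsics = field(default_factory=lambda: INTRINSICS_PROFILES["d415-vga"])
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    background_depth_mm: float = 2500.0
    n_leaves: int = 15
    n_shadow_blobs: int = 8
    #: optional second (depth) camera: (pixel intrinsics, depth->colour transform)
    depth_camera: Optional[tuple[PinholeProjection, RigidTransform]] = None

    @classmethod
    def from_file(cls, path: str | Path) -> "SceneSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        cam = (
            CameraIntrinsics.from_dict(cfg["camera"])
            if isinstance(cfg.get("camera"), dict)
            else INTRINSICS_PROFILES[cfg.get("camera", "d415-vga")]
        )
        objs = []
        for o in cfg["objects"]:
            if "model" in o:
                objs.append(
                    VegetableModel.standard(
                        o["model"],
                        position=o.get("position", (0.0, 0.0, 600.0)),
                        axis_angle_deg=o.get("axis_angle_deg", 0.0),
                    )
                )
            else:
                objs.append(
                    VegetableModel(
                        o["class"],
                        o["diameter_mm"],
                        o["length_mm"],
                        position=np.asarray(o.get("position", (0.0, 0.0, 600.0)), float),
                        axis=axis_from_angle(o.get("axis_angle_deg", 0.0)),
                    )
                )
        noise = NoiseSpec(**cfg.get("noise", {}))
        return cls(
            objects=objs,
            camera=cam,
            noise=noise,
            seed=int(cfg.get("seed", 0)),
            background_depth_mm=float(cfg.get("background_depth_mm", 2500.0)),
            n_leaves=int(cfg.get("n_leaves", 15)),
            n_shadow_blobs=int(cfg.get("n_shadow_blobs", 8)),
        )


@dataclass
class RenderedScene:
    """Raster outputs plus the ground truth that produced them."""

    color: np.ndarray  # H x W x 3 uint8
    depth: DepthMap
    detections: list[Detection]  # ground truth, score 1.0
    spec: SceneSpec
    masks: list[np.ndarray] = field(default_factory=list)  # per-object silhouettes


# ---------------------------------------------------------------------------
# analytic ground truth


def _object_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (w, v) completing the object axis u; w is chosen in the
    image plane (perpendicular to the optical axis) so the widest-section
    endpoints share the object centre's Z — exactly the configuration the
    radius-corrected equations assume."""
    z = np.array([0.0, 0.0, 1.0])
    if abs(u @ z) > 0.999:
        w = np.array([1.0, 0.0, 0.0])
    else:
        w = np.cross(u, z)
        w /= np.linalg.norm(w)
    v = np.cross(u, w)
    return w, v


def center_surface_depth(model: VegetableModel) -> float:
    """Depth (Z, mm) of the visible front surface at the object centre:
    centre Z minus the circular cross-section radius."""
    return float(model.position[2] - model.diameter_mm / 2.0)


def ground_truth_keypoints(model: VegetableModel, cam: CameraIntrinsics) -> KeypointSet:
    proj = PinholeProjection.from_intrinsics(cam)
    u = model.axis
    w, _ = _object_frame(u)
    Pc = model.position
    half_len = model.length_mm / 2.0
    r = model.diameter_mm / 2.0

    def prj(P) -> PixelPoint:
        X, Y, Z = P
        if Z <= 0:
            raise RenderError("object point behind camera")
        return PixelPoint(proj.fx * X / Z + proj.cx, proj.fy * Y / Z + proj.cy)

    p_a = prj(Pc + u * half_len)
    p_b = prj(Pc - u * half_len)
    top, bottom = (p_a, p_b) if p_a.y <= p_b.y else (p_b, p_a)
    q_a = prj(Pc + w * r)
    q_b = prj(Pc - w * r)
    left, right = (q_a, q_b) if q_a.x <= q_b.x else (q_b, q_a)
    # peduncle sits beyond the Top end along the axis (decorative)
    ped_end = u if p_a.y <= p_b.y else -u
    peduncle = prj(Pc + ped_end * (half_len + 0.1 * model.length_mm))
    center = prj(Pc)
    return KeypointSet(
        peduncle=peduncle, top=top, left=left, bottom=bottom, right=right, center=center
    )


def _surface_points(model: VegetableModel, n_axial: int = 24, n_angular: int = 24) -> np.ndarray:
    """Coarse parametric sampling of the surface, for projected-box bounds."""
    u = model.axis
    w, v = _object_frame(u)
    r = model.diameter_mm / 2.0
    phis = np.linspace(0, 2 * np.pi, n_angular, endpoint=False)
    ring = np.outer(np.cos(phis), w) + np.outer(np.sin(phis), v)  # (n_angular, 3)
    if model.shape == "capsule":
        h = (model.length_mm - model.diameter_mm) / 2.0
        ts = np.linspace(-h, h, max(n_axial // 2, 2))
        pts = [model.position + u * t + ring * r for t in ts]
        # hemispherical caps
        for sign in (-1.0, 1.0):
            for lat in np.linspace(0, np.pi / 2, 6)[1:]:
                rr = r * np.cos(lat)
                off = sign * (h + r * np.sin(lat))
                pts.append(model.position + u * off + ring * rr)
    else:
        lats = np.linspace(-np.pi / 2, np.pi / 2, n_axial)
        pts = [
            model.position
            + u * (model.length_mm / 2.0) * np.sin(lat)
            + ring * (r * np.cos(lat))
            for lat in lats
        ]
    return np.concatenate(pts, axis=0)


def approx_projected_box(model: VegetableModel, cam: CameraIntrinsics) -> tuple:
    """Tight axis-aligned bounds of the projected silhouette (sampled)."""
    proj = PinholeProjection.from_intrinsics(cam)
    P = _surface_points(model)
    if np.any(P[:, 2] <= 0):
        raise RenderError("object extends behind the camera")
    xs = proj.fx * P[:, 0] / P[:, 2] + proj.cx
    ys = proj.fy * P[:, 1] / P[:, 2] + proj.cy
    return (float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max()))


def ground_truth_detection(model: VegetableModel, cam: CameraIntrinsics) -> Detection:
    """Exact detection (score 1.0) as an ideal detector would emit it."""
    return Detection(
        class_label=model.class_label,
        score=1.0,
        box=approx_projected_box(model, cam),
        keypoints=ground_truth_keypoints(model, cam),
    )


# ---------------------------------------------------------------------------
# ray casting


def _ray_ellipsoid_depth(model: VegetableModel, dirs: np.ndarray) -> np.ndarray:
    u = model.axis
    w, v = _object_frame(u)
    semi = np.array([model.length_mm / 2.0, model.diameter_mm / 2.0, model.diameter_mm / 2.0])
    M = np.stack([u, w, v]) / semi[:, None]  # world -> unit-sphere frame
    op = M @ (-model.position)
    dp = dirs @ M.T
    a = np.einsum("ij,ij->i", dp, dp)
    b = 2.0 * dp @ op
    c = op @ op - 1.0
    disc = b * b - 4.0 * a * c
    t = np.full(dirs.shape[0], np.inf)
    hit = disc >= 0
    th = (-b[hit] - np.sqrt(disc[hit])) / (2.0 * a[hit])
    th[th <= 0] = np.inf
    t[hit] = th
    return t


def _ray_sphere_entry(C: np.ndarray, r: float, dirs: np.ndarray) -> np.ndarray:
    dd = np.einsum("ij,ij->i", dirs, dirs)
    b = dirs @ C
    c = C @ C - r * r
    disc = b * b - dd * c
    t = np.full(dirs.shape[0], np.inf)
    hit = disc >= 0
    th = (b[hit] - np.sqrt(disc[hit])) / dd[hit]
    th[th <= 0] = np.inf
    t[hit] = th
    return t


def _ray_capsule_depth(model: VegetableModel, dirs: np.ndarray) -> np.ndarray:
    u = model.axis
    h = (model.length_mm - model.diameter_mm) / 2.0
    r = model.diameter_mm / 2.0
    A = model.position - u * h
    B = model.position + u * h
    ba = B - A
    oa = -A
    baba = ba @ ba
    bard = dirs @ ba
    baoa = ba @ oa
    rdoa = dirs @ oa
    oaoa = oa @ oa
    dd = np.einsum("ij,ij->i", dirs, dirs)
    a = baba * dd - bard**2
    b = baba * rdoa - baoa * bard
    c = baba * oaoa - baoa**2 - r * r * baba
    t = np.full(dirs.shape[0], np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = b * b - a * c
        ok = (disc >= 0) & (a > 1e-12)
        tb = np.where(ok, (-b - np.sqrt(np.maximum(disc, 0.0))) / np.where(ok, a, 1.0), np.inf)
        y = baoa + tb * bard
        body = ok & (tb > 0) & (y >= 0) & (y <= baba)
    t[body] = tb[body]
    # union with the two cap spheres: first entry into any of the solids
    t = np.minimum(t, _ray_sphere_entry(A, r, dirs))
    t = np.minimum(t, _ray_sphere_entry(B, r, dirs))
    return t


def _object_depth(model: VegetableModel, dirs: np.ndarray) -> np.ndarray:
    if model.shape == "ellipsoid":
        return _ray_ellipsoid_depth(model, dirs)
    return _ray_capsule_depth(model, dirs)


def _leafy_background(shape, rng: np.random.Generator, n_leaves: int, n_shadows: int) -> np.ndarray:
    """Procedural leafy backdrop: green base + leaf blobs + dark shadows."""
    H, W = shape
    img = np.empty((H, W, 3), float)
    base = np.array([55.0, 125.0, 55.0])
    img[:] = base
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    for dark, count, rmin, rmax in ((False, n_leaves, 15, 40), (True, n_shadows, 8, 30)):
        for _ in range(count):
            cx, cy = rng.uniform(0, W), rng.uniform(0, H)
            a, bsz = rng.uniform(rmin, rmax, size=2)
            th = rng.uniform(0, np.pi)
            ct, st = np.cos(th), np.sin(th)
            xr = (xs - cx) * ct + (ys - cy) * st
            yr = -(xs - cx) * st + (ys - cy) * ct
            m = (xr / a) ** 2 + (yr / bsz) ** 2 < 1.0
            if dark:
                col = rng.uniform((18, 32, 18), (42, 62, 42))
            else:
                col = rng.uniform((30, 90, 30), (60, 125, 60))
            img[m] = col
    img += rng.normal(0.0, 5.0, size=img.shape)
    return img.clip(0, 255)


def render(spec: SceneSpec) -> RenderedScene:
    """Ray-cast the scene into a colour image, a depth map and ground truth.

    Depth is the Z coordinate of the nearest surface along each pixel ray;
    the background sits on a far plane.  Per object, the silhouette pixels
    in its ``hole_width_px`` leftmost silhouette columns are zeroed to mimic
    stereo occlusion, and Gaussian depth noise is added to valid pixels.
    """
    cam = spec.camera
    H, W = cam.height_px, cam.width_px
    proj = PinholeProjection.from_intrinsics(cam)
    rng = np.random.default_rng(spec.seed)

    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    dirs = np.column_stack(
        [
            ((xs - proj.cx) / proj.fx).ravel(),
            ((ys - proj.cy) / proj.fy).ravel(),
            np.ones(H * W),
        ]
    )

    depth = np.full(H * W, spec.background_depth_mm)
    owner = np.full(H * W, -1)
    masks: list[np.ndarray] = []
    for i, obj in enumerate(spec.objects):
        if obj.position[2] <= 0:
            raise RenderError(f"object {i} is behind the camera")
        t = _object_depth(obj, dirs)
        nearer = t < depth
        depth = np.where(nearer, t, depth)
        owner = np.where(nearer, i, owner)
        masks.append(t < np.inf)
    for i in range(len(spec.objects)):
        for j in range(i + 1, len(spec.objects)):
            if np.any(masks[i] & masks[j]):
                warnings.warn(
                    f"objects {i} and {j} overlap in projection; occlusion "
                    "between vegetables is not modelled",
                    stacklevel=2,
                )

    color = _leafy_background((H, W), rng, spec.n_leaves, spec.n_shadow_blobs)
    flat = color.reshape(-1, 3)
    for i, obj in enumerate(spec.objects):
        sel = owner == i
        flat[sel] = np.array(CLASS_COLORS[obj.class_label], float) + rng.normal(
            0.0, 2.0, size=(int(sel.sum()), 3)
        )
    color = flat.reshape(H, W, 3).clip(0, 255).astype(np.uint8)

    depth = depth.reshape(H, W)
    owner = owner.reshape(H, W)
    if spec.noise.depth_noise_mm > 0:
        depth = np.maximum(depth + rng.normal(0.0, spec.noise.depth_noise_mm, depth.shape), 1.0)

    # stereo-occlusion holes: the w leftmost silhouette columns of each object
    w_hole = spec.noise.hole_width_px
    if w_hole > 0:
        for i in range(len(spec.objects)):
            m = (owner == i)
            cols = np.nonzero(m.any(axis=0))[0]
            if cols.size:
                kill = m & (np.arange(W)[None, :] < cols[0] + w_hole)
                depth[kill] = 0.0

    dets = [ground_truth_detection(obj, cam) for obj in spec.objects]
    return RenderedScene(
        color=color,
        depth=DepthMap(depth),
        detections=dets,
        spec=spec,
        masks=[m.reshape(H, W) for m in masks],
    )


def render_depth_frame(spec: SceneSpec) -> DepthMap:
    """Ray-cast the scene's depth from the second (depth) camera.

    ``spec.depth_camera`` holds the depth camera's pixel intrinsics and the
    depth->colour rigid transform; objects are moved into the depth frame
    and cast with the same geometry, giving the oracle for alignment tests.
    """
    if spec.depth_camera is None:
        raise InvalidInputError("scene spec has no depth camera")
    proj, T = spec.depth_camera
    cam = spec.camera
    H, W = cam.height_px, cam.width_px
    Rinv = T.rotation.T
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    dirs = np.column_stack(
        [
            ((xs - proj.cx) / proj.fx).ravel(),
            ((ys - proj.cy) / proj.fy).ravel(),
            np.ones(H * W),
        ]
    )
    depth = np.full(H * W, spec.background_depth_mm)
    for obj in spec.objects:
        moved = replace(
            obj,
            position=Rinv @ (obj.position - T.translation),
            axis=Rinv @ obj.axis,
        )
        t = _object_depth(moved, dirs)
        depth = np.minimum(depth, t)
    return DepthMap(depth.reshape(H, W))


# ---------------------------------------------------------------------------
# detector emulation


def detection_score(box_area: float, area_ref: float = DEFAULT_SCORE_AREA) -> float:
    """Monotone confidence model: s(a) = min(1, a / area_ref)."""
    return float(min(1.0, max(box_area, 0.0) / area_ref))


def perturb_detection(
    gt: Detection,
    noise: NoiseSpec,
    rng: np.random.Generator | int,
    area_ref: float = DEFAULT_SCORE_AREA,
) -> Detection:
    """Jitter a ground-truth detection into a realistic one.

    Keypoints and box corners receive i.i.d. Gaussian pixel noise; the score
    becomes the area-monotone confidence, so far/small objects drop below
    the detector contract threshold.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s = noise.keypoint_jitter_px
    arr = gt.keypoints.as_array()
    arr[:, :2] += rng.normal(0.0, s, size=(6, 2)) if s > 0 else 0.0
    x0, y0, x1, y1 = gt.box
    if s > 0:
        jx0, jy0, jx1, jy1 = rng.normal(0.0, s, size=4)
        x0, y0, x1, y1 = x0 + jx0, y0 + jy0, x1 + jx1, y1 + jy1
        x0, x1 = min(x0, x1), max(x0, x1)
        y0, y1 = min(y0, y1), max(y0, y1)
    return replace(
        gt,
        keypoints=KeypointSet.from_array(arr),
        box=(x0, y0, x1, y1),
        score=detection_score((x1 - x0) * (y1 - y0), area_ref),
    )


def mask_principal_frame(mask: np.ndarray, elongation_threshold: float = 1.35):
    """Centroid and object-axis frame of a binary silhouette.

    Returns ``(centroid_xy, u, v)`` with ``u`` the object axis oriented
    upward in the image (negative y) and ``v = perp(u)`` oriented rightward.
    For clearly elongated silhouettes the axis is the PCA major axis; for
    near-round ones (elongation below the threshold — oblate tomatoes are
    *wider* than long, so their major image axis is the diameter) the axis
    is the principal direction closer to vertical, matching how fruit hang
    within +/-45 degrees of upright.
    """
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise InvalidInputError("empty mask")
    c = np.array([xs.mean(), ys.mean()])
    pts = np.column_stack([xs - c[0], ys - c[1]]).astype(float)
    cov = pts.T @ pts / max(xs.size, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    elongation = np.sqrt(max(evals[0], 1e-12) / max(evals[1], 1e-12))
    if elongation >= elongation_threshold:
        u = evecs[:, 0]
    else:
        u = evecs[:, int(np.argmin(np.abs(evecs[0, :])))]  # closer to vertical
    if u[1] > 0:
        u = -u
    v = np.array([-u[1], u[0]])
    if v[0] < 0:
        v = -v
    return c, u, v


def _edge_point(c, e, e_perp, q, s, extreme: str) -> PixelPoint:
    """Sub-silhouette keypoint: among pixels within 1 px of the extreme
    coordinate along ``e``, place the point at the extreme with the mean
    transverse coordinate (centres the chord endpoint)."""
    qx = q.max() if extreme == "max" else q.min()
    sel = np.abs(q - qx) < 1.0
    p = c + e * qx + e_perp * s[sel].mean()
    return PixelPoint(float(p[0]), float(p[1]))


def keypoints_from_mask(mask: np.ndarray) -> KeypointSet:
    """Geometric keypoints of a silhouette: axis endpoints, widest chord
    endpoints, centroid, and an extrapolated peduncle."""
    c, u, v = mask_principal_frame(mask)
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs - c[0], ys - c[1]]).astype(float)
    t = pts @ u
    s = pts @ v
    top = _edge_point(c, u, v, t, s, "max")  # u points up (negative y)
    bottom = _edge_point(c, u, v, t, s, "min")
    right = _edge_point(c, v, u, s, t, "max")
    left = _edge_point(c, v, u, s, t, "min")
    span = t.max() - t.min()
    ped = c + u * (t.max() + 0.08 * span)
    return KeypointSet(
        peduncle=PixelPoint(float(ped[0]), float(ped[1])),
        top=top,
        left=left,
        bottom=bottom,
        right=right,
        center=PixelPoint(float(c[0]), float(c[1])),
    )


def make_color_detector(
    seed: int = 0,
    jitter_px: float = 0.0,
    area_ref: float = DEFAULT_SCORE_AREA,
    threshold: float = SCORE_THRESHOLD,
    color_tol: float = 25.0,
    min_area_px: int = 60,
):
    """Build an image-based detector for synthetic scenes.

    Segments each class's flat silhouette colour, extracts geometric
    keypoints from the connected components, scores by on-image box area
    and filters at the contract threshold.  Deterministic for a fixed image
    and seed (the jitter stream is derived from the image content), so it
    satisfies the detector contract and can drive the zoom-in loop: zoomed
    objects cover more pixels, score higher, and survive the threshold.
    """
    from scipy import ndimage

    palette = {k: np.array(vals, float) for k, vals in CLASS_COLORS.items()}

    def detector(image: np.ndarray) -> list[Detection]:
        img = np.asarray(image, dtype=float)
        rng = np.random.default_rng(
            [seed, int(img.sum()) % (2**31 - 1), img.shape[0], img.shape[1]]
        )
        out: list[Detection] = []
        for label, col in palette.items():
            dist = np.linalg.norm(img - col, axis=-1)
            lab, n = ndimage.label(dist < color_tol)
            if n == 0:
                continue
            counts = np.bincount(lab.ravel())
            slices = ndimage.find_objects(lab)
            for comp in range(1, n + 1):
                if counts[comp] < min_area_px:
                    continue
                sl = slices[comp - 1]
                m = np.zeros(lab.shape, bool)
                m[sl] = lab[sl] == comp
                kp = keypoints_from_mask(m)
                if jitter_px > 0:
                    arr = kp.as_array()
                    arr[:, :2] += rng.normal(0.0, jitter_px, size=(6, 2))
                    kp = KeypointSet.from_array(arr)
                ys, xs = np.nonzero(m)
                box = (float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max()))
                score = detection_score((box[2] - box[0]) * (box[3] - box[1]), area_ref)
                if score >= threshold:
                    out.append(Detection(label, score, box, kp))
        return out

    return detector


#: Named detector factories for config plumbing.  "synthetic-oracle" is the
#: noiseless colour-silhouette detector; "noisy-synthetic" adds 1 px jitter.
DETECTOR_FACTORIES = {
    "synthetic-oracle": lambda seed=0: make_color_detector(seed=seed, jitter_px=0.0),
    "noisy-synthetic": lambda seed=0: make_color_detector(seed=seed, jitter_px=1.0),
}
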