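"""Reader/writer/validator for the six-keypoint COCO annotation dialect.

The dataset dialect: four vegetable categories, each object annotated with
an ROI box and exactly six keypoints in the fixed order
``[peduncle, top, left, bottom, right, center]`` (18 numbers per object as
``x, y, v`` triples).  Visibility follows the COCO convention: 0 = not
labeled, 1 = labeled but occluded, 2 = labeled and visible.  Coordinates
are continuous 0-based pixel positions.

Serialisation is deterministic (sorted keys, fixed indentation) so written
files are diffable; the skeleton edges exist for visualisation only and are
never used in computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import SchemaError
from .geometry import KEYPOINT_NAMES, KeypointSet
from .zoomin import CLASS_LABELS

__all__ = [
    "AnnotationRecord",
    "SKELETON",
    "read_coco",
    "write_coco",
    "validate",
    "records_from_scene",
    "split_train_test",
]

#: Visualisation-only skeleton over 1-based keypoint indices:
#: top-center, center-bottom, left-right, peduncle-top.
SKELETON = [[2, 6], [6, 4], [3, 5], [1, 2]]

_CATEGORY_IDS = {name: i + 1 for i, name in enumerate(CLASS_LABELS)}
_CATEGORY_NAMES = {v: k for k, v in _CATEGORY_IDS.items()}


@dataclass
class AnnotationRecord:
    """One annotated object on one image."""

    image_id: int
    image_width: int
    image_height: int
    category: str
    bbox: tuple[float, float, float, float]  # x, y, w, h (px)
    keypoints: KeypointSet
    annotation_id: int = 0
    file_name: str = ""

    def __post_init__(self) -> None:
        if self.category not in CLASS_LABELS:
            raise SchemaError(f"unknown category {self.category!r}", self.annotation_id)
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise SchemaError(f"box must have positive extent, got {self.bbox!r}", self.annotation_id)

    def issues(self) -> list[str]:
        """Dialect violations that are flaggable rather than fatal."""
        out = []
        for name, p in self.keypoints.items():
            v = self.keypoints.visibility.get(name, 0)
            if v == 2 and not (0 <= p.x <= self.image_width - 1 and 0 <= p.y <= self.image_height - 1):
                out.append(f"visible keypoint {name!r} at ({p.x:.1f}, {p.y:.1f}) outside image bounds")
        if not self.keypoints.is_orientation_consistent():
            out.append("left keypoint lies right of the right keypoint")
        return out


def _categories_block() -> list[dict]:
    return [
        {
            "id": cid,
            "name": name,
            "supercategory": "vegetable",
            "keypoints": list(KEYPOINT_NAMES),
            "skeleton": SKELETON,
        }
        for name, cid in _CATEGORY_IDS.items()
    ]


def write_coco(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Write records as a standard COCO keypoints JSON file."""
    images: dict[int, dict] = {}
    annotations = []
    for rec in records:
        images.setdefault(
            rec.image_id,
            {
                "id": rec.image_id,
                "width": rec.image_width,
                "height": rec.image_height,
                "file_name": rec.file_name or f"image_{rec.image_id:06d}.png",
            },
        )
        arr = rec.keypoints.as_array()
        kps: list[float] = []
        for x, y, v in arr:
            kps.extend([float(x), float(y), int(v)])
        x, y, w, h = rec.bbox
        annotations.append(
            {
                "id": rec.annotation_id,
                "image_id": rec.image_id,
                "category_id": _CATEGORY_IDS[rec.category],
                "bbox": [float(x), float(y), float(w), float(h)],
                "area": float(w * h),
                "iscrowd": 0,
                "num_keypoints": int(np.count_nonzero(arr[:, 2] > 0)),
                "keypoints": kps,
            }
        )
    doc = {
        "images": sorted(images.values(), key=lambda d: d["id"]),
        "annotations": annotations,
        "categories": _categories_block(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_coco(path: str | Path) -> list[AnnotationRecord]:
    """Read and validate a COCO keypoints file against the dialect.

    Raises :class:`SchemaError` naming the offending record on a wrong
    keypoint count, unknown category, or malformed JSON.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "annotations" not in doc or "images" not in doc:
        raise SchemaError("missing top-level 'images'/'annotations' blocks")
    images = {img["id"]: img for img in doc["images"]}
    cat_names = dict(_CATEGORY_NAMES)
    for cat in doc.get("categories", []):
        if cat.get("keypoints") and list(cat["keypoints"]) != list(KEYPOINT_NAMES):
            raise SchemaError(
                f"category {cat.get('name')!r} declares keypoints {cat.get('keypoints')!r}; "
                f"the dialect requires {list(KEYPOINT_NAMES)}"
            )
        cat_names[cat["id"]] = cat["name"]
    records = []
    for ann in doc["annotations"]:
        aid = ann.get("id", "?")
        kps = ann.get("keypoints", [])
        if len(kps) != 18:
            raise SchemaError(
                f"expected 18 keypoint numbers (6 x [x, y, v]), got {len(kps)}", aid
            )
        cat = cat_names.get(ann.get("category_id"))
        if cat not in CLASS_LABELS:
            raise SchemaError(f"unknown category id {ann.get('category_id')!r}", aid)
        img = images.get(ann.get("image_id"))
        if img is None:
            raise SchemaError(f"annotation references missing image {ann.get('image_id')!r}", aid)
        vs = [int(v) for v in kps[2::3]]
        if any(v not in (0, 1, 2) for v in vs):
            raise SchemaError(f"visibility flags must be in {{0,1,2}}, got {vs}", aid)
        kp = KeypointSet.from_array(np.array(kps, dtype=float).reshape(6, 3))
        records.append(
            AnnotationRecord(
                image_id=img["id"],
                image_width=img["width"],
                image_height=img["height"],
                category=cat,
                bbox=tuple(float(b) for b in ann["bbox"]),
                keypoints=kp,
                annotation_id=ann.get("id", 0),
                file_name=img.get("file_name", ""),
            )
        )
    return records


@dataclass
class ValidationReport:
    total: int
    passed: int
    per_category: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)  # (annotation_id, reasons)

    @property
    def all_passed(self) -> bool:
        return self.passed == self.total


def validate(path: str | Path) -> ValidationReport:
    """Per-record pass/fail report; never raises on flaggable issues."""
    records = read_coco(path)
    failures = []
    per_cat: dict[str, int] = {}
    for rec in records:
        per_cat[rec.category] = per_cat.get(rec.category, 0) + 1
        issues = rec.issues()
        if issues:
            failures.append((rec.annotation_id, issues))
    return ValidationReport(
        total=len(records),
        passed=len(records) - len(failures),
        per_category=per_cat,
        failures=failures,
    )


def records_from_scene(scene, image_id: int = 1, file_name: str = "") -> list[AnnotationRecord]:
    """Convert a rendered synthetic scene's ground truth to annotations."""
    cam = scene.spec.camera
    out = []
    for i, det in enumerate(scene.detections):
        x0, y0, x1, y1 = det.box
        out.append(
            AnnotationRecord(
                image_id=image_id,
                image_width=cam.width_px,
                image_height=cam.height_px,
                category=det.class_label,
                bbox=(x0, y0, x1 - x0, y1 - y0),
                keypoints=det.keypoints,
                annotation_id=i + 1,
                file_name=file_name,
            )
        )
    return out


def split_train_test(
    records: Sequence[AnnotationRecord], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Seeded per-category split of *images* into train/test sets (the
    conventional 320/80-per-category layout at the default fraction)."""
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[int]] = {}
    for rec in records:
        by_cat.setdefault(rec.category, [])
        if rec.image_id not in by_cat[rec.category]:
            by_cat[rec.category].append(rec.image_id)
    train_ids: set[int] = set()
    for ids in by_cat.values():
        ids = sorted(ids)
        rng.shuffle(ids)
        k = int(round(train_fraction * len(ids)))
        train_ids.update(ids[:k])
    train = [r for r in records if r.image_id in train_ids]
    test = [r for r in records if r.image_id not in train_ids]
    return train, test
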