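"""COCO-dialect instance-segmentation dataset I/O and mask conversions.

Conventions used throughout the package (stated once here):

* Coordinates are 0-based with origin at the top-left; boxes are
  ``[x, y, w, h]`` half-open in pixel units.
* Polygon segmentations are lists of flat ``[x0, y0, x1, y1, ...]`` vertex
  sequences; a pixel belongs to the mask iff its *center* lies inside any
  polygon under the even-odd rule.
* Run-length encodings are uncompressed COCO RLE: column-major scan,
  ``counts`` alternating runs starting with the zero-run.
* ``iscrowd`` annotations are accepted and treated as ordinary instances
  (single-class leaf problem).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

__all__ = [
    "ImageRecord",
    "InstanceAnnotation",
    "Category",
    "DatasetBundle",
    "DatasetFormatError",
    "DatasetIntegrityError",
    "load_dataset",
    "save_dataset",
    "rasterize",
    "rasterize_polygons",
    "mask_to_rle",
    "rle_to_mask",
    "mask_to_bbox",
    "mask_area",
]


class DatasetFormatError(ValueError):
    """Malformed dataset payload (missing keys, bad polygons...)."""


class DatasetIntegrityError(ValueError):
    """Referential-integrity violation (dangling ids, duplicates...)."""


@dataclass
class ImageRecord:
    id: int
    file_name: str
    width: int
    height: int


@dataclass
class Category:
    id: int
    name: str


@dataclass
class InstanceAnnotation:
    """One instance: mask (polygons or RLE), box, area, optional score."""

    id: int
    image_id: int
    category_id: int
    segmentation: list | dict
    bbox: list[float]
    area: float
    score: float | None = None
    iscrowd: int = 0

    def has_polygons(self) -> bool:
        return isinstance(self.segmentation, list)


@dataclass
class DatasetBundle:
    """A full dataset: records, annotations, categories and (optionally)
    decoded pixel arrays keyed by image id."""

    images: list[ImageRecord] = field(default_factory=list)
    annotations: list[InstanceAnnotation] = field(default_factory=list)
    categories: list[Category] = field(default_factory=list)
    pixels: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def image_by_id(self, image_id: int) -> ImageRecord:
        for rec in self.images:
            if rec.id == image_id:
                return rec
        raise KeyError(image_id)

    def annotations_for(self, image_id: int) -> list[InstanceAnnotation]:
        return [a for a in self.annotations if a.image_id == image_id]

    def validate(self) -> None:
        img_ids = [r.id for r in self.images]
        if len(set(img_ids)) != len(img_ids):
            dupes = sorted({i for i in img_ids if img_ids.count(i) > 1})
            raise DatasetIntegrityError(f"duplicate image ids: {dupes}")
        ann_ids = [a.id for a in self.annotations]
        if len(set(ann_ids)) != len(ann_ids):
            dupes = sorted({i for i in ann_ids if ann_ids.count(i) > 1})
            raise DatasetIntegrityError(f"duplicate annotation ids: {dupes}")
        img_set, cat_set = set(img_ids), {c.id for c in self.categories}
        for a in self.annotations:
            if a.image_id not in img_set:
                raise DatasetIntegrityError(
                    f"annotation {a.id} references missing image id {a.image_id}"
                )
            if cat_set and a.category_id not in cat_set:
                raise DatasetIntegrityError(
                    f"annotation {a.id} references missing category id {a.category_id}"
                )

    def copy(self) -> "DatasetBundle":
        return DatasetBundle(
            images=[replace(r) for r in self.images],
            annotations=[replace(a) for a in self.annotations],
            categories=[replace(c) for c in self.categories],
            pixels={k: v.copy() for k, v in self.pixels.items()},
        )


# ---------------------------------------------------------------------------
# mask primitives


def rasterize_polygons(polygons: list[list[float]], height: int, width: int) -> np.ndarray:
    """Rasterize flat-coordinate polygons by pixel-center even-odd containment.

    A pixel at (row r, col c) has its center at continuous coordinates
    (x = c + 0.5, y = r + 0.5); it is set iff the center is inside any of
    the polygons (crossing-number test, counted per polygon).
    """
    mask = np.zeros((height, width), dtype=bool)
    if not polygons:
        return mask
    cx = np.arange(width, dtype=np.float64) + 0.5
    cy = np.arange(height, dtype=np.float64) + 0.5
    px = np.broadcast_to(cx, (height, width))
    py = np.broadcast_to(cy[:, None], (height, width))
    for poly in polygons:
        poly = np.asarray(poly, dtype=np.float64)
        if poly.size < 6 or poly.size % 2:
            raise DatasetFormatError(
                f"polygon needs >= 3 (x, y) vertices, got {poly.size / 2:g}"
            )
        xs, ys = poly[0::2], poly[1::2]
        inside = np.zeros((height, width), dtype=bool)
        n = len(xs)
        for i in range(n):
            x1, y1 = xs[i], ys[i]
            x2, y2 = xs[(i + 1) % n], ys[(i + 1) % n]
            if y1 == y2:
                continue
            crosses = (y1 > py) != (y2 > py)
            with np.errstate(invalid="ignore"):
                xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (px < xint)
        mask |= inside
    return mask


def rle_to_mask(rle: dict) -> np.ndarray:
    """Decode uncompressed column-major COCO RLE to a boolean H×W mask."""
    h, w = rle["size"]
    counts = np.asarray(rle["counts"], dtype=np.int64)
    if counts.sum() != h * w:
        raise DatasetFormatError(
            f"RLE counts sum to {counts.sum()}, expected {h * w}"
        )
    vals = np.zeros(len(counts), dtype=bool)
    vals[1::2] = True
    flat = np.repeat(vals, counts)
    return flat.reshape((w, h)).T  # column-major


def mask_to_rle(mask: np.ndarray) -> dict:
    """Encode a boolean mask as uncompressed column-major COCO RLE."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.T.reshape(-1)
    if flat.size == 0:
        return {"size": [h, w], "counts": []}
    changes = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat[0]:  # RLE starts with the zero-run
        counts = [0] + counts
    return {"size": [int(h), int(w)], "counts": [int(c) for c in counts]}


def rasterize(ann: InstanceAnnotation, height: int, width: int) -> np.ndarray:
    """Decode an annotation's segmentation (polygons or RLE) to a mask."""
    if isinstance(ann.segmentation, dict):
        return rle_to_mask(ann.segmentation)
    return rasterize_polygons(ann.segmentation, height, width)


def mask_to_bbox(mask: np.ndarray) -> list[int]:
    """Tight axis-aligned [x, y, w, h] hull; [0, 0, 0, 0] for empty masks."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return [0, 0, 0, 0]
    y0, y1 = int(rows[0]), int(rows[-1]) + 1
    x0, x1 = int(cols[0]), int(cols[-1]) + 1
    return [x0, y0, x1 - x0, y1 - y0]


def mask_area(mask: np.ndarray) -> int:
    """Number of true pixels."""
    return int(np.asarray(mask, dtype=bool).sum())


# ---------------------------------------------------------------------------
# dataset JSON I/O


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise DatasetFormatError(f"missing key {key!r} in {where}")
    return d[key]


def load_dataset(
    json_path: str | Path, image_root: str | Path | None = None
) -> DatasetBundle:
    """Load a COCO-dialect dataset and (if ``image_root`` given) its pixels.

    Validates referential integrity; violations raise
    :class:`DatasetIntegrityError` naming the offending ids.
    """
    json_path = Path(json_path)
    with open(json_path) as fh:
        payload = json.load(fh)
    for key in ("images", "annotations", "categories"):
        _require(payload, key, str(json_path))
    images = [
        ImageRecord(
            id=int(_require(r, "id", "image record")),
            file_name=str(_require(r, "file_name", "image record")),
            width=int(_require(r, "width", "image record")),
            height=int(_require(r, "height", "image record")),
        )
        for r in payload["images"]
    ]
    annotations = []
    for a in payload["annotations"]:
        annotations.append(
            InstanceAnnotation(
                id=int(_require(a, "id", "annotation")),
                image_id=int(_require(a, "image_id", "annotation")),
                category_id=int(_require(a, "category_id", "annotation")),
                segmentation=_require(a, "segmentation", "annotation"),
                bbox=[float(v) for v in _require(a, "bbox", "annotation")],
                area=float(_require(a, "area", "annotation")),
                score=float(a["score"]) if "score" in a else None,
                iscrowd=int(a.get("iscrowd", 0)),
            )
        )
    categories = [
        Category(id=int(c["id"]), name=str(c.get("name", ""))) for c in payload["categories"]
    ]
    bundle = DatasetBundle(images=images, annotations=annotations, categories=categories)
    bundle.validate()
    if image_root is not None:
        root = Path(image_root)
        for rec in bundle.images:
            path = root / rec.file_name
            if path.exists():
                arr = np.asarray(PILImage.open(path).convert("RGB"))
                if arr.shape[:2] != (rec.height, rec.width):
                    raise DatasetIntegrityError(
                        f"image {rec.id}: file {rec.file_name} is "
                        f"{arr.shape[1]}x{arr.shape[0]}, record says "
                        f"{rec.width}x{rec.height}"
                    )
                bundle.pixels[rec.id] = arr
    return bundle


def save_dataset(
    bundle: DatasetBundle, json_path: str | Path, image_root: str | Path | None = None
) -> None:
    """Write the dataset JSON and (when pixels are present) PNG image files."""
    bundle.validate()
    payload = {
        "images": [
            {"id": r.id, "file_name": r.file_name, "width": r.width, "height": r.height}
            for r in bundle.images
        ],
        "annotations": [
            {
                "id": a.id,
                "image_id": a.image_id,
                "category_id": a.category_id,
                "segmentation": a.segmentation,
                "bbox": list(a.bbox),
                "area": a.area,
                "iscrowd": a.iscrowd,
                **({"score": a.score} if a.score is not None else {}),
            }
            for a in bundle.annotations
        ],
        "categories": [{"id": c.id, "name": c.name} for c in bundle.categories],
    }
    json_path = Path(json_path)
    json_path.parent.mkdir(parents=True, exist_ok=True)
    with open(json_path, "w") as fh:
        json.dump(payload, fh)
    if image_root is not None and bundle.pixels:
        root = Path(image_root)
        root.mkdir(parents=True, exist_ok=True)
        for rec in bundle.images:
            if rec.id in bundle.pixels:
                PILImage.fromarray(bundle.pixels[rec.id]).save(root / rec.file_name)
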