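"""Annotation-consistent data augmentation (online and offline).

Photometric operations (Gaussian blur, brightness/contrast, pixel dropout)
change pixels only; geometric operations (horizontal flip, rotation)
transform the image *and* every polygon / mask / box consistently, with
masks re-derived from the transformed geometry and areas recomputed.

Two deployment modes mirror common training practice:

* **online** — random ops applied per image as it is drawn during
  training (exposed as a seeded iterator);
* **offline** — the whole dataset is expanded up front with ``n_copies``
  augmented variants per image under fresh ids.

Default magnitudes (brightness/contrast ±25%, dropout ≤2%, rotation ±15°)
are package defaults, configurable per op.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.ndimage import rotate as nd_rotate

from .dataset_io import (
    DatasetBundle,
    InstanceAnnotation,
    mask_area,
    mask_to_bbox,
    mask_to_rle,
    rasterize,
)
from .filters import glpf

__all__ = ["AugmentSpec", "apply_augment", "expand_offline", "online_iter", "SUPPORTED_OPS"]

SUPPORTED_OPS = (
    "horizontal_flip",
    "gaussian_blur",
    "brightness_contrast",
    "pixel_dropout",
    "rotation",
    "random_combo",
)

_DEFAULT_PARAMS = {
    "gaussian_blur": {"size_choices": (3, 5), "sigma_range": (0.5, 1.5)},
    "brightness_contrast": {"brightness_range": (-0.25, 0.25), "contrast_range": (-0.25, 0.25)},
    "pixel_dropout": {"fraction_range": (0.0, 0.02)},
    "rotation": {"angle_range": (-15.0, 15.0)},
}


@dataclass(frozen=True)
class AugmentSpec:
    """Ordered augmentation recipe.

    ``ops`` are drawn from :data:`SUPPORTED_OPS`; ``params`` overrides the
    per-op parameter ranges; ``probability`` is the chance each listed op
    fires (1.0 = always).
    """

    mode: str = "offline"  # online | offline
    ops: tuple[str, ...] = ("horizontal_flip", "brightness_contrast")
    params: dict = field(default_factory=dict)
    probability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("online", "offline"):
            raise ValueError(f"mode must be 'online' or 'offline', got {self.mode!r}")
        for op in self.ops:
            if op not in SUPPORTED_OPS:
                raise ValueError(f"unsupported augmentation op {op!r}")
        rot = self.op_params("rotation")
        lo, hi = rot["angle_range"]
        if not (-180 < lo <= hi <= 180):
            raise ValueError("rotation angle range must lie in (-180, 180]")
        fr = self.op_params("pixel_dropout")["fraction_range"]
        if not (0 <= fr[0] <= fr[1] < 1):
            raise ValueError("dropout fraction range must lie in [0, 1)")

    def op_params(self, op: str) -> dict:
        merged = dict(_DEFAULT_PARAMS.get(op, {}))
        merged.update(self.params.get(op, {}))
        return merged


# ---------------------------------------------------------------------------
# individual ops


def _flip_annotation(ann: InstanceAnnotation, height: int, width: int) -> InstanceAnnotation:
    if ann.has_polygons():
        seg = []
        for poly in ann.segmentation:
            p = np.asarray(poly, dtype=np.float64).copy()
            p[0::2] = width - p[0::2]  # mirror about the image's vertical midline
            seg.append(p.tolist())
        mask = None
    else:
        mask = rasterize(ann, height, width)[:, ::-1]
        seg = mask_to_rle(mask)
    if mask is None:
        mask = rasterize(replace(ann, segmentation=seg), height, width)
    return replace(
        ann,
        segmentation=seg,
        bbox=[float(v) for v in mask_to_bbox(mask)],
        area=float(mask_area(mask)),
    )


def _rotate_annotation(
    ann: InstanceAnnotation, angle: float, height: int, width: int
) -> InstanceAnnotation:
    cy, cx = (height - 1) / 2.0 + 0.5, (width - 1) / 2.0 + 0.5
    if ann.has_polygons():
        # rotate vertices about the image center (image-frame rotation is
        # clockwise-positive to match the raster rotation below)
        t = np.deg2rad(angle)
        c, s = np.cos(t), np.sin(t)
        seg = []
        for poly in ann.segmentation:
            p = np.asarray(poly, dtype=np.float64).reshape(-1, 2)
            dx, dy = p[:, 0] - cx, p[:, 1] - cy
            p[:, 0] = cx + c * dx - s * dy
            p[:, 1] = cy + s * dx + c * dy
            seg.append(p.reshape(-1).tolist())
        mask = rasterize(replace(ann, segmentation=seg), height, width)
    else:
        m = rasterize(ann, height, width)
        mask = nd_rotate(
            m, -angle, reshape=False, order=0, mode="constant", cval=False
        ).astype(bool)
        seg = mask_to_rle(mask)
    return replace(
        ann,
        segmentation=seg,
        bbox=[float(v) for v in mask_to_bbox(mask)],
        area=float(mask_area(mask)),
    )


def apply_augment(
    img: np.ndarray,
    annotations: list[InstanceAnnotation],
    spec: AugmentSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[InstanceAnnotation]]:
    """Apply the spec's ops in order; returns new image + new annotations."""
    out = np.asarray(img).astype(np.uint8, copy=True)
    anns = [replace(a) for a in annotations]
    h, w = out.shape[:2]
    for op in spec.ops:
        if spec.probability < 1.0 and rng.random() >= spec.probability:
            continue
        if op == "random_combo":
            pool = [o for o in SUPPORTED_OPS if o != "random_combo"]
            chosen = [o for o in pool if rng.random() < 0.5]
            sub = replace(spec, ops=tuple(chosen), probability=1.0)
            out, anns = apply_augment(out, anns, sub, rng)
            h, w = out.shape[:2]
            continue
        if op == "horizontal_flip":
            out = out[:, ::-1].copy()
            anns = [_flip_annotation(a, h, w) for a in anns]
        elif op == "gaussian_blur":
            p = spec.op_params(op)
            size = int(rng.choice(p["size_choices"]))
            sigma = float(rng.uniform(*p["sigma_range"]))
            out = glpf(out, size, sigma)
        elif op == "brightness_contrast":
            p = spec.op_params(op)
            b = rng.uniform(*p["brightness_range"]) * 255.0
            c = 1.0 + rng.uniform(*p["contrast_range"])
            out = np.clip(np.rint(c * (out.astype(np.float64) - 128.0) + 128.0 + b), 0, 255).astype(np.uint8)
        elif op == "pixel_dropout":
            p = spec.op_params(op)
            frac = float(rng.uniform(*p["fraction_range"]))
            if frac > 0:
                drop = rng.random((h, w)) < frac
                out[drop] = 0
        elif op == "rotation":
            p = spec.op_params(op)
            angle = float(rng.uniform(*p["angle_range"]))
            out = nd_rotate(out, -angle, reshape=False, order=1, mode="mirror")
            out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
            anns = [_rotate_annotation(a, angle, h, w) for a in anns]
            anns = [a for a in anns if a.area > 0]  # instances rotated fully out
        else:  # pragma: no cover - guarded by AugmentSpec validation
            raise ValueError(f"unsupported augmentation op {op!r}")
    return out, anns


def expand_offline(bundle: DatasetBundle, spec: AugmentSpec, n_copies: int) -> DatasetBundle:
    """Append ``n_copies`` augmented variants per image under fresh ids.

    Deterministic for a fixed ``spec.seed``; two runs produce bit-identical
    bundles.
    """
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    out = bundle.copy()
    if n_copies == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    next_img = max((r.id for r in bundle.images), default=0) + 1
    next_ann = max((a.id for a in bundle.annotations), default=0) + 1
    for rec in bundle.images:
        if rec.id not in bundle.pixels:
            raise ValueError(f"image {rec.id} has no pixel data loaded")
        for k in range(n_copies):
            img, anns = apply_augment(
                bundle.pixels[rec.id], bundle.annotations_for(rec.id), spec, rng
            )
            new_id = next_img
            next_img += 1
            stem, dot, ext = rec.file_name.rpartition(".")
            name = f"{stem}_aug{k}.{ext}" if dot else f"{rec.file_name}_aug{k}"
            out.images.append(replace(rec, id=new_id, file_name=name))
            out.pixels[new_id] = img
            for a in anns:
                out.annotations.append(replace(a, id=next_ann, image_id=new_id))
                next_ann += 1
    out.validate()
    return out


def online_iter(
    bundle: DatasetBundle, spec: AugmentSpec, seed: int | None = None
) -> Iterator[tuple[int, np.ndarray, list[InstanceAnnotation]]]:
    """Endless seeded stream of augmented (image_id, image, annotations)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    while True:
        for rec in bundle.images:
            img, anns = apply_augment(
                bundle.pixels[rec.id], bundle.annotations_for(rec.id), spec, rng
            )
            yield rec.id, img, anns
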