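"""Seeded generator of cluttered leaf scenes with exact ground truth.

Emulates the structure of a greenhouse leaf-instance dataset at desk
scale: each scene layers lobed-ellipse "leaves" of varying size over a
flat, noisy, or shape-cluttered background; later leaves occlude earlier
ones; a configurable fraction of leaves is pre-blurred in place (as camera
motion / focus would); annotations record the *visible* region of every
leaf (amodal completion is out of scope), encoded as run-length masks so
ground-truth areas are exact.  A ledger carries the true per-image counts
and areas, giving every downstream module an exact oracle.

A mock predictor perturbs the ground truth with controllable error
(instance drops, mask translation, erosion/dilation, spurious instances,
score noise) and, in blur-aware mode, gates each instance on the local
sharpness of the image so that blurring the data reduces the number of
predicted masks — the qualitative behavior of a detector facing defocused
instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, shift as nd_shift

from .dataset_io import (
    Category,
    DatasetBundle,
    ImageRecord,
    InstanceAnnotation,
    mask_area,
    mask_to_bbox,
    mask_to_rle,
    rasterize,
    rasterize_polygons,
)
from .evaluate import Prediction
from .filters import FilterType, FilterSpec
from .refine import refine_instance

__all__ = [
    "SceneConfig",
    "PerturbSpec",
    "SceneGenerationError",
    "generate_scenes",
    "mock_predict",
    "instance_sharpness",
]


class SceneGenerationError(RuntimeError):
    """Raised when leaf placement is infeasible after bounded retries."""


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one batch of synthetic scenes.

    Defaults give ~7 leaves per 160×160 scene over a cluttered background
    with moderate occlusion and a fifth of the leaves pre-blurred.
    """

    image_size: tuple[int, int] = (160, 160)  # (H, W)
    n_leaves: tuple[int, int] = (4, 10)  # inclusive range
    leaf_size: tuple[int, int] = (7, 18)  # semi-major axis range, pixels
    occlusion_probability: float = 0.3
    blur_fraction: float = 0.2
    background: str = "clutter"  # flat | noise | clutter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves[0] > self.n_leaves[1] or self.n_leaves[0] < 0:
            raise ValueError("n_leaves range must be non-empty and non-negative")
        if self.leaf_size[0] > self.leaf_size[1] or self.leaf_size[0] < 2:
            raise ValueError("leaf_size range must be non-empty with minimum >= 2")
        for name in ("occlusion_probability", "blur_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.background not in ("flat", "noise", "clutter"):
            raise ValueError(f"unknown background {self.background!r}")


@dataclass(frozen=True)
class PerturbSpec:
    """Controllable error model of the mock predictor.

    ``morph_pixels`` > 0 dilates each predicted mask, < 0 erodes it.
    With ``blur_sensitivity`` > 0 the predictor becomes deterministic in
    the image: an instance is emitted only when the mean gradient
    magnitude inside its mask is at least ``sharpness_threshold``, and its
    mask is additionally eroded in proportion to the sharpness deficit.
    """

    translation: int = 0
    morph_pixels: int = 0
    drop_probability: float = 0.0
    spurious_rate: float = 0.0
    tp_score_range: tuple[float, float] = (1.0, 1.0)
    spurious_score_range: tuple[float, float] = (0.1, 0.6)
    blur_sensitivity: float = 0.0
    sharpness_threshold: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_probability <= 1.0:
            raise ValueError("drop_probability must be in [0, 1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")


# ---------------------------------------------------------------------------
# scene drawing


def _leaf_polygon(rng: np.random.Generator, cy: float, cx: float, r_major: float):
    """Lobed ellipse: radius modulated by a low-order radial harmonic."""
    aspect = rng.uniform(0.55, 0.95)
    phi = rng.uniform(0, np.pi)
    k = int(rng.integers(3, 7))
    amp = rng.uniform(0.05, 0.22)
    phase = rng.uniform(0, 2 * np.pi)
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    rad = 1.0 + amp * np.sin(k * theta + phase)
    ex = r_major * rad * np.cos(theta)
    ey = r_major * aspect * rad * np.sin(theta)
    x = cx + ex * np.cos(phi) - ey * np.sin(phi)
    y = cy + ex * np.sin(phi) + ey * np.cos(phi)
    return np.stack([x, y], axis=1).reshape(-1).tolist()


def _background(rng: np.random.Generator, h: int, w: int, kind: str) -> np.ndarray:
    base = np.array([72, 58, 46], dtype=np.float64)  # soil-toned
    img = np.tile(base, (h, w, 1))
    if kind == "flat":
        pass
    elif kind == "noise":
        img = rng.uniform(20, 160, size=(h, w, 3))
    else:  # clutter-shapes: stems, pots, ground litter
        img += rng.normal(0, 6, size=(h, w, 3))
        for _ in range(int(rng.integers(6, 14))):
            color = rng.uniform(20, 200, size=3)
            if rng.random() < 0.5:  # rectangle (trellis / pot edge)
                y0 = int(rng.integers(0, h))
                x0 = int(rng.integers(0, w))
                hh = int(rng.integers(3, max(4, h // 3)))
                ww = int(rng.integers(3, max(4, w // 3)))
                img[y0 : y0 + hh, x0 : x0 + ww] = color
            else:  # ellipse blob
                cy, cx = rng.uniform(0, h), rng.uniform(0, w)
                ry, rx = rng.uniform(2, h / 5), rng.uniform(2, w / 5)
                yy, xx = np.mgrid[0:h, 0:w]
                blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1
                img[blob] = color
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _paint_leaf(
    img: np.ndarray, mask: np.ndarray, rng: np.random.Generator
) -> None:
    h, w = mask.shape
    color = np.array(
        [rng.uniform(20, 90), rng.uniform(90, 200), rng.uniform(20, 90)]
    )
    yy, xx = np.nonzero(mask)
    # gentle linear shading across the leaf + pixel noise for texture
    gdir = rng.uniform(-1, 1, size=2)
    ramp = (yy - yy.mean()) * gdir[0] + (xx - xx.mean()) * gdir[1]
    span = np.ptp(ramp)
    if span > 0:
        ramp = (ramp - ramp.min()) / span - 0.5
    shade = 1.0 + 0.35 * ramp
    vals = color[None, :] * shade[:, None] + rng.normal(0, 4, size=(len(yy), 3))
    img[yy, xx] = np.clip(np.rint(vals), 0, 255).astype(np.uint8)


_MAX_PLACEMENT_TRIES = 60


def generate_scenes(
    cfg: SceneConfig, n_images: int
) -> tuple[DatasetBundle, list[dict]]:
    """Generate ``n_images`` scenes; returns (bundle, ledger).

    The ledger has one dict per image: ``image_id``, ``leaf_count``,
    ``areas`` (visible pixel counts, annotation order) and ``blurred``
    flags.  Fully-occluded leaves are discarded.  Deterministic per
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    bundle = DatasetBundle(categories=[Category(id=1, name="leaf")])
    ledger: list[dict] = []
    ann_id = 1
    for idx in range(n_images):
        image_id = idx + 1
        img = _background(rng, h, w, cfg.background)
        n = int(rng.integers(cfg.n_leaves[0], cfg.n_leaves[1] + 1))
        full_masks: list[np.ndarray] = []
        for leaf_i in range(n):
            r = float(rng.uniform(cfg.leaf_size[0], cfg.leaf_size[1]))
            occlude = full_masks and rng.random() < cfg.occlusion_probability
            placed = False
            for _ in range(_MAX_PLACEMENT_TRIES):
                if occlude:
                    target = full_masks[int(rng.integers(len(full_masks)))]
                    ty, tx = np.nonzero(target)
                    j = int(rng.integers(len(ty)))
                    cy = ty[j] + rng.uniform(-r / 2, r / 2)
                    cx = tx[j] + rng.uniform(-r / 2, r / 2)
                else:
                    cy = rng.uniform(r, h - r) if h > 2 * r else h / 2
                    cx = rng.uniform(r, w - r) if w > 2 * r else w / 2
                poly = _leaf_polygon(rng, cy, cx, r)
                mask = rasterize_polygons([poly], h, w)
                if mask_area(mask) < 12:
                    continue
                overlaps = any(np.logical_and(mask, m).any() for m in full_masks)
                if occlude or not overlaps:
                    full_masks.append(mask)
                    placed = True
                    break
            if not placed:
                raise SceneGenerationError(
                    f"could not place leaf {leaf_i + 1}/{n} in image {image_id} "
                    f"after {_MAX_PLACEMENT_TRIES} tries"
                )
        # later leaves occlude earlier ones: owner map gives disjoint visible masks
        owner = np.full((h, w), -1, dtype=np.int32)
        for i, m in enumerate(full_masks):
            owner[m] = i
        entry = {"image_id": image_id, "leaf_count": 0, "areas": [], "blurred": []}
        visible_masks = [owner == i for i in range(len(full_masks))]
        blur_flags = []
        for visible in visible_masks:
            blur_flags.append(rng.random() < cfg.blur_fraction)
            if visible.any():
                _paint_leaf(img, visible, rng)
        for visible, blurred in zip(visible_masks, blur_flags):
            area = mask_area(visible)
            if area == 0:
                continue  # fully occluded
            if blurred:
                img = refine_instance(
                    img, visible, FilterSpec(FilterType.GLPF, 5, 1.5)
                )
            bundle.annotations.append(
                InstanceAnnotation(
                    id=ann_id,
                    image_id=image_id,
                    category_id=1,
                    segmentation=mask_to_rle(visible),
                    bbox=[float(v) for v in mask_to_bbox(visible)],
                    area=float(area),
                )
            )
            ann_id += 1
            entry["leaf_count"] += 1
            entry["areas"].append(area)
            entry["blurred"].append(bool(blurred))
        bundle.images.append(
            ImageRecord(id=image_id, file_name=f"scene_{image_id:05d}.png", width=w, height=h)
        )
        bundle.pixels[image_id] = img
        ledger.append(entry)
    bundle.validate()
    return bundle, ledger


# ---------------------------------------------------------------------------
# mock predictor


def instance_sharpness(img: np.ndarray, mask: np.ndarray) -> float:
    """Mean gradient magnitude of the grayscale image inside the mask."""
    gray = np.asarray(img, dtype=np.float64)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gy, gx)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return 0.0
    return float(mag[m].mean())


def _spurious_mask(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    ry, rx = rng.uniform(3, max(4, h / 8)), rng.uniform(3, max(4, w / 8))
    cy, cx = rng.uniform(ry, h - ry), rng.uniform(rx, w - rx)
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1


def mock_predict(
    bundle: DatasetBundle, perturb: PerturbSpec, seed: int = 0
) -> list[Prediction]:
    """Simulate a segmentation model's output on a ground-truth bundle.

    With a zero-perturbation spec, predictions equal the ground truth with
    score 1.0.  In blur-aware mode (``blur_sensitivity`` > 0), instances
    whose local sharpness falls below ``sharpness_threshold`` are dropped
    and the rest are eroded in proportion to the sharpness deficit,
    modelling the detector's degradation on defocused regions.
    """
    rng = np.random.default_rng(seed)
    preds: list[Prediction] = []
    for rec in bundle.images:
        h, w = rec.height, rec.width
        img = bundle.pixels.get(rec.id)
        for ann in sorted(bundle.annotations_for(rec.id), key=lambda a: a.id):
            if perturb.drop_probability > 0 and rng.random() < perturb.drop_probability:
                continue
            mask = rasterize(ann, h, w)
            morph = perturb.morph_pixels
            if perturb.blur_sensitivity > 0:
                if img is None:
                    raise ValueError("blur-aware prediction needs pixel data in the bundle")
                s = instance_sharpness(img, mask)
                if s < perturb.sharpness_threshold:
                    continue
                deficit = max(0.0, 1.0 - s / (2 * perturb.sharpness_threshold))
                morph -= int(round(perturb.blur_sensitivity * deficit))
            if perturb.translation > 0:
                dy = int(rng.integers(-perturb.translation, perturb.translation + 1))
                dx = int(rng.integers(-perturb.translation, perturb.translation + 1))
                mask = nd_shift(
                    mask.astype(np.uint8), (dy, dx), order=0, mode="constant", cval=0
                ).astype(bool)
            if morph > 0:
                mask = binary_dilation(mask, iterations=morph)
            elif morph < 0:
                mask = binary_erosion(mask, iterations=-morph)
            if not mask.any():
                continue
            lo, hi = perturb.tp_score_range
            score = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            preds.append(
                Prediction(
                    image_id=rec.id,
                    category_id=ann.category_id,
                    score=score,
                    mask=mask.astype(bool),
                    bbox=[float(v) for v in mask_to_bbox(mask)],
                )
            )
        if perturb.spurious_rate > 0:
            for _ in range(rng.poisson(perturb.spurious_rate)):
                m = _spurious_mask(rng, h, w)
                lo, hi = perturb.spurious_score_range
                preds.append(
                    Prediction(
                        image_id=rec.id,
                        category_id=1,
                        score=float(rng.uniform(lo, hi)),
                        mask=m,
                        bbox=[float(v) for v in mask_to_bbox(m)],
                    )
                )
    return preds
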