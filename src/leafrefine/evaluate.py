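"""COCO-protocol instance-segmentation evaluation, implemented from scratch.

Average precision follows the standard MS-COCO recipe: predictions pooled
over all images and sorted by confidence, greedy per-image matching at a
fixed IoU threshold, precision–recall curve interpolated at 101 evenly
spaced recall levels, AP = mean interpolated precision.  ``AP50-95`` is the
mean AP over IoU thresholds 0.50:0.05:0.95.  With a single leaf category
the category-averaged mAP equals that category's AP.  All APs are reported
on the 0–100 scale.

Matching rules (deterministic): predictions are visited in descending
score order (ties broken by prediction order); each takes the unmatched
ground truth with the highest IoU ≥ threshold (IoU ties broken by lowest
ground-truth index).  Unmatched predictions are false positives, unmatched
ground truths false negatives.  At most 100 detections per image are kept.

The instance-count analyses layer on top: the number of predicted masks at
a score threshold, and the relative change rate of that count between a
filtered and a baseline condition, averaged over a kernel-size series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import DatasetBundle, mask_area, rasterize, rle_to_mask

__all__ = [
    "Prediction",
    "EvalResult",
    "mask_iou",
    "box_iou",
    "match_instances",
    "average_precision",
    "summarize",
    "count_predicted_masks",
    "change_rate",
    "average_change_rate",
]

IOU_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)
RECALL_LEVELS = np.linspace(0.0, 1.0, 101)
MAX_DETECTIONS = 100


@dataclass
class Prediction:
    """A scored instance emitted by any segmentation model."""

    image_id: int
    category_id: int
    score: float
    mask: np.ndarray | dict | None = None  # boolean array or RLE dict
    bbox: list[float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score!r}")

    def decoded_mask(self) -> np.ndarray:
        if isinstance(self.mask, dict):
            return rle_to_mask(self.mask)
        return np.asarray(self.mask, dtype=bool)


@dataclass
class EvalResult:
    """AP summary (0–100 scale) for masks and boxes plus count statistics."""

    segm: dict[str, float]
    bbox: dict[str, float]
    predicted_mask_count: int
    curves: dict = field(default_factory=dict, repr=False)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks in the same frame."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU undefined: both masks are empty")
    return float(np.logical_and(a, b).sum() / union)


def box_iou(a, b) -> float:
    """IoU of two [x, y, w, h] boxes (half-open pixel intervals)."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if aw < 0 or ah < 0 or bw < 0 or bh < 0:
        raise ValueError("box width/height must be non-negative")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    if union == 0:
        raise ValueError("IoU undefined: both boxes are empty")
    return float(inter / union)


def _iou_matrix(preds, gts, iou_kind: str, gt_masks=None, pred_masks=None) -> np.ndarray:
    n_p, n_g = len(preds), len(gts)
    M = np.zeros((n_p, n_g))
    for i in range(n_p):
        for j in range(n_g):
            try:
                if iou_kind == "mask":
                    M[i, j] = mask_iou(pred_masks[i], gt_masks[j])
                else:
                    M[i, j] = box_iou(preds[i].bbox, gts[j].bbox)
            except ValueError:
                M[i, j] = 0.0
    return M


def match_instances(
    preds,
    gts,
    iou_threshold: float,
    iou_kind: str = "mask",
    *,
    image_shape: tuple[int, int] | None = None,
) -> dict:
    """Greedy score-ordered matching of predictions to ground truths.

    All items must belong to one image.  Returns a dict with ``matches``
    (list of (pred_index, gt_index) pairs), ``fp`` and ``fn`` index lists.
    """
    if iou_kind not in ("mask", "box"):
        raise ValueError(f"iou_kind must be 'mask' or 'box', got {iou_kind!r}")
    if iou_kind == "mask":
        if image_shape is None:
            m = next((p.decoded_mask() for p in preds if p.mask is not None), None)
            if m is None and gts:
                raise ValueError("image_shape required when no masks are decodable")
            image_shape = m.shape if m is not None else (1, 1)
        pred_masks = [p.decoded_mask() for p in preds]
        gt_masks = [rasterize(g, *image_shape) for g in gts]
    else:
        pred_masks = gt_masks = None
    M = _iou_matrix(preds, gts, iou_kind, gt_masks, pred_masks)
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    gt_taken = np.zeros(len(gts), dtype=bool)
    matches, fp = [], []
    for i in order:
        best_j, best_iou = -1, iou_threshold
        for j in range(len(gts)):
            if not gt_taken[j] and M[i, j] >= best_iou and (best_j < 0 or M[i, j] > best_iou):
                best_j, best_iou = j, M[i, j]
        if best_j >= 0:
            gt_taken[best_j] = True
            matches.append((i, best_j))
        else:
            fp.append(i)
    fn = [j for j in range(len(gts)) if not gt_taken[j]]
    return {"matches": matches, "fp": fp, "fn": fn}


def _pooled_tp_flags(
    preds_by_image: dict, gts_by_image: dict, iou_matrices: dict, iou_threshold: float
):
    """TP/FP flag per pooled prediction, sorted by descending score."""
    flags, scores = [], []
    for image_id, preds in preds_by_image.items():
        gts = gts_by_image.get(image_id, [])
        M = iou_matrices[image_id]
        order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))[:MAX_DETECTIONS]
        gt_taken = np.zeros(len(gts), dtype=bool)
        for i in order:
            best_j, best_iou = -1, iou_threshold
            for j in range(len(gts)):
                if not gt_taken[j] and M[i, j] >= best_iou and (best_j < 0 or M[i, j] > best_iou):
                    best_j, best_iou = j, M[i, j]
            tp = best_j >= 0
            if tp:
                gt_taken[best_j] = True
            flags.append(tp)
            scores.append(preds[i].score)
    if not flags:
        return np.zeros(0, dtype=bool), np.zeros(0)
    scores = np.asarray(scores)
    flags = np.asarray(flags, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    return flags[order], scores[order]


def _ap_from_flags(flags: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP (0–1 scale) from score-sorted TP flags."""
    if n_gt == 0:
        raise ValueError("AP undefined with zero ground-truth instances")
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope: max precision at any recall >= r
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(recall, RECALL_LEVELS, side="left")
    interp = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
    return float(interp.mean())


def _group(preds, gts: DatasetBundle):
    preds_by_image: dict[int, list] = {}
    for p in preds:
        preds_by_image.setdefault(p.image_id, []).append(p)
    gts_by_image = {rec.id: gts.annotations_for(rec.id) for rec in gts.images}
    return preds_by_image, gts_by_image


def _precompute_ious(preds_by_image, gts_by_image, gts: DatasetBundle, iou_kind: str):
    matrices = {}
    for image_id, preds in preds_by_image.items():
        g = gts_by_image.get(image_id, [])
        if iou_kind == "mask":
            rec = gts.image_by_id(image_id)
            shape = (rec.height, rec.width)
            pm = [p.decoded_mask() for p in preds]
            gm = [rasterize(a, *shape) for a in g]
            matrices[image_id] = _iou_matrix(preds, g, "mask", gm, pm)
        else:
            matrices[image_id] = _iou_matrix(preds, g, "box")
    return matrices


def average_precision(
    preds, gts: DatasetBundle, iou_threshold: float, iou_kind: str = "mask"
) -> float:
    """AP (0–100) at one IoU threshold, pooled over all images."""
    preds_by_image, gts_by_image = _group(preds, gts)
    matrices = _precompute_ious(preds_by_image, gts_by_image, gts, iou_kind)
    n_gt = sum(len(v) for v in gts_by_image.values())
    flags, _ = _pooled_tp_flags(preds_by_image, gts_by_image, matrices, iou_threshold)
    return 100.0 * _ap_from_flags(flags, n_gt)


def summarize(
    preds, gts: DatasetBundle, score_threshold: float = 0.5
) -> EvalResult:
    """Full COCO-style summary: AP50/AP75/AP50-95 for masks and boxes."""
    preds_by_image, gts_by_image = _group(preds, gts)
    n_gt = sum(len(v) for v in gts_by_image.values())
    result = {}
    curves = {}
    for kind in ("mask", "box"):
        matrices = _precompute_ious(preds_by_image, gts_by_image, gts, kind)
        aps = {}
        for t in IOU_THRESHOLDS:
            flags, scores = _pooled_tp_flags(preds_by_image, gts_by_image, matrices, t)
            aps[float(t)] = 100.0 * _ap_from_flags(flags, n_gt)
            if flags.size:
                tp = np.cumsum(flags)
                fp = np.cumsum(~flags)
                curves[(kind, float(t))] = {
                    "recall": (tp / n_gt).tolist(),
                    "precision": (tp / (tp + fp)).tolist(),
                    "score": scores.tolist(),
                }
        result[kind] = {
            "ap50": aps[0.5],
            "ap75": aps[0.75],
            "ap50_95": float(np.mean(list(aps.values()))),
            "ap_by_threshold": aps,
        }
    return EvalResult(
        segm=result["mask"],
        bbox=result["box"],
        predicted_mask_count=count_predicted_masks(preds, score_threshold),
        curves=curves,
    )


def count_predicted_masks(preds, score_threshold: float = 0.5) -> int:
    """Number of predictions at or above the score threshold."""
    return sum(1 for p in preds if p.score >= score_threshold)


def change_rate(count_filtered: int, count_baseline: int) -> float:
    """Relative change of the predicted-mask count vs a baseline condition."""
    if count_baseline <= 0:
        raise ValueError("baseline count must be positive")
    return (count_filtered - count_baseline) / count_baseline


def average_change_rate(rates) -> float:
    """Mean change rate over a kernel-size series."""
    rates = list(rates)
    if not rates:
        raise ValueError("need at least one change rate")
    return float(np.mean(rates))
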