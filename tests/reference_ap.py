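"""Independent reference implementation of COCO-style average precision.

Written as a deliberately plain, loop-based second route — sharing no code
with ``leafrefine.evaluate`` — following the standard COCO accumulation
procedure: per-image greedy matching of score-sorted detections, pooled
TP/FP flags, precision envelope, 101-recall-point interpolation.  Used
only as a test oracle.
"""

from __future__ import annotations

import numpy as np


def iou_masks(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    return inter / union if union else 0.0


def iou_boxes(a, b) -> float:
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    x0, y0 = max(ax0, bx0), max(ay0, by0)
    x1, y1 = min(ax0 + aw, bx0 + bw), min(ay0 + ah, by0 + bh)
    inter = max(0.0, x1 - x0) * max(0.0, y1 - y0)
    union = aw * ah + bw * bh - inter
    return inter / union if union else 0.0


def reference_ap(
    detections: list[dict], ground_truths: list[dict], threshold: float, kind: str
) -> float:
    """AP on the 0-1 scale.

    ``detections``: dicts with image_id, score, and mask (bool array) or
    box [x, y, w, h].  ``ground_truths``: dicts with image_id and mask/box.
    """
    image_ids = sorted(
        {d["image_id"] for d in detections} | {g["image_id"] for g in ground_truths}
    )
    records = []  # (score, order, is_tp)
    order = 0
    for img in image_ids:
        dets = [d for d in detections if d["image_id"] == img]
        gts = [g for g in ground_truths if g["image_id"] == img]
        dets = sorted(dets, key=lambda d: -d["score"])[:100]
        used = [False] * len(gts)
        for d in dets:
            best, best_iou = -1, threshold
            for j, g in enumerate(gts):
                if used[j]:
                    continue
                iou = (
                    iou_masks(d["mask"], g["mask"])
                    if kind == "mask"
                    else iou_boxes(d["box"], g["box"])
                )
                if iou >= best_iou and (best < 0 or iou > best_iou):
                    best, best_iou = j, iou
            if best >= 0:
                used[best] = True
                records.append((d["score"], order, True))
            else:
                records.append((d["score"], order, False))
            order += 1
    n_gt = len(ground_truths)
    if n_gt == 0:
        raise ValueError("no ground truths")
    records.sort(key=lambda r: (-r[0], r[1]))
    tp = fp = 0
    recalls, precisions = [], []
    for _, _, is_tp in records:
        tp += is_tp
        fp += not is_tp
        recalls.append(tp / n_gt)
        precisions.append(tp / (tp + fp))
    # precision envelope from the right
    for i in range(len(precisions) - 2, -1, -1):
        precisions[i] = max(precisions[i], precisions[i + 1])
    total = 0.0
    for r_level in np.linspace(0, 1, 101):
        p = 0.0
        for rec, prec in zip(recalls, precisions):
            if rec >= r_level:
                p = prec
                break
        total += p
    return total / 101.0


def reference_summary(detections, ground_truths, kind: str) -> dict:
    """AP50 / AP75 / AP50-95 on the 0-100 scale."""
    thresholds = [0.5 + 0.05 * i for i in range(10)]
    aps = [reference_ap(detections, ground_truths, t, kind) for t in thresholds]
    return {
        "ap50": 100.0 * aps[0],
        "ap75": 100.0 * aps[5],
        "ap50_95": 100.0 * float(np.mean(aps)),
    }
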