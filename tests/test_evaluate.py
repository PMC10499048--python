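"""From-scratch AP engine tests: analytic cases, brute-force PR oracle,
and equivalence with an independent reference implementation."""

import numpy as np
import pytest

from leafrefine.dataset_io import (
    Category,
    DatasetBundle,
    ImageRecord,
    InstanceAnnotation,
    mask_to_bbox,
    mask_to_rle,
    rasterize,
)
from leafrefine.evaluate import (
    Prediction,
    average_change_rate,
    average_precision,
    box_iou,
    change_rate,
    count_predicted_masks,
    mask_iou,
    match_instances,
    summarize,
)
from leafrefine.synthetic import PerturbSpec, SceneConfig, generate_scenes, mock_predict

from reference_ap import reference_ap, reference_summary


def _square_mask(h, w, r0, c0, side):
    m = np.zeros((h, w), dtype=bool)
    m[r0 : r0 + side, c0 : c0 + side] = True
    return m


def _bundle_from_masks(masks_by_image, h=30, w=30):
    b = DatasetBundle(categories=[Category(1, "leaf")])
    ann_id = 1
    for img_id, masks in masks_by_image.items():
        b.images.append(ImageRecord(img_id, f"i{img_id}.png", w, h))
        for m in masks:
            b.annotations.append(
                InstanceAnnotation(
                    ann_id, img_id, 1, mask_to_rle(m),
                    [float(v) for v in mask_to_bbox(m)], float(m.sum()),
                )
            )
            ann_id += 1
    return b


def _pred(img_id, mask, score):
    return Prediction(
        image_id=img_id, category_id=1, score=score, mask=mask,
        bbox=[float(v) for v in mask_to_bbox(mask)],
    )


class TestIou:
    def test_identical_masks(self):
        m = _square_mask(20, 20, 2, 2, 8)
        assert mask_iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = _square_mask(20, 20, 0, 0, 5)
        b = _square_mask(20, 20, 10, 10, 5)
        assert mask_iou(a, b) == 0.0

    def test_offset_squares_integer_counts(self):
        # two 10x10 squares offset by 4 rows: 60 / 140
        a = _square_mask(30, 30, 0, 0, 10)
        b = _square_mask(30, 30, 4, 0, 10)
        assert mask_iou(a, b) == pytest.approx(60 / 140)

    def test_both_empty_rejected(self):
        z = np.zeros((5, 5), dtype=bool)
        with pytest.raises(ValueError):
            mask_iou(z, z)

    def test_box_iou_matches_mask_iou_for_rects(self):
        a = _square_mask(30, 30, 0, 0, 10)
        b = _square_mask(30, 30, 4, 0, 10)
        assert box_iou([0, 0, 10, 10], [0, 4, 10, 10]) == pytest.approx(mask_iou(a, b))

    def test_translated_square_closed_form(self):
        # side s shifted by d: IoU = (s−d)·s / (2s² − (s−d)·s)
        s, d = 12, 3
        a = _square_mask(40, 40, 5, 5, s)
        b = _square_mask(40, 40, 5 + d, 5, s)
        expected = (s - d) * s / (2 * s * s - (s - d) * s)
        assert mask_iou(a, b) == pytest.approx(expected)


class TestMatching:
    def test_perfect_predictions_all_tp(self):
        masks = [_square_mask(30, 30, 0, 0, 8), _square_mask(30, 30, 15, 15, 8)]
        b = _bundle_from_masks({1: masks})
        preds = [_pred(1, m, 1.0) for m in masks]
        res = match_instances(preds, b.annotations, 0.5, "mask", image_shape=(30, 30))
        assert len(res["matches"]) == 2 and not res["fp"] and not res["fn"]

    def test_below_threshold_pair_is_fp_and_fn(self):
        gt = _square_mask(30, 30, 0, 0, 10)
        pred_mask = _square_mask(30, 30, 4, 0, 10)  # IoU 0.42857 < 0.5
        b = _bundle_from_masks({1: [gt]})
        res = match_instances(
            [_pred(1, pred_mask, 0.9)], b.annotations, 0.5, "mask", image_shape=(30, 30)
        )
        assert res["fp"] == [0] and res["fn"] == [0] and not res["matches"]

    def test_higher_score_wins_contested_gt(self):
        gt = _square_mask(30, 30, 5, 5, 10)
        b = _bundle_from_masks({1: [gt]})
        p_hi = _pred(1, gt, 0.9)
        p_lo = _pred(1, gt.copy(), 0.8)
        res = match_instances([p_lo, p_hi], b.annotations, 0.5, "mask", image_shape=(30, 30))
        assert res["matches"] == [(1, 0)] and res["fp"] == [0]


class TestAveragePrecision:
    def test_perfect_predictions_score_100(self, small_scene):
        bundle, _ = small_scene
        preds = mock_predict(bundle, PerturbSpec(), seed=0)
        res = summarize(preds, bundle)
        for block in (res.segm, res.bbox):
            assert block["ap50"] == 100.0
            assert block["ap75"] == 100.0
            assert block["ap50_95"] == 100.0

    def test_low_iou_pair_gives_zero_ap50(self):
        gt = _square_mask(30, 30, 0, 0, 10)
        b = _bundle_from_masks({1: [gt]})
        preds = [_pred(1, _square_mask(30, 30, 4, 0, 10), 0.9)]
        assert average_precision(preds, b, 0.5, "mask") == 0.0

    def test_three_gt_two_tp_one_fp_oracle(self):
        # 3 GTs, TPs at scores 0.9 and 0.7 (IoU 0.8-ish), FP at 0.8
        g1 = _square_mask(40, 40, 0, 0, 10)
        g2 = _square_mask(40, 40, 14, 0, 10)
        g3 = _square_mask(40, 40, 28, 0, 10)
        b = _bundle_from_masks({1: [g1, g2, g3]}, h=40, w=40)
        p1 = _square_mask(40, 40, 0, 1, 10)  # IoU 9/11 with g1
        p2 = _square_mask(40, 40, 14, 1, 10)
        fp = _square_mask(40, 40, 0, 25, 10)
        preds = [_pred(1, p1, 0.9), _pred(1, fp, 0.8), _pred(1, p2, 0.7)]
        got = average_precision(preds, b, 0.5, "mask")
        # brute-force PR enumeration: precisions (1, 1/2, 2/3) -> envelope
        # (1, 2/3, 2/3); 34 recall levels at 1.0, 33 at 2/3, rest 0
        assert got == pytest.approx(100 * 56 / 101)
        dets = [{"image_id": 1, "score": s, "mask": m} for m, s in
                [(p1, 0.9), (fp, 0.8), (p2, 0.7)]]
        gts = [{"image_id": 1, "mask": m} for m in (g1, g2, g3)]
        assert got == pytest.approx(100 * reference_ap(dets, gts, 0.5, "mask"))

    def test_zero_ground_truths_rejected(self):
        b = _bundle_from_masks({1: []})
        with pytest.raises(ValueError):
            average_precision([_pred(1, _square_mask(30, 30, 0, 0, 5), 0.9)], b, 0.5)

    def test_score_monotone_rescaling_invariance(self, cluttered_bundle, noisy_predictions):
        bundle, _ = cluttered_bundle
        base = summarize(noisy_predictions, bundle)
        rescaled = [
            Prediction(p.image_id, p.category_id, p.score**3, p.mask, p.bbox)
            for p in noisy_predictions
        ]
        res = summarize(rescaled, bundle)
        assert res.segm["ap50"] == pytest.approx(base.segm["ap50"])
        assert res.bbox["ap50_95"] == pytest.approx(base.bbox["ap50_95"])

    def test_lowest_score_zero_iou_fp_never_increases_ap(self, cluttered_bundle, noisy_predictions):
        bundle, _ = cluttered_bundle
        base = average_precision(noisy_predictions, bundle, 0.5, "mask")
        junk = np.zeros((160, 160), dtype=bool)
        junk[:3, :3] = True
        worse = noisy_predictions + [_pred(bundle.images[0].id, junk, 0.01)]
        assert average_precision(worse, bundle, 0.5, "mask") <= base + 1e-12

    def test_ap50_dominates_ap75(self, cluttered_bundle, noisy_predictions):
        bundle, _ = cluttered_bundle
        res = summarize(noisy_predictions, bundle)
        for block in (res.segm, res.bbox):
            assert block["ap50"] >= block["ap75"] >= 0.0
            assert block["ap50"] >= block["ap50_95"]

    def test_matches_independent_reference_on_random_scenes(self):
        rng = np.random.default_rng(123)
        worst = 0.0
        for trial in range(12):
            b, _ = generate_scenes(
                SceneConfig(seed=500 + trial, image_size=(80, 80),
                            n_leaves=(2, 5), leaf_size=(6, 12)), 2)
            spec = PerturbSpec(
                translation=int(rng.integers(0, 4)),
                morph_pixels=int(rng.integers(-2, 3)),
                drop_probability=float(rng.uniform(0, 0.4)),
                spurious_rate=float(rng.uniform(0, 1.5)),
                tp_score_range=(0.5, 1.0),
            )
            preds = mock_predict(b, spec, seed=trial)
            if not preds:
                continue
            res = summarize(preds, b)
            dets = [{"image_id": p.image_id, "score": p.score,
                     "mask": p.decoded_mask(), "box": p.bbox} for p in preds]
            gts = [{"image_id": a.image_id,
                    "mask": rasterize(a, 80, 80), "box": a.bbox}
                   for a in b.annotations]
            for kind, block in (("mask", res.segm), ("box", res.bbox)):
                ref = reference_summary(dets, gts, kind)
                for key in ("ap50", "ap75", "ap50_95"):
                    worst = max(worst, abs(block[key] - ref[key]))
        assert worst < 0.1


class TestCounts:
    def test_empty_predictions(self):
        assert count_predicted_masks([]) == 0

    def test_all_above_threshold(self):
        m = _square_mask(10, 10, 0, 0, 3)
        preds = [_pred(1, m, 0.6 + 0.05 * i) for i in range(5)]
        assert count_predicted_masks(preds, 0.5) == 5

    def test_mixed_scores_filtered(self):
        m = _square_mask(10, 10, 0, 0, 3)
        scores = [0.1, 0.49, 0.5, 0.77, 0.93]
        preds = [_pred(1, m, s) for s in scores]
        assert count_predicted_masks(preds, 0.5) == sum(s >= 0.5 for s in scores)

    def test_change_rate_zero_for_equal_counts(self):
        assert change_rate(100, 100) == 0.0

    def test_change_rate_on_printed_count_pair(self):
        assert change_rate(918, 889) == pytest.approx(0.03262092238470191)

    def test_change_rate_requires_positive_baseline(self):
        with pytest.raises(ValueError):
            change_rate(5, 0)

    def test_average_change_rate_is_mean(self):
        assert average_change_rate([0.01, 0.02, 0.03]) == pytest.approx(0.02)
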