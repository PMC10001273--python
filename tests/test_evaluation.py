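"""Box matching, pooled metrics, PR curve / AP, threshold selection."""

import itertools

import pytest

from negdetect import (
    BoundingBox,
    ConsistencyError,
    EvaluationCounts,
    MatchCriterion,
    Metrics,
    UndefinedMetricError,
    evaluate,
    f1_score,
    match_image,
    pr_curve,
    select_threshold,
)
from negdetect.evaluation import PRCurve, PRPoint

from conftest import det, make_image, make_manifest

LITERAL = MatchCriterion()
GREEDY = MatchCriterion(counting="one_to_one_greedy")
IOU50 = MatchCriterion(mode="iou_threshold", iou_min=0.5)


class TestMatchImage:
    def test_overlapping_detection_is_a_true_positive(self):
        counts = match_image([det("i", (5, 5, 15, 15), 0.9)],
                             [BoundingBox(10, 10, 30, 30)], LITERAL)
        assert counts == EvaluationCounts(tp=1, fp=0, fn=0)

    def test_disjoint_detection_fires_both_fp_and_fn(self):
        counts = match_image([det("i", (50, 50, 60, 60), 0.9)],
                             [BoundingBox(10, 10, 30, 30)], LITERAL)
        assert counts == EvaluationCounts(tp=0, fp=1, fn=1)

    def test_two_detections_over_one_truth_literal_vs_greedy(self):
        dets = [det("i", (10, 10, 20, 20), 0.9), det("i", (15, 15, 25, 25), 0.8)]
        truths = [BoundingBox(12, 12, 28, 28)]
        assert match_image(dets, truths, LITERAL) == EvaluationCounts(2, 0, 0)
        assert match_image(dets, truths, GREEDY) == EvaluationCounts(1, 1, 0)

    def test_empty_inputs_are_valid(self):
        assert match_image([], [], LITERAL) == EvaluationCounts(0, 0, 0)
        assert match_image([], [BoundingBox(0, 0, 5, 5)], LITERAL) \
            == EvaluationCounts(0, 0, 1)

    def test_iou_mode_requires_sufficient_overlap(self):
        # IoU of these boxes is 25/175 ~ 0.14: a hit under any_overlap,
        # a miss under IoU >= 0.5
        dets = [det("i", (0, 0, 10, 10), 0.9)]
        truths = [BoundingBox(5, 5, 15, 15)]
        assert match_image(dets, truths, LITERAL).tp == 1
        assert match_image(dets, truths, IOU50).tp == 0

    def test_literal_mode_equals_all_pairs_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n_d, n_t = rng.integers(0, 7, 2)
            dets, truths = [], []
            for k in range(n_d):
                x0, y0 = rng.integers(0, 40, 2)
                w, h = rng.integers(1, 20, 2)
                dets.append(det("i", (x0, y0, x0 + w, y0 + h),
                                float(rng.random())))
            for _k in range(n_t):
                x0, y0 = rng.integers(0, 40, 2)
                w, h = rng.integers(1, 20, 2)
                truths.append(BoundingBox(x0, y0, x0 + w, y0 + h))
            counts = match_image(dets, truths, LITERAL)
            # independent exhaustive predicate check
            over = [[d.box.intersection_area(t) > 0 for t in truths]
                    for d in dets]
            tp = sum(any(row) for row in over)
            fn = sum(1 for j in range(len(truths))
                     if not any(over[i][j] for i in range(len(dets))))
            assert counts == EvaluationCounts(tp, len(dets) - tp, fn)

    def test_greedy_never_exceeds_truth_count_in_tp(self, rng):
        for _ in range(100):
            n_d, n_t = rng.integers(0, 7, 2)
            dets = [det("i", (x, y, x + w, y + h), float(rng.random()))
                    for x, y, w, h in zip(rng.integers(0, 30, n_d),
                                          rng.integers(0, 30, n_d),
                                          rng.integers(1, 15, n_d),
                                          rng.integers(1, 15, n_d))]
            truths = [BoundingBox(x, y, x + w, y + h)
                      for x, y, w, h in zip(rng.integers(0, 30, n_t),
                                            rng.integers(0, 30, n_t),
                                            rng.integers(1, 15, n_t),
                                            rng.integers(1, 15, n_t))]
            counts = match_image(dets, truths, GREEDY)
            assert counts.tp <= len(truths)
            assert counts.tp + counts.fn == len(truths)
            assert counts.tp + counts.fp == len(dets)


class TestMetrics:
    def test_formulas_on_pooled_counts(self):
        metrics = Metrics.from_counts(EvaluationCounts(tp=7, fp=3, fn=3))
        assert metrics.recall == pytest.approx(0.7)
        assert metrics.precision == pytest.approx(0.7)
        assert metrics.f1 == pytest.approx(0.7)

    def test_degenerate_counts_flag_metrics_as_undefined(self):
        metrics = Metrics.from_counts(EvaluationCounts(0, 0, 0))
        assert metrics.recall is None and not metrics.recall_defined
        assert metrics.precision is None and not metrics.precision_defined
        assert metrics.f1 is None and not metrics.f1_defined

    def test_f1_lies_between_precision_and_recall(self, rng):
        for _ in range(300):
            tp, fp, fn = (int(v) for v in rng.integers(0, 30, 3))
            m = Metrics.from_counts(EvaluationCounts(tp, fp, fn))
            if m.recall is not None and m.precision is not None \
                    and m.f1 is not None:
                assert min(m.precision, m.recall) - 1e-12 <= m.f1 \
                    <= max(m.precision, m.recall) + 1e-12

    def test_f1_score_helper_is_the_harmonic_mean(self):
        assert f1_score(0.7, 0.7) == pytest.approx(0.7)
        assert f1_score(0.0, 0.0) == 0.0


class TestEvaluate:
    def test_threshold_filters_with_greater_or_equal(self, single_truth_manifest):
        dets = [det("img0", (10, 10, 30, 30), 0.5),
                det("img0", (50, 50, 60, 60), 0.4)]
        counts, _ = evaluate(single_truth_manifest, dets, 0.5)
        assert counts == EvaluationCounts(1, 0, 0)  # 0.5 survives, 0.4 dropped
        counts, _ = evaluate(single_truth_manifest, dets, 0.4)
        assert counts == EvaluationCounts(1, 1, 0)

    def test_unknown_image_id_is_a_consistency_error(self, single_truth_manifest):
        with pytest.raises(ConsistencyError):
            evaluate(single_truth_manifest, [det("ghost", (0, 0, 5, 5), 0.5)], 0)

    def test_raising_threshold_never_increases_tp_or_fp(self, rng):
        manifest = make_manifest(
            *[make_image(f"im{i}", boxes=[(10, 10, 30, 30)]) for i in range(10)])
        dets = []
        for i in range(10):
            for _ in range(int(rng.integers(0, 4))):
                x0, y0 = rng.integers(0, 60, 2)
                dets.append(det(f"im{i}", (x0, y0, x0 + 10, y0 + 10),
                                float(rng.random())))
        prev_tp, prev_fp = None, None
        for threshold in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
            counts, _ = evaluate(manifest, dets, threshold)
            if prev_tp is not None:
                assert counts.tp <= prev_tp
                assert counts.fp <= prev_fp
            prev_tp, prev_fp = counts.tp, counts.fp

    def test_appending_negative_images_dilutes_precision_only(self, rng):
        """Adding truth-free images never changes recall and never raises
        precision (the statistically expected dilution effect)."""
        polyp = [make_image(f"p{i}", boxes=[(10, 10, 30, 30)]) for i in range(20)]
        dets = [det(f"p{i}", (12, 12, 28, 28), 0.9) for i in range(15)]
        negatives, neg_dets = [], []
        for i in range(10):
            negatives.append(make_image(f"n{i}"))
            if i % 2 == 0:
                neg_dets.append(det(f"n{i}", (5, 5, 25, 25), 0.8))
        base = make_manifest(*polyp)
        augmented = make_manifest(*(polyp + negatives))
        _, m0 = evaluate(base, dets, 0.5)
        _, m1 = evaluate(augmented, dets + neg_dets, 0.5)
        assert m1.recall == m0.recall
        assert m1.precision <= m0.precision


class TestPRCurve:
    def test_perfect_detector_has_ap_one(self, single_truth_manifest):
        curve = pr_curve(single_truth_manifest,
                         [det("img0", (10, 10, 30, 30), 0.99)])
        assert curve.ap == pytest.approx(1.0)

    def test_single_false_positive_has_ap_zero(self, single_truth_manifest):
        curve = pr_curve(single_truth_manifest,
                         [det("img0", (50, 50, 60, 60), 0.99)])
        assert curve.ap == pytest.approx(0.0)

    def test_step_estimator_on_tp_fp_tp_sequence(self):
        """Three detections at descending confidence (hit, miss, hit) against
        two truths integrate to AP = 1*0.5 + (2/3)*0.5 = 5/6."""
        manifest = make_manifest(
            make_image("a", boxes=[(10, 10, 30, 30)]),
            make_image("b", boxes=[(10, 10, 30, 30)]),
        )
        dets = [
            det("a", (12, 12, 28, 28), 0.9),   # TP
            det("a", (60, 60, 80, 80), 0.8),   # FP
            det("b", (12, 12, 28, 28), 0.7),   # TP
        ]
        curve = pr_curve(manifest, dets)
        assert [p.threshold for p in curve.points] == [0.9, 0.8, 0.7]
        assert curve.ap == pytest.approx(5 / 6)

    def test_no_truth_boxes_makes_ap_undefined(self):
        manifest = make_manifest(make_image("n0"))
        with pytest.raises(UndefinedMetricError):
            pr_curve(manifest, [det("n0", (0, 0, 5, 5), 0.5)])

    @pytest.mark.parametrize("criterion", [LITERAL, GREEDY, IOU50],
                             ids=["literal", "greedy", "iou"])
    def test_curve_points_equal_direct_evaluation_at_each_threshold(
            self, rng, criterion):
        """Dual route: the incremental threshold sweep must agree with a
        from-scratch evaluation at every distinct confidence."""
        manifest = make_manifest(
            *[make_image(f"im{i}", boxes=[(10, 10, 30, 30)]) for i in range(8)],
            make_image("neg0"),
        )
        dets = []
        for i in range(8):
            for _ in range(int(rng.integers(0, 4))):
                x0, y0 = rng.integers(0, 50, 2)
                dets.append(det(f"im{i}", (x0, y0, x0 + 15, y0 + 15),
                                float(rng.random())))
        dets.append(det("neg0", (0, 0, 10, 10), float(rng.random())))
        curve = pr_curve(manifest, dets, criterion)
        for point in curve.points:
            counts, _ = evaluate(manifest, dets, point.threshold, criterion)
            assert counts == point.counts

    def test_ap_matches_brute_force_threshold_enumeration(self, rng):
        """Independent oracle: enumerate every distinct confidence cut with
        evaluate() and integrate the step area by hand."""
        import numpy as np
        for seed in range(5):
            local = np.random.default_rng(seed)
            manifest = make_manifest(
                *[make_image(f"im{i}", boxes=[(10, 10, 30, 30)])
                  for i in range(6)])
            dets = []
            for i in range(6):
                for _ in range(int(local.integers(0, 4))):
                    x0, y0 = local.integers(0, 50, 2)
                    dets.append(det(f"im{i}", (x0, y0, x0 + 15, y0 + 15),
                                    float(local.random())))
            if not dets:
                continue
            thresholds = sorted({d.confidence for d in dets}, reverse=True)
            ap, prev_recall = 0.0, 0.0
            for thr in thresholds:
                counts, metrics = evaluate(manifest, dets, thr)
                recall = metrics.recall or 0.0
                precision = metrics.precision or 0.0
                ap += precision * (recall - prev_recall)
                prev_recall = recall
            curve = pr_curve(manifest, dets)
            assert curve.ap == pytest.approx(ap)

    def test_recall_is_non_decreasing_as_threshold_drops(self, rng):
        manifest = make_manifest(
            *[make_image(f"im{i}", boxes=[(10, 10, 30, 30)]) for i in range(6)])
        dets = [det(f"im{i % 6}", (12, 12, 28, 28), float(rng.random()))
                for i in range(12)]
        curve = pr_curve(manifest, dets)
        recalls = [p.metrics.recall for p in curve.points]
        assert all(a <= b + 1e-12 for a, b in itertools.pairwise(recalls))


class TestSelectThreshold:
    def test_unique_maximum_is_selected(self, single_truth_manifest):
        dets = [det("img0", (12, 12, 28, 28), 0.9),
                det("img0", (50, 50, 70, 70), 0.3)]
        curve = pr_curve(single_truth_manifest, dets)
        assert select_threshold(curve) == 0.9

    def test_ties_break_toward_the_smaller_threshold(self):
        point = lambda thr, tp, fp, fn: PRPoint(
            thr, EvaluationCounts(tp, fp, fn),
            Metrics.from_counts(EvaluationCounts(tp, fp, fn)))
        curve = PRCurve(points=[point(0.8, 1, 0, 1), point(0.5, 1, 0, 1)],
                        ap=0.5)
        assert select_threshold(curve) == 0.5

    def test_single_point_curve_returns_its_threshold(self, single_truth_manifest):
        curve = pr_curve(single_truth_manifest,
                         [det("img0", (12, 12, 28, 28), 0.42)])
        assert select_threshold(curve) == 0.42

    def test_all_undefined_f1_is_a_selection_error(self):
        curve = PRCurve(points=[PRPoint(
            0.5, EvaluationCounts(0, 0, 0),
            Metrics.from_counts(EvaluationCounts(0, 0, 0)))], ap=0.0)
        with pytest.raises(UndefinedMetricError):
            select_threshold(curve)
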