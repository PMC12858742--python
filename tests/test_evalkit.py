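"""Evaluation metrics against hand geometry and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import linear_sum_assignment

from bedsynth.cocoio import AnnotationRecord, Detection
from bedsynth.errors import ParameterError
from bedsynth.evalkit import (
    EvalConfig,
    KEYPOINT_SIGMAS,
    ap_ar,
    aspect_log_ratio,
    filter_confidence,
    iou,
    nms,
    oks,
    score_persons,
)

from conftest import detections_from, toy_dataset
from oracles import greedy_nms, iou_cell_count, reference_ap_ar


class TestIoU:
    def test_identical_boxes(self):
        assert iou([3, 4, 10, 12], [3, 4, 10, 12]) == 1.0

    def test_disjoint_boxes(self):
        assert iou([0, 0, 5, 5], [10, 10, 5, 5]) == 0.0

    def test_hand_geometry_one_seventh(self):
        assert iou([0, 0, 2, 2], [1, 1, 2, 2]) == pytest.approx(1 / 7, abs=1e-12)

    def test_degenerate_empty_boxes(self):
        assert iou([0, 0, 0, 0], [0, 0, 0, 0]) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_cell_count_oracle_on_integer_boxes(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            a = [rng.integers(0, 20), rng.integers(0, 20), rng.integers(1, 15), rng.integers(1, 15)]
            b = [rng.integers(0, 20), rng.integers(0, 20), rng.integers(1, 15), rng.integers(1, 15)]
            assert iou(a, b) == pytest.approx(iou_cell_count(a, b), abs=1e-12)

    @given(
        st.tuples(*[st.floats(0, 50) for _ in range(2)], *[st.floats(0.1, 30) for _ in range(2)]),
        st.tuples(*[st.floats(0, 50) for _ in range(2)], *[st.floats(0.1, 30) for _ in range(2)]),
    )
    def test_symmetric_and_bounded(self, a, b):
        v = iou(list(a), list(b))
        assert 0.0 <= v <= 1.0
        assert v == iou(list(b), list(a))


class TestFilterAndNms:
    def test_zero_threshold_identity(self):
        dets = detections_from({0: [([0, 0, 5, 5], 0.3), ([1, 1, 4, 4], 0.001)]})
        assert filter_confidence(dets, 0.0) == dets

    def test_threshold_one_empties(self):
        dets = detections_from({0: [([0, 0, 5, 5], 0.99)]})
        assert filter_confidence(dets, 1.0) == []

    def test_mixed_set_equals_bruteforce(self):
        rng = np.random.default_rng(0)
        dets = [
            Detection(0, [0, 0, 5, 5], float(c)) for c in rng.uniform(0, 1, 50)
        ]
        got = filter_confidence(dets, 0.2)
        assert got == [d for d in dets if d.confidence >= 0.2]

    def test_single_detection_unchanged(self):
        dets = detections_from({0: [([0, 0, 5, 5], 0.4)]})
        assert nms(dets) == dets

    def test_duplicate_boxes_keep_highest_confidence(self):
        dets = detections_from({0: [([0, 0, 5, 5], 0.8), ([0, 0, 5, 5], 0.9)]})
        kept = nms(dets, 0.65)
        assert len(kept) == 1 and kept[0].confidence == 0.9

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reference_greedy(self, seed):
        rng = np.random.default_rng(seed)
        boxes = np.column_stack(
            [rng.uniform(0, 60, 50), rng.uniform(0, 60, 50), rng.uniform(5, 30, 50), rng.uniform(5, 30, 50)]
        )
        scores = rng.uniform(0, 1, 50)
        dets = [Detection(0, list(b), float(s)) for b, s in zip(boxes, scores)]
        kept = nms(dets, 0.5)
        oracle_idx = greedy_nms(boxes.tolist(), scores.tolist(), 0.5)
        assert [d.confidence for d in kept] == [scores[i] for i in oracle_idx]

    def test_order_invariance_up_to_tiebreak(self):
        rng = np.random.default_rng(5)
        boxes = np.column_stack(
            [rng.uniform(0, 40, 20), rng.uniform(0, 40, 20), rng.uniform(5, 20, 20), rng.uniform(5, 20, 20)]
        )
        scores = rng.uniform(0, 1, 20)  # continuous: no ties
        dets = [Detection(0, list(b), float(s)) for b, s in zip(boxes, scores)]
        shuffled = [dets[i] for i in rng.permutation(20)]
        a = sorted(d.confidence for d in nms(dets, 0.5))
        b = sorted(d.confidence for d in nms(shuffled, 0.5))
        assert a == b


class TestScorePersons:
    def test_perfect_detections_score_one(self):
        ds = toy_dataset({0: [[0, 0, 50, 80]], 1: [[5, 5, 40, 60]]})
        dets = [Detection(a.image_id, list(a.bbox), 1.0) for a in ds.annotations]
        sv = score_persons(ds.annotations, dets)
        assert np.allclose(sv.scores, 1.0)

    def test_half_overlap_scores_zero(self):
        ds = toy_dataset({0: [[0, 0, 10, 10]]})
        det = Detection(0, [5.0, 0.0, 10.0, 10.0], 0.9)  # IoU = 1/3
        sv = score_persons(ds.annotations, [det])
        assert sv.scores[0] == 0.0

    def test_unmatched_ground_truths_score_zero(self):
        ds = toy_dataset({0: [[0, 0, 10, 10], [100, 100, 10, 10]]})
        det = Detection(0, [0.0, 0.0, 10.0, 10.0], 0.9)
        sv = score_persons(ds.annotations, [det])
        assert sorted(sv.scores) == [0.0, 1.0]

    def test_binary_variant(self):
        ds = toy_dataset({0: [[0, 0, 10, 10]]})
        det = Detection(0, [1.0, 0.0, 10.0, 10.0], 0.9)  # IoU = 9/11 > 0.75
        sv = score_persons(ds.annotations, [det], EvalConfig(binary_score=True))
        assert sv.scores[0] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_equals_optimal_assignment_on_separated_instances(self, seed):
        # ground truths far apart, detections perturbed copies: the greedy
        # total must equal the optimal-assignment total
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        gts, dets = [], []
        for i in range(n):
            x, y = 200.0 * i, 50.0
            gts.append(AnnotationRecord(id=i, image_id=0, bbox=[x, y, 40, 70]))
            dets.append(
                Detection(0, [x + rng.uniform(-6, 6), y + rng.uniform(-6, 6), 40, 70],
                          float(rng.uniform(0.3, 1.0)))
            )
        sv = score_persons(gts, dets)
        # oracle: maximise total matched IoU with the Hungarian algorithm
        cost = np.zeros((n, n))
        for i, g in enumerate(gts):
            for j, d in enumerate(dets):
                cost[i, j] = -iou(g.bbox, d.bbox)
        ri, ci = linear_sum_assignment(cost)
        optimal = sum(
            -cost[i, j] if -cost[i, j] >= 0.75 else 0.0 for i, j in zip(ri, ci)
        )
        assert sum(sv.scores) == pytest.approx(optimal, abs=1e-12)

    def test_monotone_in_matched_iou(self):
        ds = toy_dataset({0: [[0, 0, 20, 20]]})
        worse = Detection(0, [4.0, 0.0, 20.0, 20.0], 0.9)
        better = Detection(0, [1.0, 0.0, 20.0, 20.0], 0.9)
        s_w = score_persons(ds.annotations, [worse]).scores[0]
        s_b = score_persons(ds.annotations, [better]).scores[0]
        assert s_b >= s_w


class TestApAr:
    def test_perfect_detections_hit_hundred(self):
        ds = toy_dataset({0: [[0, 0, 50, 80]], 1: [[5, 5, 40, 60], [90, 9, 30, 30]]})
        dets = [Detection(a.image_id, list(a.bbox), 1.0) for a in ds.annotations]
        summary = ap_ar(ds.annotations, dets)
        assert summary.ap == pytest.approx(100.0, abs=1e-9)
        assert summary.ar == pytest.approx(100.0, abs=1e-9)

    def test_no_detections_zero(self):
        ds = toy_dataset({0: [[0, 0, 50, 80]]})
        summary = ap_ar(ds.annotations, [])
        assert summary.ap == 0.0 and summary.ar == 0.0

    def test_no_ground_truth_undefined_marker(self):
        summary = ap_ar([], detections_from({0: [([0, 0, 5, 5], 0.9)]}))
        assert summary.ap is None and summary.ar is None

    def test_toy_set_with_fp_and_miss_matches_reference(self):
        ds = toy_dataset({0: [[0, 0, 50, 80]], 1: [[10, 10, 40, 60]], 2: [[0, 0, 30, 30]]})
        dets = [
            Detection(0, [1.0, 1.0, 50.0, 80.0], 0.9),   # good match
            Detection(1, [200.0, 200.0, 40.0, 60.0], 0.8),  # false positive
            # image 2 ground truth missed entirely
        ]
        summary = ap_ar(ds.annotations, dets)
        gts = [(a.image_id, a.bbox) for a in ds.annotations]
        ref = reference_ap_ar(
            gts, [(d.image_id, d.bbox, d.confidence) for d in dets],
            EvalConfig().ap_iou_grid,
        )
        assert summary.ap == pytest.approx(ref[0], abs=1e-6)
        assert summary.ar == pytest.approx(ref[1], abs=1e-6)


class TestOks:
    def _gt(self, area_side=100.0):
        kps = np.zeros((17, 3))
        kps[:, 0] = np.linspace(10, 90, 17)
        kps[:, 1] = np.linspace(10, 90, 17)
        kps[:, 2] = 2
        return AnnotationRecord(
            id=0, image_id=0, bbox=[0.0, 0.0, area_side, area_side], keypoints=kps
        )

    def test_exact_prediction_is_one(self):
        gt = self._gt()
        assert oks(gt, gt.keypoints[:, :2]) == pytest.approx(1.0, abs=1e-12)

    def test_single_keypoint_closed_form(self):
        kps = np.zeros((17, 3))
        kps[0, :] = [50.0, 50.0, 2.0]
        gt = AnnotationRecord(id=0, image_id=0, bbox=[0.0, 0.0, 100.0, 100.0], keypoints=kps)
        s = np.sqrt(gt.area)
        k = 2.0 * KEYPOINT_SIGMAS[0]
        pred = gt.keypoints[:, :2].copy()
        pred[0, 0] += s * k  # displacement d = s*k -> OKS = exp(-1/2)
        assert oks(gt, pred) == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_far_predictions_vanish(self):
        gt = self._gt()
        pred = gt.keypoints[:, :2] + 10_000.0
        assert oks(gt, pred) < 1e-6

    def test_unlabelled_gt_undefined(self):
        kps = np.zeros((17, 3))
        gt = AnnotationRecord(id=0, image_id=0, bbox=[0.0, 0.0, 10.0, 10.0], keypoints=kps)
        assert oks(gt, kps[:, :2]) is None


class TestAspectLogRatio:
    def test_square_box_is_zero(self):
        v, _, _ = aspect_log_ratio([[0, 0, 7, 7]])
        assert v[0] == 0.0

    def test_two_to_one_wide(self):
        v, _, _ = aspect_log_ratio([[0, 0, 10, 5]])
        assert v[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        boxes = np.column_stack(
            [np.zeros(500), np.zeros(500), rng.uniform(5, 50, 500), rng.uniform(5, 50, 500)]
        )
        _, edges, density = aspect_log_ratio(boxes)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ParameterError):
            aspect_log_ratio([[0, 0, 0, 5]])
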