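"""Detection, segmentation, and endpoint metric definitions."""

import numpy as np
import pytest

from ellipick.ellipse import PlanePoint
from ellipick.metrics import (
    ConfusionCounts,
    DetectionImage,
    DetectionSet,
    EndpointEvalRecord,
    GroundTruthBox,
    PredictedBox,
    angle_error,
    average_precision,
    classification_accuracy,
    distance_error,
    endpoint_label_outcomes,
    evaluate_endpoints,
    mean_average_precision,
    precision_recall,
    segmentation_metrics,
)
from ellipick.pipeline import EndpointPair
from ellipick.synthetic import DetectionSetConfig, generate_detection_set
from oracles import average_precision_oracle


def _pair(head, root) -> EndpointPair:
    return EndpointPair(PlanePoint(*head), PlanePoint(*root), 1.0, 1.0)


class TestPrecisionRecall:
    def test_arithmetic(self):
        p, r = precision_recall(ConfusionCounts(tp=50, fp=10, fn=5))
        assert p == pytest.approx(50 / 60)
        assert r == pytest.approx(50 / 55)

    def test_perfect_counts(self):
        assert precision_recall(ConfusionCounts(tp=7, fp=0, fn=0)) == (1.0, 1.0)

    def test_undefined_precision_is_none_with_warning(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            p, r = precision_recall(ConfusionCounts(tp=0, fp=0, fn=3))
        assert p is None
        assert r == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0)


def _det_set(entries, gts) -> DetectionSet:
    """entries: (confidence, box); gts: boxes — all one class, one image."""
    return DetectionSet(
        images=[
            DetectionImage(
                ground_truth=[GroundTruthBox(0, g) for g in gts],
                predictions=[PredictedBox(0, c, b) for c, b in entries],
            )
        ]
    )


BOX_A = (0.0, 0.0, 10.0, 10.0)
BOX_B = (50.0, 50.0, 60.0, 60.0)
FAR = (200.0, 200.0, 210.0, 210.0)


class TestAveragePrecision:
    def test_single_confident_hit(self):
        d = _det_set([(0.9, (0.0, 0.0, 10.0, 9.0))], [BOX_A])  # IoU 0.9
        assert average_precision(d, 0) == 1.0

    def test_hand_enumerated_staircase(self):
        """Hit at 0.9, miss at 0.8, hit at 0.7 against two truths gives
        AP = 1 * 0.5 + (2/3) * 0.5."""
        d = _det_set([(0.9, BOX_A), (0.8, FAR), (0.7, BOX_B)], [BOX_A, BOX_B])
        assert average_precision(d, 0) == pytest.approx(1 * 0.5 + (2 / 3) * 0.5)

    def test_duplicate_detection_counts_as_fp(self):
        d = _det_set([(0.9, BOX_A), (0.8, BOX_A)], [BOX_A])
        # Second duplicate is a false positive; recall saturates at the first.
        assert average_precision(d, 0) == 1.0
        d2 = _det_set([(0.9, BOX_A), (0.8, BOX_A)], [BOX_A, BOX_B])
        assert average_precision(d2, 0) == pytest.approx(0.5)

    def test_no_ground_truth_returns_none(self):
        d = _det_set([(0.9, BOX_A)], [])
        assert average_precision(d, 0) is None

    def test_no_predictions_gives_zero(self):
        assert average_precision(_det_set([], [BOX_A]), 0) == 0.0

    def test_matches_threshold_enumeration_oracle(self, rng):
        for _ in range(30):
            n_gt = int(rng.integers(1, 6))
            gts = [
                (x, y, x + 10.0, y + 10.0)
                for x, y in rng.uniform(0, 300, (n_gt, 2))
            ]
            preds = []
            for _ in range(int(rng.integers(0, 12))):
                if rng.random() < 0.5 and gts:
                    gx, gy, _, _ = gts[int(rng.integers(0, n_gt))]
                    box = (gx + 1.0, gy + 1.0, gx + 11.0, gy + 11.0)
                else:
                    x, y = rng.uniform(400, 800, 2)
                    box = (x, y, x + 10.0, y + 10.0)
                preds.append((float(rng.random()), box))
            d = _det_set(preds, gts)
            assert average_precision(d, 0) == pytest.approx(
                average_precision_oracle(d, 0), abs=1e-12
            )

    def test_invariant_to_monotone_confidence_transform(self):
        d = _det_set([(0.9, BOX_A), (0.8, FAR), (0.7, BOX_B)], [BOX_A, BOX_B])
        squashed = _det_set(
            [(0.9**4, BOX_A), (0.8**4, FAR), (0.7**4, BOX_B)], [BOX_A, BOX_B]
        )
        assert average_precision(d, 0) == average_precision(squashed, 0)

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            average_precision(_det_set([], [BOX_A]), 0, iou_threshold=1.5)


class TestMeanAveragePrecision:
    def test_mean_over_realized_class_staircases(self):
        cfg = DetectionSetConfig(
            patterns={0: (2, (True, True)), 1: (2, (True, False, True))}
        )
        ds, expected = generate_detection_set(cfg, seed=0)
        assert expected[0] == 1.0
        assert expected[1] == pytest.approx(1 * 0.5 + (2 / 3) * 0.5)
        assert mean_average_precision(ds) == pytest.approx(
            (expected[0] + expected[1]) / 2
        )

    def test_single_class_equals_ap(self):
        ds, expected = generate_detection_set(
            DetectionSetConfig(patterns={0: (3, (True, False, True))}), seed=1
        )
        assert mean_average_precision(ds) == pytest.approx(expected[0])

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            mean_average_precision(DetectionSet(images=[DetectionImage()]))


class TestSegmentationMetrics:
    def test_identical_masks(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[2:6, 2:6] = 1
        rep = segmentation_metrics(m, m)
        assert rep.per_class[0].iou == 1.0
        assert rep.per_class[1].iou == 1.0
        assert rep.miou == 1.0

    def test_all_foreground_versus_half(self):
        pred = np.ones((10, 10), dtype=np.uint8)
        gt = np.zeros((10, 10), dtype=np.uint8)
        gt[:5] = 1
        rep = segmentation_metrics(pred, gt)
        assert rep.per_class[1].iou == pytest.approx(0.5)
        assert rep.per_class[0].iou == 0.0
        assert rep.miou == pytest.approx(0.25)

    def test_confusion_sums_to_pixel_count(self, rng):
        pred = (rng.random((17, 23)) > 0.5).astype(np.uint8)
        gt = (rng.random((17, 23)) > 0.5).astype(np.uint8)
        rep = segmentation_metrics(pred, gt)
        for cls in (0, 1):
            c = rep.per_class[cls].counts
            assert c.tp + c.fp + c.fn + c.tn == 17 * 23

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_metrics(np.zeros((4, 4)), np.zeros((4, 5)))


class TestDistanceError:
    def test_perfect_prediction(self):
        r = EndpointEvalRecord(_pair((3, 4), (10, 10)), _pair((3, 4), (10, 10)))
        assert distance_error(r) == 0.0

    def test_head_off_by_three_four(self):
        r = EndpointEvalRecord(_pair((3, 4), (10, 10)), _pair((0, 0), (10, 10)))
        assert distance_error(r) == pytest.approx(2.5)

    def test_both_endpoints_off_by_two(self):
        r = EndpointEvalRecord(_pair((0, 2), (10, 12)), _pair((0, 0), (10, 10)))
        assert distance_error(r) == pytest.approx(2.0)

    def test_symmetric_under_swap(self, rng):
        for _ in range(20):
            a = _pair(tuple(rng.uniform(0, 100, 2)), tuple(rng.uniform(0, 100, 2)))
            b = _pair(tuple(rng.uniform(0, 100, 2)), tuple(rng.uniform(0, 100, 2)))
            fwd = distance_error(EndpointEvalRecord(a, b))
            rev = distance_error(EndpointEvalRecord(b, a))
            assert fwd == pytest.approx(rev)
            assert fwd >= 0.0


class TestAngleError:
    def test_identical_axes(self):
        r = EndpointEvalRecord(_pair((0, 0), (10, 5)), _pair((2, 1), (12, 6)))
        assert angle_error(r) == pytest.approx(0.0)

    def test_small_offset(self):
        truth = _pair((np.cos(np.radians(10)) * 10, np.sin(np.radians(10)) * 10), (0, 0))
        pred = _pair((np.cos(np.radians(14.3)) * 10, np.sin(np.radians(14.3)) * 10), (0, 0))
        assert angle_error(EndpointEvalRecord(pred, truth)) == pytest.approx(4.3, abs=1e-9)

    def test_wraparound_near_180(self):
        truth = _pair((np.cos(np.radians(179)) * 10, np.sin(np.radians(179)) * 10), (0, 0))
        pred = _pair((np.cos(np.radians(1)) * 10, np.sin(np.radians(1)) * 10), (0, 0))
        assert angle_error(EndpointEvalRecord(pred, truth)) == pytest.approx(2.0, abs=1e-9)

    def test_bounded_on_random_records(self, rng):
        for _ in range(100):
            r = EndpointEvalRecord(
                _pair(tuple(rng.uniform(0, 50, 2)), tuple(rng.uniform(50, 100, 2))),
                _pair(tuple(rng.uniform(0, 50, 2)), tuple(rng.uniform(50, 100, 2))),
            )
            assert 0.0 <= angle_error(r) <= 90.0


class TestClassificationAccuracy:
    def test_all_correct(self):
        assert classification_accuracy([True] * 10) == 1.0

    def test_92_of_100(self):
        assert classification_accuracy([True] * 92 + [False] * 8) == pytest.approx(0.92)

    def test_half(self):
        assert classification_accuracy([True, False]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_accuracy([])

    def test_label_outcomes_detect_swap(self):
        truth = _pair((0, 0), (100, 100))
        swapped = EndpointEvalRecord(_pair((99, 99), (1, 1)), truth)
        assert endpoint_label_outcomes(swapped) == (False, False)
        correct = EndpointEvalRecord(_pair((1, 1), (99, 99)), truth)
        assert endpoint_label_outcomes(correct) == (True, True)


class TestEvaluateEndpoints:
    def test_aggregates_over_records(self):
        truth = _pair((0, 0), (10, 0))
        records = [
            EndpointEvalRecord(_pair((0, 2), (10, 2)), truth),  # DE 2, AE 0
            EndpointEvalRecord(_pair((9, -1), (1, 1)), truth),  # labels swapped
        ]
        de, ae, ca = evaluate_endpoints(records)
        assert de > 0
        assert 0.0 <= ae <= 90.0
        assert ca == pytest.approx(0.5)
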