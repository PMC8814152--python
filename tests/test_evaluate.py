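"""Metric conventions: one-vs-rest classification, ROC/AUC, pixel and
detection metrics, and the rounding/aggregation used for reporting."""

import numpy as np
import pytest

from jawdx.evaluate import (ConfusionMatrix, bbox_from_mask, box_iou,
                            class_metrics, confusion_from_predictions,
                            detection_metrics, f1_score, macro_mean,
                            roc_auc, round2, segmentation_metrics)


class TestClassMetrics:
    def test_perfect_diagonal_gives_100(self):
        cm = ConfusionMatrix(np.diag([5, 3, 2]), ("a", "b", "c"))
        out = class_metrics(cm)
        for cls in ("a", "b", "c"):
            for metric, value in out["per_class"][cls].items():
                assert value == 100.0, (cls, metric)

    def test_hand_counted_three_class(self):
        # rows = truth: class 0 has TP=2, FN=1, FP=0
        cm = ConfusionMatrix([[2, 1, 0], [0, 2, 0], [0, 0, 1]],
                             ("a", "b", "c"))
        out = class_metrics(cm)["per_class"]["a"]
        assert out["precision"] == 100.0
        assert out["sensitivity"] == pytest.approx(66.67)
        assert out["accuracy"] == pytest.approx(round2(100 * 5 / 6))

    def test_f1_identity(self):
        assert f1_score(68.18, 71.43) == 69.77

    def test_zero_denominator_flagged_not_nan(self):
        cm = ConfusionMatrix([[0, 0], [3, 2]], ("a", "b"))
        out = class_metrics(cm)
        assert out["per_class"]["a"]["precision"] == 0.0
        assert any("a." in f for f in out["undefined"])

    def test_macro_mean_is_unweighted(self):
        assert macro_mean([86.32, 88.89, 91.45, 91.45, 85.47]) == 88.72


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (62.585, 62.59),   # half-up at the 3rd decimal
        (68.105, 68.11),
        (92.656, 92.66),
        (1.0, 1.0),
        (66.138, 66.14),
    ])
    def test_half_up(self, x, expected):
        assert round2(x) == expected


def brute_force_auc(scores, labels):
    """Pair-counting statistic: P(random positive outscores random negative),
    ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([[0.9], [0.8], [0.2], [0.1]])
        labels = np.array([0, 0, 1, 1])  # class index 0 is positive
        out = roc_auc(scores, labels, classes=("x",))
        assert out["x"]["auc"] == pytest.approx(1.0)

    def test_derived_three_quarter_example(self):
        # pos {0.9, 0.4}, neg {0.6, 0.1}: 3 of 4 pairs ordered correctly
        scores = np.array([[0.9], [0.4], [0.6], [0.1]])
        labels = np.array([0, 0, 1, 1])
        out = roc_auc(scores, labels, classes=("x",))
        assert out["x"]["auc"] == pytest.approx(0.75)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.random((20, 2))
        labels = rng.integers(0, 2, size=20)
        base = roc_auc(scores, labels, ("a", "b"))["a"]["auc"]
        perm = rng.permutation(20)
        out = roc_auc(scores[perm], labels[perm], ("a", "b"))["a"]["auc"]
        assert out == pytest.approx(base)

    def test_single_class_flagged(self):
        out = roc_auc(np.array([[0.5], [0.6]]), np.array([0, 0]), ("x",))
        assert out["x"]["auc"] is None and out["x"]["undefined"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        scores = np.round(rng.random((n, 1)), 2)  # induce ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        out = roc_auc(scores, labels, ("pos",))
        # class index 0 is "positive" when label == 0
        expected = brute_force_auc(scores[:, 0], (labels == 0).astype(int))
        assert out["pos"]["auc"] == pytest.approx(expected, abs=1e-9)


class TestSegmentationMetrics:
    def test_exact_prediction(self):
        mask = np.zeros((10, 10))
        mask[2:5, 2:5] = 1
        out = segmentation_metrics([mask], [mask], ["DC"])
        assert out["per_category"]["DC"]["iou"] == 100.0
        assert out["per_category"]["DC"]["sensitivity"] == 100.0

    def test_half_overlap_iou_one_third(self):
        # pred = upper half, truth = left half of a square frame
        pred = np.zeros((8, 8))
        pred[:4, :] = 1
        true = np.zeros((8, 8))
        true[:, :4] = 1
        out = segmentation_metrics([pred], [true], ["DC"])
        assert out["per_category"]["DC"]["iou"] == pytest.approx(
            round2(100 / 3))

    def test_empty_prediction(self):
        true = np.zeros((6, 6))
        true[1:3, 1:3] = 1
        out = segmentation_metrics([np.zeros((6, 6))], [true], ["PC"])
        assert out["per_category"]["PC"]["sensitivity"] == 0.0
        assert out["per_category"]["PC"]["iou"] == 0.0

    def test_empty_truth_skipped_with_flag(self):
        out = segmentation_metrics([np.ones((4, 4))], [np.zeros((4, 4))],
                                   ["AB"])
        assert out["skipped_empty_truth"] == ["AB"]
        assert "AB" not in out["per_category"]

    def test_macro_row_averages_categories(self):
        m1 = np.zeros((8, 8)); m1[:4] = 1
        m2 = np.zeros((8, 8)); m2[:, :4] = 1
        out = segmentation_metrics([m1, m2], [m1, m2], ["DC", "PC"])
        assert out["macro"]["iou"] == 100.0


class TestBboxFromMask:
    def test_single_block_tight_half_open_box(self):
        mask = np.zeros((32, 32))
        mask[5:15, 5:15] = 1
        boxes = bbox_from_mask(mask, min_area=20)
        assert len(boxes) == 1
        assert boxes[0][:4] == (5, 5, 15, 15)

    def test_empty_mask_empty_list(self):
        assert bbox_from_mask(np.zeros((8, 8))) == []

    def test_two_disjoint_blocks(self):
        mask = np.zeros((32, 32))
        mask[2:10, 2:10] = 1
        mask[20:30, 20:30] = 1
        assert len(bbox_from_mask(mask, min_area=20)) == 2

    def test_small_components_discarded(self):
        mask = np.zeros((32, 32))
        mask[0, 0] = 1
        mask[10:20, 10:20] = 1
        assert len(bbox_from_mask(mask, min_area=20)) == 1

    def test_confidence_is_mean_soft_probability(self):
        mask = np.zeros((16, 16))
        mask[0:5, 0:5] = 1
        soft = np.where(mask > 0, 0.8, 0.1)
        boxes = bbox_from_mask(mask, soft_mask=soft, min_area=5)
        assert boxes[0][4] == pytest.approx(0.8)


class TestDetectionMetrics:
    def test_exact_match(self):
        out = detection_metrics([[(0, 0, 10, 10, 0.9)]], [[(0, 0, 10, 10)]])
        assert out["ap"] == 100.0
        assert out["iou"] == 100.0
        assert out["precision"] == 100.0

    def test_box_iou_derived_example(self):
        assert box_iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_fp_then_tp_gives_ap_50(self):
        preds = [[(50, 50, 60, 60, 0.9), (0, 0, 10, 10, 0.8)]]
        gts = [[(0, 0, 10, 10)]]
        out = detection_metrics(preds, gts)
        assert out["ap"] == 50.0

    def test_appending_false_positives_never_raises_ap(self):
        gts = [[(0, 0, 10, 10)]]
        base = detection_metrics([[(0, 0, 10, 10, 0.9)]], gts)["ap"]
        worse = detection_metrics(
            [[(0, 0, 10, 10, 0.9), (30, 30, 40, 40, 0.5),
              (60, 60, 70, 70, 0.4)]], gts)["ap"]
        assert worse <= base

    def test_each_truth_matched_at_most_once(self):
        preds = [[(0, 0, 10, 10, 0.9), (0, 0, 10, 10, 0.8)]]
        gts = [[(0, 0, 10, 10)]]
        out = detection_metrics(preds, gts)
        assert out["sensitivity"] == 100.0
        assert out["precision"] == 50.0


class TestConfusionConstruction:
    def test_counts_and_total(self):
        cm = confusion_from_predictions([0, 0, 1, 1, 1], [0, 1, 1, 1, 0],
                                        ("a", "b"))
        np.testing.assert_array_equal(cm.counts, [[1, 1], [1, 2]])
        assert cm.total == 5
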