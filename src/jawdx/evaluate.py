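"""Classification, segmentation and detection metrics.

Classification metrics are one-vs-rest per class from a confusion matrix
(rows = truth, columns = prediction): accuracy (TP+TN)/total, precision
TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(TN+FP), and F1; the macro
row is the unweighted mean over classes.  ROC/AUC is one-vs-rest on softmax
scores.  Pixel segmentation metrics pool TP/FP/TN/FN over all samples of a
category; detection converts masks to connected-component bounding boxes and
scores them with greedy IoU matching and all-point interpolated average
precision.

All percentages are computed in double precision and reported at two
decimals, rounded half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from skimage.measure import label as cc_label, regionprops
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionMatrix", "MetricsReport", "round2", "macro_mean", "f1_score",
    "confusion_from_predictions", "class_metrics", "roc_auc",
    "segmentation_metrics", "bbox_from_mask", "box_iou", "detection_metrics",
    "evaluate_model",
]


def round2(x: float) -> float:
    """Round to 2 decimals, half-up (the reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def macro_mean(values) -> float:
    """Unweighted mean over classes, reported at 2 decimals."""
    return round2(float(np.mean(np.asarray(values, dtype=np.float64))))


def f1_score(precision_pct: float, sensitivity_pct: float) -> float:
    """F1 (percent) from precision/sensitivity percentages."""
    p, r = float(precision_pct), float(sensitivity_pct)
    if p + r <= 0:
        return 0.0
    return round2(2.0 * p * r / (p + r))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray          # (n, n) ints, rows = truth
    classes: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.classes)
        if self.counts.shape != (n, n) or np.any(self.counts < 0):
            raise ValueError("invalid confusion matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_from_predictions(y_true, y_pred, classes) -> ConfusionMatrix:
    classes = tuple(classes)
    n = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[idx[t] if isinstance(t, str) else t,
               idx[p] if isinstance(p, str) else p] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def _safe_pct(num, den, flags, name):
    if den == 0:
        flags.append(name)
        return 0.0
    return 100.0 * num / den


def class_metrics(confusion: ConfusionMatrix) -> dict:
    """One-vs-rest per-class metrics (percent, 2 decimals) plus macro means.

    Zero-denominator metrics are reported as 0 and listed under
    ``"undefined"`` rather than returned as NaN.
    """
    c = confusion.counts
    total = c.sum()
    per_class = {}
    flags: list = []
    for i, name in enumerate(confusion.classes):
        tp = c[i, i]
        fn = c[i].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        acc = _safe_pct(tp + tn, total, flags, f"{name}.accuracy")
        prec = _safe_pct(tp, tp + fp, flags, f"{name}.precision")
        sens = _safe_pct(tp, tp + fn, flags, f"{name}.sensitivity")
        spec = _safe_pct(tn, tn + fp, flags, f"{name}.specificity")
        per_class[name] = {
            "accuracy": round2(acc), "precision": round2(prec),
            "sensitivity": round2(sens), "specificity": round2(spec),
            "f1": f1_score(round2(prec), round2(sens)),
        }
    macro = {metric: macro_mean([per_class[c][metric]
                                 for c in confusion.classes])
             for metric in ("accuracy", "precision", "sensitivity",
                            "specificity", "f1")}
    return {"per_class": per_class, "macro": macro, "undefined": flags}


def roc_auc(scores: np.ndarray, labels, classes) -> dict:
    """One-vs-rest ROC curves and AUC per class.

    ``scores`` is (N, n_classes) softmax probabilities.  AUC equals the
    probability that a random positive outscores a random negative (ties
    count one half); classes absent from (or covering all of) the labels get
    ``auc=None`` with a flag.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    out = {}
    for i, name in enumerate(classes):
        pos = labels == (name if labels.dtype.kind == "U" else i)
        if pos.all() or not pos.any():
            out[name] = {"auc": None, "undefined": True}
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), scores[:, i])
        out[name] = {"auc": float(np.trapezoid(tpr, fpr)),
                     "fpr": fpr.tolist(), "tpr": tpr.tolist(),
                     "undefined": False}
    return out


def segmentation_metrics(pred_masks, true_masks, categories) -> dict:
    """Pixel metrics pooled within category, plus the macro-mean row.

    Only lesion samples belong here; a lesion sample with an empty
    ground-truth mask is skipped with a flag.
    """
    pools: dict = {}
    skipped = []
    for pred, true, cat in zip(pred_masks, true_masks, categories):
        true = np.asarray(true) > 0
        if not true.any():
            skipped.append(cat)
            continue
        pred = np.asarray(pred) >= 0.5
        tp = int((pred & true).sum())
        fp = int((pred & ~true).sum())
        fn = int((~pred & true).sum())
        tn = int((~pred & ~true).sum())
        agg = pools.setdefault(cat, [0, 0, 0, 0])
        agg[0] += tp; agg[1] += fp; agg[2] += fn; agg[3] += tn
    per_cat = {}
    flags: list = []
    for cat, (tp, fp, fn, tn) in pools.items():
        per_cat[cat] = {
            "pixel_accuracy": round2(_safe_pct(tp + tn, tp + fp + fn + tn,
                                               flags, f"{cat}.pixel_accuracy")),
            "sensitivity": round2(_safe_pct(tp, tp + fn, flags,
                                            f"{cat}.sensitivity")),
            "specificity": round2(_safe_pct(tn, tn + fp, flags,
                                            f"{cat}.specificity")),
            "iou": round2(_safe_pct(tp, tp + fp + fn, flags, f"{cat}.iou")),
        }
    macro = {}
    if per_cat:
        macro = {m: macro_mean([v[m] for v in per_cat.values()])
                 for m in ("pixel_accuracy", "sensitivity", "specificity",
                           "iou")}
    return {"per_category": per_cat, "macro": macro,
            "skipped_empty_truth": skipped, "undefined": flags}


def bbox_from_mask(binary_mask, soft_mask=None, min_area: int = 20) -> list:
    """Connected components (8-connectivity) to confidence-scored boxes.

    Boxes are (x0, y0, x1, y1) half-open; confidence is the mean soft-mask
    probability within the component (1.0 if no soft mask).  Components
    smaller than ``min_area`` pixels are discarded.
    """
    mask = np.asarray(binary_mask) > 0
    if not mask.any():
        return []
    lab = cc_label(mask, connectivity=2)
    boxes = []
    for region in regionprops(lab):
        if region.area < min_area:
            continue
        y0, x0, y1, x1 = region.bbox
        if soft_mask is None:
            conf = 1.0
        else:
            conf = float(np.asarray(soft_mask)[lab == region.label].mean())
        boxes.append((int(x0), int(y0), int(x1), int(y1), conf))
    return boxes


def box_iou(a, b) -> float:
    ax0, ay0, ax1, ay1 = a[:4]
    bx0, by0, bx1, by1 = b[:4]
    iw = max(0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    if inter == 0:
        return 0.0
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def detection_metrics(pred_boxes_per_sample, gt_boxes_per_sample,
                      iou_threshold: float = 0.5) -> dict:
    """AP, precision, sensitivity and mean matched IoU for one category.

    Predictions are ranked by confidence across samples and matched greedily
    to unmatched ground truths of the same sample at IoU >= threshold; AP is
    the area under the all-point interpolated precision-recall curve.
    """
    entries = []
    n_gt = 0
    for si, (preds, gts) in enumerate(zip(pred_boxes_per_sample,
                                          gt_boxes_per_sample)):
        n_gt += len(gts)
        for box in preds:
            entries.append((float(box[4]) if len(box) > 4 else 1.0, si, box))
    entries.sort(key=lambda e: (-e[0], e[1]))
    matched: dict = {}
    tp_flags, ious = [], []
    for conf, si, box in entries:
        best_iou, best_j = 0.0, None
        for j, gt in enumerate(gt_boxes_per_sample[si]):
            if (si, j) in matched:
                continue
            iou = box_iou(box, gt)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j is not None and best_iou >= iou_threshold:
            matched[(si, best_j)] = True
            tp_flags.append(1)
            ious.append(best_iou)
        else:
            tp_flags.append(0)
    tp_flags = np.asarray(tp_flags, dtype=np.float64)
    n_pred = len(tp_flags)
    tp_total = tp_flags.sum()
    precision_pct = 100.0 * tp_total / n_pred if n_pred else 0.0
    sensitivity_pct = 100.0 * tp_total / n_gt if n_gt else 0.0
    if n_gt == 0 or n_pred == 0:
        ap = 0.0
    else:
        cum_tp = np.cumsum(tp_flags)
        recall = cum_tp / n_gt
        precision = cum_tp / np.arange(1, n_pred + 1)
        # all-point interpolation: precision envelope integrated over recall
        env = np.maximum.accumulate(precision[::-1])[::-1]
        r_prev, ap = 0.0, 0.0
        for r, p in zip(recall, env):
            ap += (r - r_prev) * p
            r_prev = r
        ap *= 100.0
    return {"ap": round2(ap), "precision": round2(precision_pct),
            "sensitivity": round2(sensitivity_pct),
            "iou": round2(100.0 * float(np.mean(ious))) if ious else 0.0,
            "n_predictions": n_pred, "n_ground_truth": n_gt}


@dataclass
class MetricsReport:
    """Everything the evaluation stage computes, JSON-serialisable."""

    classification: dict
    auc: dict
    segmentation: dict
    detection: dict
    n_samples: int
    mode: str
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"mode": self.mode, "n_samples": self.n_samples,
                "classification": self.classification, "auc": self.auc,
                "segmentation": self.segmentation, "detection": self.detection,
                "extras": self.extras}


def evaluate_model(predict_fn, samples, classes, min_area: int = 20,
                   iou_threshold: float = 0.5, mode: str = "five_class"
                   ) -> MetricsReport:
    """Run ``predict_fn(image) -> Prediction`` over samples and assemble the
    full report (classification + ROC/AUC + pixel + detection metrics)."""
    classes = tuple(classes)
    label_of = {c: i for i, c in enumerate(classes)}

    def as_label(category):
        if category in label_of:
            return label_of[category]
        return label_of["lesion"]  # binary mode folds lesion categories

    y_true, y_pred, scores = [], [], []
    seg_pred, seg_true, seg_cats = [], [], []
    det_pred: dict = {}
    det_gt: dict = {}
    for s in samples:
        pred = predict_fn(s.image)
        y_true.append(as_label(s.category))
        y_pred.append(int(np.argmax(pred.probs)))
        scores.append(pred.probs)
        if s.category != "healthy":
            seg_pred.append(pred.mask)
            seg_true.append(s.mask)
            seg_cats.append(s.category)
            det_pred.setdefault(s.category, []).append(pred.boxes)
            gt_boxes = bbox_from_mask(s.mask, min_area=1)
            det_gt.setdefault(s.category, []).append(gt_boxes)
    confusion = confusion_from_predictions(y_true, y_pred, classes)
    detection = {cat: detection_metrics(det_pred[cat], det_gt[cat],
                                        iou_threshold=iou_threshold)
                 for cat in sorted(det_pred)}
    if detection:
        det_macro = {m: macro_mean([v[m] for v in detection.values()])
                     for m in ("ap", "precision", "sensitivity", "iou")}
    else:
        det_macro = {}
    accuracy = 100.0 * np.mean(np.asarray(y_true) == np.asarray(y_pred))
    return MetricsReport(
        classification=class_metrics(confusion),
        auc=roc_auc(np.asarray(scores), np.asarray(y_true), classes),
        segmentation=segmentation_metrics(seg_pred, seg_true, seg_cats),
        detection={"per_category": detection, "macro": det_macro},
        n_samples=len(samples), mode=mode,
        extras={"overall_accuracy": round2(float(accuracy)),
                "confusion": confusion.counts.tolist()})
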