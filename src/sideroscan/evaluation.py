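"""Detection and agreement metrics.

Object detection is scored with PASCAL-VOC-style average precision at IoU
0.5 (all-point precision-envelope interpolation by default, the 11-point
variant by flag) and its unweighted mean over the five grades.  Rater
agreement uses exact concordance, Cohen's kappa (two raters), Fleiss' kappa
(many raters) and one-vs-rest F1 per grade; slide-level accuracy uses the
absolute THS error.  ``hypothetical_map`` converts a grading confusion
matrix into the mAP an otherwise perfect detector would reach with that
grading behavior (per-class AP collapses to precision x recall when every
detection has unit confidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .annotations import GRADES, GradeCounts
from .detector import Detection, box_iou_matrix
from .scoring import total_hemosiderin_score


@dataclass
class RatingMatrix:
    """Integer grades: cells x raters x repeats, with rater group labels."""

    grades: np.ndarray  # (n_cells, n_raters, n_repeats)
    rater_groups: list[str] = field(default_factory=list)
    repeat_labels: tuple = ("V0", "V1")

    def __post_init__(self) -> None:
        g = np.asarray(self.grades)
        if g.ndim != 3:
            raise ValueError("grades must be cells x raters x repeats")
        if g.min() < 0 or g.max() > 4:
            raise ValueError("grades must lie in 0..4")
        self.grades = g.astype(int)

    def ratings(self, rater: int, repeat: int = 0) -> np.ndarray:
        return self.grades[:, rater, repeat]

    def category_counts(self, repeat: int = 0) -> np.ndarray:
        """cells x 5 table of how many raters chose each grade."""
        g = self.grades[:, :, repeat]
        counts = np.zeros((g.shape[0], 5), dtype=int)
        for k in GRADES:
            counts[:, k] = (g == k).sum(axis=1)
        return counts


@dataclass
class PRCurve:
    """Sorted-confidence precision/recall curve with its AP."""

    confidences: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    ap: float
    n_truth: int


def _boxes_center(items) -> np.ndarray:
    out = np.empty((len(items), 4))
    for i, b in enumerate(items):
        x, y, w, h = b
        out[i] = (x + w / 2, y + h / 2, w, h)
    return out


def average_precision(detections, truths, iou_threshold: float = 0.5,
                      eleven_point: bool = False) -> PRCurve:
    """Single-class VOC average precision.

    ``detections`` are ``Detection`` objects or ``(box, confidence)``
    pairs, ``truths`` corner-form boxes.  Detections are matched greedily
    in order of descending confidence to the highest-IoU unmatched truth
    at IoU >= threshold; duplicates count as false positives.
    """
    pairs = []
    for d in detections:
        if isinstance(d, Detection):
            pairs.append((d.box, d.confidence))
        else:
            pairs.append((d[0], d[1]))
    n_truth = len(truths)
    if not pairs:
        return PRCurve(np.zeros(0), np.zeros(0), np.zeros(0), 0.0, n_truth)
    order = sorted(range(len(pairs)), key=lambda i: (-pairs[i][1], i))
    det_boxes = _boxes_center([pairs[i][0] for i in order])
    confs = np.array([pairs[i][1] for i in order])
    truth_boxes = _boxes_center(list(truths)) if n_truth else np.zeros((0, 4))
    iou = box_iou_matrix(det_boxes, truth_boxes)
    matched = np.zeros(n_truth, dtype=bool)
    tp = np.zeros(len(order))
    for i in range(len(order)):
        if n_truth == 0:
            continue
        cand = np.where(~matched, iou[i], -1.0)
        j = int(cand.argmax())
        if cand[j] >= iou_threshold:
            matched[j] = True
            tp[i] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(order) + 1)
    recall = cum_tp / n_truth if n_truth else np.zeros(len(order))
    ap = _area_under_envelope(precision, recall, eleven_point)
    return PRCurve(confs, precision, recall, ap, n_truth)


def _area_under_envelope(precision: np.ndarray, recall: np.ndarray,
                         eleven_point: bool) -> float:
    if len(precision) == 0:
        return 0.0
    if eleven_point:
        ap = 0.0
        for r in np.linspace(0, 1, 11):
            mask = recall >= r
            ap += precision[mask].max() if mask.any() else 0.0
        return ap / 11.0
    r = np.concatenate(([0.0], recall, [recall[-1] if len(recall) else 0.0]))
    p = np.concatenate(([0.0], precision, [0.0]))
    # precision envelope (non-increasing from the right)
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def mean_average_precision(curves: dict[int, PRCurve]) -> tuple[float, list[int]]:
    """Unweighted mean AP over grades with ground truth; returns excluded grades."""
    included = [g for g, c in curves.items() if c.n_truth > 0]
    excluded = [g for g in curves if curves[g].n_truth == 0]
    if not included:
        raise ValueError("no grade has ground-truth instances")
    return float(np.mean([curves[g].ap for g in included])), excluded


def evaluate_detections(detections, truth_cells, iou_threshold: float = 0.5,
                        eleven_point: bool = False) -> dict:
    """Per-grade AP and mAP for Detection lists against CellAnnotations."""
    curves = {}
    for g in GRADES:
        dets_g = [d for d in detections if d.grade_class == g]
        truths_g = [c.box_xywh for c in truth_cells if c.grade == g]
        curves[g] = average_precision(dets_g, truths_g, iou_threshold, eleven_point)
    try:
        m, excluded = mean_average_precision(curves)
    except ValueError:
        m, excluded = float("nan"), list(GRADES)
    return {"per_grade": curves, "map": m, "excluded_grades": excluded}


# ---------------------------------------------------------------------------
# agreement statistics


def concordance(pred, true) -> float:
    """Fraction of exact grade matches."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("length mismatch between rating vectors")
    if pred.size == 0:
        raise ValueError("empty rating vectors")
    return float((pred == true).mean())


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Chance-corrected two-rater agreement over grades 0..4.

    Returns NaN when expected agreement is 1 (both raters constant and
    equal), where the statistic is undefined.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError("length mismatch between rating vectors")
    n = a.size
    pa = np.array([(a == g).mean() for g in GRADES])
    pb = np.array([(b == g).mean() for g in GRADES])
    p_e = float(pa @ pb)
    if abs(1.0 - p_e) < 1e-12:
        return float("nan")
    return float(cohen_kappa_score(a, b, labels=list(GRADES)))


def fleiss_kappa(table) -> float:
    """Fleiss' kappa from a cells x 5 category-count table.

    Every cell must be rated by the same number (>= 2) of raters.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be cells x categories")
    row_sums = t.sum(axis=1)
    if not np.all(row_sums == row_sums[0]):
        raise ValueError("unequal rater counts per cell")
    if row_sums[0] < 2:
        raise ValueError("need at least 2 raters per cell")
    return float(_sm_fleiss_kappa(t, method="fleiss"))


def per_grade_f1(pred, true) -> list[float | None]:
    """One-vs-rest F1 per grade; None where the grade has neither support
    nor predictions (undefined, not zero)."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    _, _, f1, support = precision_recall_fscore_support(
        true, pred, labels=list(GRADES), zero_division=0
    )
    out: list[float | None] = []
    for g in GRADES:
        if support[g] == 0 and not np.any(pred == g):
            out.append(None)
        else:
            out.append(float(f1[g]))
    return out


def per_grade_f1_over_raters(preds_by_rater, true) -> dict[int, tuple[float, float]]:
    """Mean and SD of each grade's F1 across raters (defined values only)."""
    per_rater = [per_grade_f1(p, true) for p in preds_by_rater]
    out = {}
    for g in GRADES:
        vals = [f[g] for f in per_rater if f[g] is not None]
        if vals:
            out[g] = (float(np.mean(vals)), float(np.std(vals)))
    return out


def ths_error(gt_counts: list[GradeCounts], pred_counts: list[GradeCounts]
              ) -> tuple[float, float]:
    """Mean and SD (population) of per-slide absolute THS differences."""
    if len(gt_counts) != len(pred_counts):
        raise ValueError("slide lists must align")
    errs = np.array([
        abs(total_hemosiderin_score(g) - total_hemosiderin_score(p))
        for g, p in zip(gt_counts, pred_counts)
    ], dtype=float)
    return float(errs.mean()), float(errs.std())


def hypothetical_map(confusion: np.ndarray) -> float:
    """mAP of a perfect detector with the given 5x5 grading confusion.

    With every cell detected at its true location with unit confidence,
    each class's all-point AP reduces to precision_c x recall_c.  Classes
    without ground truth are excluded from the mean.
    """
    m = np.asarray(confusion, dtype=float)
    if m.shape != (5, 5):
        raise ValueError("confusion matrix must be 5x5 (true x predicted)")
    aps = []
    for c in GRADES:
        support = m[c].sum()
        if support == 0:
            continue
        predicted = m[:, c].sum()
        recall = m[c, c] / support
        precision = m[c, c] / predicted if predicted > 0 else 0.0
        aps.append(precision * recall)
    if not aps:
        raise ValueError("no class has ground-truth instances")
    return float(np.mean(aps))
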