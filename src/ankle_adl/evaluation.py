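"""Event-level validation statistics.

Predicted and ground-truth segments of one activity are paired one-to-one
by temporal overlap (an optimal assignment).  From the matching come event-level counts
(TP = matched pairs, FN = unmatched truth, FP = unmatched predictions),
sensitivity, the F-score ``2TP / (2TP + FN + FP)``, and the per-pair
absolute duration difference dT = |T_truth - T_pred| with its median and
boxplot-outlier fraction.  Specificity is computed on the per-sample
(frame) complement, the only well-posed notion of a true negative for
event detection.  A 4x4 confusion matrix reports, for each pair of
activities (A, B), the percentage of truth-A events overlapping at least
one predicted-B segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .types import ActivityLabel, ANNOTATION_LABELS, Segment, SegmentSet

#: Row/column order of the confusion matrix.
CONFUSION_ORDER = ANNOTATION_LABELS


@dataclass(frozen=True)
class EventMatching:
    """One-to-one pairing between truth and predicted segments."""

    pairs: tuple[tuple[Segment, Segment], ...]
    unmatched_truth: tuple[Segment, ...]
    unmatched_pred: tuple[Segment, ...]


@dataclass(frozen=True)
class EvaluationResult:
    """Event-level detection and segmentation statistics for one activity.

    Percentages are on the 0-100 scale; ``tn`` counts frames, not events.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity_pct: float
    specificity_pct: float
    fscore_pct: float
    delta_t: tuple[float, ...] = ()
    delta_t_median_s: float = float("nan")
    outlier_pct: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "fscore_pct": self.fscore_pct,
            "delta_t_median_s": self.delta_t_median_s,
            "outlier_pct": self.outlier_pct,
        }


def match_events(truth: SegmentSet, pred: SegmentSet,
                 min_overlap_fraction: float = 0.0) -> EventMatching:
    """Optimal one-to-one matching by temporal overlap.

    A pair is admissible when its overlap is positive and at least
    ``min_overlap_fraction`` of the shorter segment's duration.  Among all
    one-to-one assignments the matching maximises the number of admissible
    pairs first and their total overlap second (a greedy pass by
    descending overlap can strand a segment that an optimal assignment
    would pair).  Deterministic for a given input.
    """
    if truth.label is not pred.label:
        raise ValidationError(
            f"cannot match {truth.label} truth against {pred.label} predictions")
    nt, np_ = len(truth), len(pred)
    if nt == 0 or np_ == 0:
        return EventMatching(pairs=(), unmatched_truth=truth.segments,
                             unmatched_pred=pred.segments)
    overlap = np.zeros((nt, np_))
    for i, t in enumerate(truth):
        for j, p in enumerate(pred):
            ov = t.overlap(p)
            if ov > 0 and ov >= min_overlap_fraction * min(t.duration, p.duration):
                overlap[i, j] = ov
    # a large per-pair bonus makes cardinality dominate total overlap
    bonus = overlap.sum() + 1.0
    weight = np.where(overlap > 0, overlap + bonus, 0.0)
    rows, cols = linear_sum_assignment(weight, maximize=True)
    used_t: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for i, j in zip(rows, cols):
        if overlap[i, j] > 0:
            used_t.add(int(i))
            used_p.add(int(j))
            pairs.append((truth.segments[i], pred.segments[j]))
    pairs.sort(key=lambda tp: tp[0].start)
    return EventMatching(
        pairs=tuple(pairs),
        unmatched_truth=tuple(t for i, t in enumerate(truth) if i not in used_t),
        unmatched_pred=tuple(p for j, p in enumerate(pred) if j not in used_p),
    )


def delta_t_stats(matching: EventMatching,
                  ) -> tuple[tuple[float, ...], float, float]:
    """Per-pair absolute duration differences, their median, and the
    percentage of boxplot outliers (beyond 1.5 x IQR from the quartiles).

    With zero pairs the list is empty and median/fraction are NaN.
    """
    deltas = tuple(abs(t.duration - p.duration) for t, p in matching.pairs)
    if not deltas:
        return (), float("nan"), float("nan")
    arr = np.asarray(deltas)
    median = float(np.median(arr))
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    n_out = int(np.sum((arr > q3 + 1.5 * iqr) | (arr < q1 - 1.5 * iqr)))
    return deltas, median, 100.0 * n_out / arr.size


def event_metrics(matching: EventMatching, frame_truth: np.ndarray,
                  frame_pred: np.ndarray) -> EvaluationResult:
    """Detection statistics from an event matching plus frame masks.

    ``frame_truth`` / ``frame_pred`` are boolean per-sample occupancy masks
    for the activity, aligned to the recording grid.  With no truth and no
    predicted events all rates are reported as 100% by convention.
    """
    frame_truth = np.asarray(frame_truth, dtype=bool)
    frame_pred = np.asarray(frame_pred, dtype=bool)
    if frame_truth.shape != frame_pred.shape:
        raise ValidationError("frame masks must have identical length")
    tp = len(matching.pairs)
    fn = len(matching.unmatched_truth)
    fp = len(matching.unmatched_pred)
    tn = int(np.sum(~frame_truth & ~frame_pred))
    fp_frames = int(np.sum(~frame_truth & frame_pred))
    sens = 100.0 * tp / (tp + fn) if tp + fn else 100.0
    spec = 100.0 * tn / (tn + fp_frames) if tn + fp_frames else 100.0
    fscore = 100.0 * 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp else 100.0
    deltas, median, out_pct = delta_t_stats(matching)
    return EvaluationResult(tp=tp, fp=fp, fn=fn, tn=tn,
                            sensitivity_pct=sens, specificity_pct=spec,
                            fscore_pct=fscore, delta_t=deltas,
                            delta_t_median_s=median, outlier_pct=out_pct)


def confusion_matrix(truth_all: dict[ActivityLabel, SegmentSet],
                     pred_all: dict[ActivityLabel, SegmentSet]) -> np.ndarray:
    """4x4 matrix of percentages: cell (A, B) is the share of truth-A
    events whose span overlaps at least one predicted-B segment."""
    mat = np.zeros((len(CONFUSION_ORDER), len(CONFUSION_ORDER)))
    for i, a in enumerate(CONFUSION_ORDER):
        truth = truth_all.get(a, SegmentSet(a))
        if len(truth) == 0:
            continue
        for j, b in enumerate(CONFUSION_ORDER):
            pred = pred_all.get(b, SegmentSet(b))
            hit = sum(1 for t in truth
                      if any(t.overlap(p) > 0 for p in pred))
            mat[i, j] = 100.0 * hit / len(truth)
    return mat


def evaluate(truth_all: dict[ActivityLabel, SegmentSet],
             pred_all: dict[ActivityLabel, SegmentSet],
             duration: float, sample_rate: float = 50.0,
             min_overlap_fraction: float = 0.0) -> dict:
    """Full report over the four activities.

    Returns a JSON-serialisable dict with one entry per activity plus the
    confusion matrix.
    """
    n = int(round(duration * sample_rate))
    report: dict = {"activities": {}}
    for label in CONFUSION_ORDER:
        truth = truth_all.get(label, SegmentSet(label))
        pred = pred_all.get(label, SegmentSet(label))
        matching = match_events(truth, pred, min_overlap_fraction)
        res = event_metrics(matching, truth.to_mask(n, sample_rate),
                            pred.to_mask(n, sample_rate))
        report["activities"][label.value] = res.to_dict()
    report["confusion_matrix"] = {
        "order": [l.value for l in CONFUSION_ORDER],
        "rows_truth_cols_detected_pct":
            confusion_matrix(truth_all, pred_all).tolist(),
    }
    return report
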