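"""Detection scoring: rotated-box IoU matching and summary metrics.

Detections are matched to ground truth greedily in descending score order
at a rotated-IoU threshold (default 0.5); each ground-truth box can absorb
at most one detection.  Matched pairs are true positives, surplus
detections false positives, unmatched ground truths false negatives; true
negatives are identically zero in detection.  Precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 their harmonic mean.  Conductance regressions are
summarized by MSE and R².
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .annotations import RotatedBox, corners
from .measure import Detection


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0  # always 0 for detection; kept for the confusion-matrix form

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn, self.tn + other.tn)


def rotated_iou(a: RotatedBox, b: RotatedBox) -> float:
    """Exact intersection-over-union of two rotated rectangles."""
    pa, pb = Polygon(corners(a)), Polygon(corners(b))
    inter = pa.intersection(pb).area
    if inter == 0.0:
        return 0.0
    return inter / (pa.area + pb.area - inter)


def match_detections(detections: list[Detection], ground_truth: list[RotatedBox],
                     iou_threshold: float = 0.5) -> EvalCounts:
    """Greedy score-ordered one-to-one matching at ``iou_threshold``.

    Equal scores break ties by lower detection index, so the outcome does
    not depend on input order.
    """
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, i))
    unmatched = list(range(len(ground_truth)))
    tp = 0
    for i in order:
        best_j, best_iou = None, 0.0
        for j in unmatched:
            iou = rotated_iou(detections[i].box, ground_truth[j])
            if iou >= iou_threshold and iou > best_iou:
                best_j, best_iou = j, iou
        if best_j is not None:
            unmatched.remove(best_j)
            tp += 1
    return EvalCounts(tp, len(detections) - tp, len(unmatched))


def precision_recall_f1(counts: EvalCounts) -> tuple[float, float, float]:
    """(precision, recall, F1); degenerate denominators give 0 by convention."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def regression_metrics(predicted, truth) -> tuple[float, float]:
    """(MSE, R²) of predicted vs true values.

    Needs n ≥ 2; a constant truth leaves R² undefined (returned as NaN with
    a warning).
    """
    pred = np.asarray(predicted, dtype=float)
    true = np.asarray(truth, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    if pred.size < 2:
        raise ValueError("need at least 2 points")
    mse = float(np.mean((pred - true) ** 2))
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant truth: R² is undefined", RuntimeWarning)
        return mse, float("nan")
    ss_res = float(np.sum((true - pred) ** 2))
    return mse, 1.0 - ss_res / ss_tot


def write_eval_report(counts: EvalCounts, iou_threshold: float,
                      path: str | os.PathLike) -> dict:
    p, r, f1 = precision_recall_f1(counts)
    report = {"precision": p, "recall": r, "f1": f1, "tp": counts.tp,
              "fp": counts.fp, "fn": counts.fn,
              "iou_threshold": iou_threshold}
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
        fh.write("\n")
    return report
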