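"""Detection scoring against ground truth: one-to-one matching under a
distance criterion, precision/recall, and the precision-recall curve.

A detection counts as a true positive when it can be matched one-to-one
to an annotated center at a physical distance of at most half the maximum
cell radius.  Matching is greedy by descending detection score — the
standard convention in detection evaluation — with each detection taking
its nearest still-unmatched truth center inside the criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .localization import DetectionSet
from .synthetic import PhantomTruth, truth_from_csv

__all__ = ["MatchReport", "PRCurve", "match_detections", "precision_recall_curve"]


@dataclass(frozen=True)
class MatchReport:
    """Counts and matched pairs for one detection set at one threshold."""

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...]  # (detection index, truth index)
    criterion_radius_um: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall pairs swept over the score thresholds, plus the
    trapezoidal area under the achieved curve."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float


def _truth_centers_um(truth, spacing) -> np.ndarray:
    if isinstance(truth, PhantomTruth):
        return truth.centers_um()
    if isinstance(truth, (str, Path)):
        centers, _ = truth_from_csv(truth, spacing)
        return centers * np.asarray(spacing)
    centers = np.atleast_2d(np.asarray(truth, dtype=float))
    if centers.size == 0:
        centers = centers.reshape(0, len(spacing))
    return centers * np.asarray(spacing)


def match_detections(dets: DetectionSet, truth, r_max_um: float) -> MatchReport:
    """Match detections to truth centers under the 50%-of-max-radius rule.

    ``truth`` may be a :class:`PhantomTruth`, a truth CSV path, or an
    (n, ndim) array of centers in lattice coordinates (same frame and
    spacing as the detections).  ``r_max_um`` is the maximum cell radius;
    the matching distance is half of it.
    """
    if r_max_um <= 0:
        raise ValueError("r_max_um must be positive")
    truth_um = _truth_centers_um(truth, dets.spacing)
    if truth_um.shape[0] and truth_um.shape[1] != dets.ndim:
        raise ValueError(
            f"{dets.ndim}D detections cannot be scored against "
            f"{truth_um.shape[1]}D truth"
        )
    criterion = 0.5 * r_max_um
    det_um = dets.centers_um()
    matched_truth = np.zeros(truth_um.shape[0], dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i in range(det_um.shape[0]):  # detections are score-descending
        if not truth_um.shape[0]:
            break
        d = np.linalg.norm(truth_um - det_um[i], axis=1)
        d[matched_truth] = np.inf
        j = int(np.argmin(d))
        if d[j] <= criterion:
            matched_truth[j] = True
            pairs.append((i, j))
    tp = len(pairs)
    return MatchReport(
        tp=tp,
        fp=dets.count - tp,
        fn=int(truth_um.shape[0]) - tp,
        pairs=tuple(pairs),
        criterion_radius_um=criterion,
    )


def precision_recall_curve(dets: DetectionSet, truth, r_max_um: float) -> PRCurve:
    """Sweep the score threshold and integrate the achieved PR curve.

    Thresholds are the unique detection scores in descending order; the
    area is the trapezoidal integral over recall from 0 to the maximum
    achieved recall, anchoring recall 0 at the precision of the strictest
    threshold.
    """
    if dets.count == 0:
        warnings.warn("empty detection set: AUC is 0", stacklevel=2)
        return PRCurve(thresholds=np.empty(0), precision=np.empty(0),
                       recall=np.empty(0), auc=0.0)
    thresholds = np.unique(dets.scores)[::-1]
    precision, recall = [], []
    for thr in thresholds:
        keep = dets.scores >= thr
        sub = DetectionSet(centers=dets.centers[keep], scores=dets.scores[keep],
                           radius_um=dets.radius_um, spacing=dets.spacing)
        report = match_detections(sub, truth, r_max_um)
        precision.append(report.precision)
        recall.append(report.recall)
    precision = np.asarray(precision)
    recall = np.asarray(recall)
    # anchor at recall 0 with the strictest threshold's precision
    r_pts = np.concatenate([[0.0], recall])
    p_pts = np.concatenate([[precision[0]], precision])
    auc = float(np.trapezoid(p_pts, r_pts))
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall,
                   auc=auc)


def report_to_json_dict(report: MatchReport) -> dict:
    """Plain-dict form of a report, for JSON serialization."""
    return {
        "tp": report.tp,
        "fp": report.fp,
        "fn": report.fn,
        "precision": report.precision,
        "recall": report.recall,
        "criterion_radius_um": report.criterion_radius_um,
    }


def curve_to_csv(curve: PRCurve, path) -> None:
    """Write the PR curve as CSV with threshold, precision, recall."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "threshold": curve.thresholds,
        "precision": curve.precision,
        "recall": curve.recall,
    }).to_csv(path, index=False, float_format="%.9g")
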