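"""Bounding-box evaluation: TP/FP/FN counting, metrics, PR curve and AP.

The counting scheme follows the box-wise definitions commonly used to
benchmark polyp detectors:

* **TP** — a predicted box that lies *over* a true box;
* **FP** — a predicted box over no true box;
* **FN** — a true box with no predicted box over it.

Because "over" is a qualitative notion, the match predicate is configurable:
``any_overlap`` (any positive-area intersection, the default) or
``iou_threshold`` (IoU >= ``iou_min``). Two counting modes are offered:

* ``literal_per_box`` (default) — applies the three definitions literally and
  independently per box: two predictions over the same truth are two TPs;
* ``one_to_one_greedy`` — COCO-style: predictions sorted by descending
  confidence each consume at most one unmatched truth.

Metrics are micro-averaged: counts are pooled over all images of an
evaluation set before recall = TP/(TP+FN), precision = TP/(TP+FP) and
F1 = 2TP/(2TP+FP+FN) are formed. Degenerate denominators yield ``None``
metrics, never silent zeros.

The PR curve sweeps the detector's confidence threshold over every distinct
confidence value; AP is the step-wise area under that curve
(sum of precision x recall-increment over points in decreasing-threshold
order), which equals the average precision at the swept thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .datasets_io import BoundingBox, DatasetManifest, Detection
from .errors import ConsistencyError, UndefinedMetricError, ValidationError

MATCH_MODES = ("any_overlap", "iou_threshold")
COUNTING_MODES = ("literal_per_box", "one_to_one_greedy")


@dataclass(frozen=True)
class MatchCriterion:
    """How a predicted box is deemed to be *over* a truth box, and how
    multiple matches are counted."""

    mode: str = "any_overlap"
    iou_min: float | None = None
    counting: str = "literal_per_box"

    def __post_init__(self) -> None:
        if self.mode not in MATCH_MODES:
            raise ValidationError(f"unknown match mode {self.mode!r}")
        if self.counting not in COUNTING_MODES:
            raise ValidationError(f"unknown counting mode {self.counting!r}")
        if self.mode == "iou_threshold":
            if self.iou_min is None or not 0.0 < self.iou_min <= 1.0:
                raise ValidationError("iou_threshold mode needs iou_min in (0, 1]")
        elif self.iou_min is not None:
            raise ValidationError("iou_min is only meaningful in iou_threshold mode")

    def is_over(self, predicted: BoundingBox, truth: BoundingBox) -> bool:
        if self.mode == "any_overlap":
            return predicted.intersection_area(truth) > 0
        return predicted.iou(truth) >= self.iou_min

    def describe(self) -> str:
        pred = "any_overlap" if self.mode == "any_overlap" else f"iou>={self.iou_min:g}"
        return f"{pred}/{self.counting}"

    @classmethod
    def parse(cls, text: str, counting: str = "literal_per_box") -> "MatchCriterion":
        """Parse ``"any_overlap"`` or ``"iou:0.5"``."""
        text = text.strip()
        if text == "any_overlap":
            return cls(mode="any_overlap", counting=counting)
        if text.startswith("iou:"):
            return cls(mode="iou_threshold", iou_min=float(text[4:]),
                       counting=counting)
        raise ValidationError(f"cannot parse match criterion {text!r}")


@dataclass(frozen=True)
class EvaluationCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("counts must be non-negative")

    def __add__(self, other: "EvaluationCounts") -> "EvaluationCounts":
        return EvaluationCounts(self.tp + other.tp, self.fp + other.fp,
                                self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    """Recall/precision/F1 with explicit undefined-ness.

    A metric is ``None`` exactly when its denominator is zero; downstream
    code must handle the flag rather than receive a fabricated 0.
    """

    recall: float | None
    precision: float | None
    f1: float | None

    @property
    def recall_defined(self) -> bool:
        return self.recall is not None

    @property
    def precision_defined(self) -> bool:
        return self.precision is not None

    @property
    def f1_defined(self) -> bool:
        return self.f1 is not None

    @classmethod
    def from_counts(cls, counts: EvaluationCounts) -> "Metrics":
        tp, fp, fn = counts.tp, counts.fp, counts.fn
        recall = tp / (tp + fn) if tp + fn > 0 else None
        precision = tp / (tp + fp) if tp + fp > 0 else None
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else None
        return cls(recall=recall, precision=precision, f1=f1)


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def match_image(
    detections: Sequence[Detection],
    truths: Sequence[BoundingBox],
    criterion: MatchCriterion,
) -> EvaluationCounts:
    """Count TP/FP/FN on a single image. Empty inputs are valid."""
    boxes = [d.box for d in detections]
    if criterion.counting == "literal_per_box":
        tp = sum(1 for b in boxes if any(criterion.is_over(b, t) for t in truths))
        fp = len(boxes) - tp
        fn = sum(1 for t in truths
                 if not any(criterion.is_over(b, t) for b in boxes))
        return EvaluationCounts(tp=tp, fp=fp, fn=fn)

    # one_to_one_greedy: descending confidence, each detection consumes the
    # best-overlapping unmatched truth that satisfies the predicate.
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    unmatched = set(range(len(truths)))
    tp = 0
    for i in order:
        box = detections[i].box
        candidates = [j for j in unmatched if criterion.is_over(box, truths[j])]
        if not candidates:
            continue
        best = max(candidates, key=lambda j: (box.iou(truths[j]), -j))
        unmatched.discard(best)
        tp += 1
    return EvaluationCounts(tp=tp, fp=len(detections) - tp, fn=len(unmatched))


def _group_by_image(
    detections: Sequence[Detection],
    manifest: DatasetManifest,
) -> dict[str, list[Detection]]:
    known = {img.image_id for img in manifest.images}
    grouped: dict[str, list[Detection]] = {image_id: [] for image_id in known}
    for det in detections:
        if det.image_id not in known:
            raise ConsistencyError(
                f"detection references unknown image {det.image_id!r}"
            )
        grouped[det.image_id].append(det)
    return grouped


def evaluate(
    manifest: DatasetManifest,
    detections: Sequence[Detection],
    threshold: float,
    criterion: MatchCriterion = MatchCriterion(),
) -> tuple[EvaluationCounts, Metrics]:
    """Evaluate pooled counts over a manifest at a confidence threshold.

    Detections with confidence below ``threshold`` are discarded (comparison
    is ``>=``: a detection at exactly the threshold survives); counts are
    summed across images and metrics computed from the pooled tally.
    """
    grouped = _group_by_image(detections, manifest)
    total = EvaluationCounts()
    for img in manifest.images:
        kept = [d for d in grouped[img.image_id] if d.confidence >= threshold]
        total = total + match_image(kept, img.truth_boxes, criterion)
    return total, Metrics.from_counts(total)


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    counts: EvaluationCounts
    metrics: Metrics


@dataclass
class PRCurve:
    """PR curve over distinct confidence thresholds, descending, plus AP."""

    points: list[PRPoint] = field(default_factory=list)
    ap: float = 0.0

    @property
    def thresholds(self) -> list[float]:
        return [p.threshold for p in self.points]


def pr_curve(
    manifest: DatasetManifest,
    detections: Sequence[Detection],
    criterion: MatchCriterion = MatchCriterion(),
) -> PRCurve:
    """Sweep the confidence threshold and integrate AP.

    One point per distinct confidence value, in decreasing order. AP is the
    step estimator ``sum_i precision_i * (recall_i - recall_{i-1})`` with
    recall_0 = 0.

    The sweep exploits the fact that a detection's TP/FP status under both
    counting modes is decided by the full (unthresholded) matching: raising
    the threshold only truncates the confidence-sorted detection list, so per
    -detection outcomes and per-truth coverage confidences can be computed
    once and accumulated.
    """
    n_truths = manifest.n_truth_boxes
    if n_truths == 0:
        raise UndefinedMetricError("AP undefined: the manifest has no truth boxes")
    grouped = _group_by_image(detections, manifest)

    det_conf: list[float] = []      # confidence of each detection
    det_is_tp: list[bool] = []      # TP status in the full evaluation
    truth_cover: list[float] = []   # per truth: max conf of a covering detection

    for img in manifest.images:
        dets = grouped[img.image_id]
        truths = img.truth_boxes
        if criterion.counting == "literal_per_box":
            for det in dets:
                over = [t for t in truths if criterion.is_over(det.box, t)]
                det_conf.append(det.confidence)
                det_is_tp.append(bool(over))
            for t in truths:
                covering = [d.confidence for d in dets
                            if criterion.is_over(d.box, t)]
                if covering:
                    truth_cover.append(max(covering))
        else:
            order = sorted(range(len(dets)),
                           key=lambda i: (-dets[i].confidence, i))
            unmatched = set(range(len(truths)))
            matched_conf: dict[int, float] = {}
            tp_flags = [False] * len(dets)
            for i in order:
                box = dets[i].box
                cands = [j for j in unmatched
                         if criterion.is_over(box, truths[j])]
                if not cands:
                    continue
                best = max(cands, key=lambda j: (box.iou(truths[j]), -j))
                unmatched.discard(best)
                matched_conf[best] = dets[i].confidence
                tp_flags[i] = True
            for i, det in enumerate(dets):
                det_conf.append(det.confidence)
                det_is_tp.append(tp_flags[i])
            truth_cover.extend(matched_conf.values())

    thresholds = sorted(set(det_conf), reverse=True)
    order = sorted(range(len(det_conf)), key=lambda i: -det_conf[i])
    cover_sorted = sorted(truth_cover, reverse=True)

    points: list[PRPoint] = []
    ap = 0.0
    prev_recall = 0.0
    di = 0          # detections consumed so far
    ci = 0          # covered truths consumed so far
    tp = fp = 0
    for thr in thresholds:
        while di < len(order) and det_conf[order[di]] >= thr:
            if det_is_tp[order[di]]:
                tp += 1
            else:
                fp += 1
            di += 1
        while ci < len(cover_sorted) and cover_sorted[ci] >= thr:
            ci += 1
        fn = n_truths - ci
        counts = EvaluationCounts(tp=tp, fp=fp, fn=fn)
        metrics = Metrics.from_counts(counts)
        points.append(PRPoint(threshold=thr, counts=counts, metrics=metrics))
        recall = metrics.recall if metrics.recall is not None else 0.0
        precision = metrics.precision if metrics.precision is not None else 0.0
        ap += precision * (recall - prev_recall)
        prev_recall = recall

    return PRCurve(points=points, ap=ap)


def select_threshold(curve: PRCurve) -> float:
    """Confidence threshold whose PR point maximizes F1.

    Ties are broken toward the smallest threshold (the most sensitive
    operating point among equals).
    """
    best_thr: float | None = None
    best_f1 = -1.0
    for point in curve.points:
        if not point.metrics.f1_defined:
            continue
        f1 = point.metrics.f1
        if f1 > best_f1 or (f1 == best_f1 and
                            (best_thr is None or point.threshold < best_thr)):
            best_f1 = f1
            best_thr = point.threshold
    if best_thr is None:
        raise UndefinedMetricError("no PR point has a defined F1 score")
    return best_thr
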