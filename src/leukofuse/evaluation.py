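"""Detection evaluation: greedy IoU matching, 101-point interpolated AP,
mAP/mAR over the IoU grid 0.50:0.95, per-class AP, PR curves, detection
confusion matrices, and interference-factor-conditional accuracy.

Matching follows the standard protocol: within an image, detections are
visited in descending confidence order and each claims the still-unmatched
ground truth (of the same class, when class-aware) with the highest IoU at or
above the working threshold. Average precision uses the 101-point
interpolation (mean over the recall grid 0.00, 0.01, ..., 1.00 of the maximum
precision attained at recall >= r), and mAP/mAR average over the ten IoU
thresholds 0.50, 0.55, ..., 0.95 and then over classes. Classes with no
ground truths in the evaluated set have undefined AP and are excluded from
the means rather than counted as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import ClassLabel, Detection, GroundTruthAnnotation, iou

__all__ = [
    "IOU_GRID",
    "RECALL_GRID",
    "BACKGROUND",
    "MatchResult",
    "PRCurve",
    "EvalReport",
    "match_detections",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "mean_ar",
    "confusion_matrix",
    "tagged_accuracy",
    "evaluate",
]

#: The ten IoU thresholds of the 0.50:0.95 evaluation protocol.
IOU_GRID: Tuple[float, ...] = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))

#: 101-point recall grid for interpolated average precision. Each point is
#: computed as k/100 so grid values are the correctly rounded doubles of the
#: decimal fractions (recall values that are exact small fractions, e.g. 3/5,
#: then compare against the grid without spurious rounding slack).
RECALL_GRID: np.ndarray = np.arange(101) / 100.0

#: Index of the background row/column in the 6x6 confusion matrix.
BACKGROUND: int = len(ClassLabel)

# Detections and fused detections share the (box, confidence, label) surface;
# everything below is duck-typed over that.
DetLike = Detection
DetsByImage = Mapping[int, Sequence[DetLike]]
GtsByImage = Mapping[int, Sequence[GroundTruthAnnotation]]


@dataclass
class MatchResult:
    """Outcome of matching one image's detections against its ground truths
    at a single IoU threshold.

    ``det_matched_gt[i]`` is the index of the ground truth claimed by
    detection i (in the sorted order used for matching) or None for a false
    positive; ``gt_matched_det[j]`` mirrors it from the ground-truth side.
    """

    det_order: List[int]
    det_matched_gt: List[Optional[int]]
    gt_matched_det: List[Optional[int]]

    @property
    def det_is_tp(self) -> List[bool]:
        return [m is not None for m in self.det_matched_gt]


def _sorted_det_indices(dets: Sequence[DetLike]) -> List[int]:
    # Descending confidence; confidence ties broken by input order.
    return sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))


def match_detections(
    dets: Sequence[DetLike],
    gts: Sequence[GroundTruthAnnotation],
    iou_threshold: float,
    class_aware: bool = True,
) -> MatchResult:
    """Greedy one-to-one matching for a single image.

    Each detection, in descending confidence order, claims the unmatched
    ground truth with the highest IoU >= ``iou_threshold`` (restricted to its
    own class when ``class_aware``); equal IoUs go to the lower ground-truth
    index. Each ground truth is claimed at most once.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold must be in (0, 1), got {iou_threshold}")
    order = _sorted_det_indices(dets)
    gt_taken: List[Optional[int]] = [None] * len(gts)
    det_matched: List[Optional[int]] = [None] * len(dets)
    for rank, di in enumerate(order):
        d = dets[di]
        best_j, best_iou = None, iou_threshold
        for j, g in enumerate(gts):
            if gt_taken[j] is not None:
                continue
            if class_aware and g.label != d.label:
                continue
            v = iou(d.box, g.box)
            if v > best_iou or (v == best_iou and v >= iou_threshold and best_j is None):
                best_j, best_iou = j, v
        if best_j is not None:
            gt_taken[best_j] = di
            det_matched[di] = best_j
    return MatchResult(
        det_order=order,
        det_matched_gt=[det_matched[i] for i in order],
        gt_matched_det=gt_taken,
    )


def _pooled_flags(
    dets_by_image: DetsByImage,
    gts_by_image: GtsByImage,
    iou_threshold: float,
    label: Optional[ClassLabel],
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Match per image, then pool (confidence, tp-flag) pairs across images.

    Returns confidences sorted descending, their TP flags, and the number of
    ground truths of the class (all classes when ``label`` is None).
    """
    confs: List[float] = []
    flags: List[bool] = []
    n_gt = 0
    image_ids = set(dets_by_image) | set(gts_by_image)
    for img in image_ids:
        gts = [g for g in gts_by_image.get(img, ()) if label is None or g.label == label]
        dets = [d for d in dets_by_image.get(img, ()) if label is None or d.label == label]
        n_gt += len(gts)
        res = match_detections(dets, gts, iou_threshold, class_aware=True)
        for rank, di in enumerate(res.det_order):
            confs.append(dets[di].confidence)
            flags.append(res.det_matched_gt[rank] is not None)
    if not confs:
        return np.empty(0), np.empty(0, dtype=bool), n_gt
    conf_arr = np.asarray(confs)
    flag_arr = np.asarray(flags)
    order = np.argsort(-conf_arr, kind="stable")
    return conf_arr[order], flag_arr[order], n_gt


def _interpolated_precision(tp: np.ndarray, n_gt: int) -> np.ndarray:
    """101-point interpolated precision along RECALL_GRID from pooled TP flags."""
    if n_gt == 0:
        raise ValueError("interpolated precision is undefined with zero ground truths")
    if tp.size == 0:
        return np.zeros_like(RECALL_GRID)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # Running max from the right: max precision attainable at recall >= r.
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(recall, RECALL_GRID, side="left")
    out = np.zeros_like(RECALL_GRID)
    valid = idx < len(recall)
    out[valid] = prec_env[idx[valid]]
    return out


def pr_curve(
    dets_by_image: DetsByImage,
    gts_by_image: GtsByImage,
    iou_threshold: float,
    label: Optional[ClassLabel] = None,
) -> "PRCurve":
    """Interpolated precision-recall curve at one IoU threshold, for one class
    or pooled over all classes (``label=None``)."""
    if label is None:
        curves = []
        for lab in ClassLabel:
            confs, flags, n_gt = _pooled_flags(dets_by_image, gts_by_image, iou_threshold, lab)
            if n_gt > 0:
                curves.append(_interpolated_precision(flags, n_gt))
        if not curves:
            raise ValueError("no ground truths in the evaluated set")
        precision = np.mean(curves, axis=0)
    else:
        confs, flags, n_gt = _pooled_flags(dets_by_image, gts_by_image, iou_threshold, label)
        if n_gt == 0:
            raise ValueError(f"no ground truths of class {label.name}; PR curve undefined")
        precision = _interpolated_precision(flags, n_gt)
    return PRCurve(
        recall=RECALL_GRID.copy(),
        precision=precision,
        iou_threshold=iou_threshold,
        label=label,
    )


@dataclass
class PRCurve:
    """101-point interpolated precision-recall curve at one IoU threshold.

    ``label`` is None for the all-classes (mean-over-classes) curve.
    Interpolated precision is non-increasing along the recall grid by
    construction.
    """

    recall: np.ndarray
    precision: np.ndarray
    iou_threshold: float
    label: Optional[ClassLabel]

    @property
    def auc(self) -> float:
        return float(np.mean(self.precision))


def average_precision(
    dets_by_image: DetsByImage,
    gts_by_image: GtsByImage,
    iou_threshold: float,
    label: ClassLabel,
) -> Optional[float]:
    """101-point interpolated AP for one class at one IoU threshold.

    Returns None (undefined, never 0 by fiat) when the class has no ground
    truths in the evaluated set.
    """
    confs, flags, n_gt = _pooled_flags(dets_by_image, gts_by_image, iou_threshold, label)
    if n_gt == 0:
        return None
    return float(np.mean(_interpolated_precision(flags, n_gt)))


def mean_ap(
    dets_by_image: DetsByImage,
    gts_by_image: GtsByImage,
    thresholds: Sequence[float] = IOU_GRID,
) -> Tuple[float, Dict[ClassLabel, Optional[float]]]:
    """mAP over the IoU grid plus per-class AP averaged over the grid.

    AP is averaged over thresholds first, then over the classes for which it
    is defined. Raises if no class has any ground truths.
    """
    per_class: Dict[ClassLabel, Optional[float]] = {}
    for lab in ClassLabel:
        aps = [average_precision(dets_by_image, gts_by_image, t, lab) for t in thresholds]
        if any(a is None for a in aps):
            per_class[lab] = None
        else:
            per_class[lab] = float(np.mean([a for a in aps if a is not None]))
    defined = [v for v in per_class.values() if v is not None]
    if not defined:
        raise ValueError("no class has ground truths; mAP undefined")
    return float(np.mean(defined)), per_class


def mean_ar(
    dets_by_image: DetsByImage,
    gts_by_image: GtsByImage,
    thresholds: Sequence[float] = IOU_GRID,
    max_detections: int = 100,
) -> float:
    """Mean average recall over the IoU grid.

    For each class and threshold, recall is the fraction of that class's
    ground truths matched when each image contributes at most its
    ``max_detections`` highest-confidence detections of the class; recalls
    are averaged over thresholds, then over defined classes.
    """
    per_class: List[float] = []
    image_ids = set(dets_by_image) | set(gts_by_image)
    for lab in ClassLabel:
        n_gt = sum(
            1 for img in image_ids for g in gts_by_image.get(img, ()) if g.label == lab
        )
        if n_gt == 0:
            continue
        recalls = []
        for t in thresholds:
            matched = 0
            for img in image_ids:
                gts = [g for g in gts_by_image.get(img, ()) if g.label == lab]
                if not gts:
                    continue
                dets = [d for d in dets_by_image.get(img, ()) if d.label == lab]
                dets = sorted(dets, key=lambda d: -d.confidence)[:max_detections]
                res = match_detections(dets, gts, t, class_aware=True)
                matched += sum(1 for m in res.gt_matched_det if m is not None)
            recalls.append(matched / n_gt)
        per_class.append(float(np.mean(recalls)))
    if not per_class:
        raise ValueError("no class has ground truths; mAR undefined")
    return float(np.mean(per_class))


def confusion_matrix(
    dets_by_image: DetsByImage,
    gts_by_image: GtsByImage,
    iou_threshold: float = 0.5,
) -> np.ndarray:
    """6x6 detection confusion matrix (five classes + background).

    Matching is class-agnostic so that cross-class confusions populate
    off-diagonal cells. Rows are true classes, columns predicted classes;
    unmatched ground truths fall into (true class, background) and unmatched
    detections into (background, predicted class). Row sums over the five
    true-class rows therefore equal the per-class ground-truth counts.
    """
    mat = np.zeros((BACKGROUND + 1, BACKGROUND + 1), dtype=int)
    image_ids = set(dets_by_image) | set(gts_by_image)
    for img in image_ids:
        gts = list(gts_by_image.get(img, ()))
        dets = list(dets_by_image.get(img, ()))
        res = match_detections(dets, gts, iou_threshold, class_aware=False)
        for rank, di in enumerate(res.det_order):
            j = res.det_matched_gt[rank]
            if j is None:
                mat[BACKGROUND, int(dets[di].label)] += 1
            else:
                mat[int(gts[j].label), int(dets[di].label)] += 1
        for j, m in enumerate(res.gt_matched_det):
            if m is None:
                mat[int(gts[j].label), BACKGROUND] += 1
    return mat


def tagged_accuracy(
    dets_by_image: DetsByImage,
    gts_by_image: GtsByImage,
    tag: str,
    iou_threshold: float = 0.5,
) -> Optional[float]:
    """Correct-class recall over ground truths carrying an interference tag.

    Over the ground truths tagged with ``tag``: the fraction matched by a
    detection of the correct class at IoU >= ``iou_threshold`` (class-aware
    matching run over each image's full detection and ground-truth lists).
    Returns None when no ground truth carries the tag.
    """
    from .core import TAG_VOCABULARY

    if tag not in TAG_VOCABULARY:
        raise ValueError(f"unknown tag {tag!r}; vocabulary is {sorted(TAG_VOCABULARY)}")
    n_tagged = 0
    n_hit = 0
    image_ids = set(dets_by_image) | set(gts_by_image)
    for img in image_ids:
        gts = list(gts_by_image.get(img, ()))
        if not any(tag in g.tags for g in gts):
            continue
        dets = list(dets_by_image.get(img, ()))
        res = match_detections(dets, gts, iou_threshold, class_aware=True)
        for j, g in enumerate(gts):
            if tag in g.tags:
                n_tagged += 1
                if res.gt_matched_det[j] is not None:
                    n_hit += 1
    if n_tagged == 0:
        return None
    return n_hit / n_tagged


@dataclass
class EvalReport:
    """Summary of a detection run: mAP/mAR over the IoU grid, the two headline
    single-threshold mAPs, per-class AP over the grid, the detection confusion
    matrix, and per-interference-tag accuracies."""

    map_50_95: float
    map_50: float
    map_75: float
    mar_50_95: float
    per_class_ap: Dict[ClassLabel, Optional[float]]
    confusion: np.ndarray
    tag_accuracy: Dict[str, Optional[float]] = field(default_factory=dict)


def evaluate(
    dets_by_image: DetsByImage,
    gts_by_image: GtsByImage,
    tags: Sequence[str] = (),
    max_detections: int = 100,
) -> EvalReport:
    """Compute the full evaluation report for one detection run."""
    m, per_class = mean_ap(dets_by_image, gts_by_image)
    m50, _ = mean_ap(dets_by_image, gts_by_image, thresholds=(0.5,))
    m75, _ = mean_ap(dets_by_image, gts_by_image, thresholds=(0.75,))
    mar = mean_ar(dets_by_image, gts_by_image, max_detections=max_detections)
    conf = confusion_matrix(dets_by_image, gts_by_image)
    tag_acc = {t: tagged_accuracy(dets_by_image, gts_by_image, t) for t in tags}
    return EvalReport(
        map_50_95=m,
        map_50=m50,
        map_75=m75,
        mar_50_95=mar,
        per_class_ap=per_class,
        confusion=conf,
        tag_accuracy=tag_acc,
    )
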