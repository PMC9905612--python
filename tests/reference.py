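"""Independent straight-line reference implementations used as oracles.

These deliberately re-derive the fusion and evaluation semantics from their
definitions with naive, unoptimised code (recomputing everything from scratch
at each step) so that agreement with the package is a genuine two-route
check, not a shared code path.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from leukofuse.core import Box, ClassLabel, Detection, GroundTruthAnnotation


# ---------------------------------------------------------------------------
# geometry


def ref_iou(a: Tuple[float, ...], b: Tuple[float, ...]) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    area_a = (ax2 - ax1) * (ay2 - ay1)
    area_b = (bx2 - bx1) * (by2 - by1)
    return inter / (area_a + area_b - inter)


# ---------------------------------------------------------------------------
# fusion pipeline, written flat


def _weighted_mean(members: List[Detection]) -> Tuple[float, float, float, float]:
    sw = sum(m.confidence for m in members)
    if sw <= 0:
        k = len(members)
        return (
            sum(m.box.x1 for m in members) / k,
            sum(m.box.y1 for m in members) / k,
            sum(m.box.x2 for m in members) / k,
            sum(m.box.y2 for m in members) / k,
        )
    return (
        sum(m.confidence * m.box.x1 for m in members) / sw,
        sum(m.confidence * m.box.y1 for m in members) / sw,
        sum(m.confidence * m.box.x2 for m in members) / sw,
        sum(m.confidence * m.box.y2 for m in members) / sw,
    )


def reference_ensemble(
    per_model: Mapping[str, Sequence[Detection]],
    cluster_iou: float = 0.55,
    min_support_fraction: float = 0.5,
    divisor_mode: str = "models",
) -> Tuple[List[dict], List[List[Detection]]]:
    """Full pipeline: greedy clustering by descending confidence, majority
    filter, majority vote (summed-confidence tie break, then class index),
    confidence-weighted box average over all members, C' = sum C / divisor.

    Returns (fused dicts sorted by descending confidence, discarded clusters).
    """
    m_count = len(per_model)
    pool = [d for lst in per_model.values() for d in lst]
    pool = sorted(
        pool, key=lambda d: (-d.confidence, str(d.model_id), d.box.corners(), int(d.label))
    )

    clusters: List[List[Detection]] = []
    for det in pool:
        joined = False
        for cl in clusters:
            if any(m.model_id == det.model_id for m in cl):
                continue
            if ref_iou(_weighted_mean(cl), det.box.corners()) >= cluster_iou:
                cl.append(det)
                joined = True
                break
        if not joined:
            clusters.append([det])

    kept = [c for c in clusters if len(c) >= min_support_fraction * m_count]
    discarded = [c for c in clusters if len(c) < min_support_fraction * m_count]

    fused = []
    for cl in kept:
        votes: Dict[ClassLabel, int] = {}
        sums: Dict[ClassLabel, float] = {}
        for m in cl:
            votes[m.label] = votes.get(m.label, 0) + 1
            sums[m.label] = sums.get(m.label, 0.0) + m.confidence
        best = max(votes.values())
        leaders = [lab for lab in sorted(votes) if votes[lab] == best]
        if len(leaders) > 1:
            top_sum = max(sums[lab] for lab in leaders)
            leaders = [lab for lab in leaders if sums[lab] == top_sum]
        label = leaders[0]
        t = best
        box = _weighted_mean(cl)
        total = sum(m.confidence for m in cl)
        conf = total / (m_count if divisor_mode == "models" else t)
        fused.append(
            {"box": box, "confidence": conf, "label": label, "support": len(cl), "majority": t}
        )
    fused.sort(key=lambda f: (-f["confidence"], int(f["label"]), f["box"]))
    return fused, discarded


def connected_components_by_iou(boxes: Sequence[Box], threshold: float) -> int:
    """Number of connected components of the pairwise-IoU graph (edges where
    IoU >= threshold). Oracle for well-separated clustering instances."""
    n = len(boxes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if ref_iou(boxes[i].corners(), boxes[j].corners()) >= threshold:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


# ---------------------------------------------------------------------------
# evaluation, written flat


def _ref_match(
    dets: Sequence, gts: Sequence, thr: float, class_aware: bool
) -> Tuple[List[Optional[int]], List[Optional[int]]]:
    """Greedy per-image matching; returns (gt index per detection in
    descending-confidence order, detection index per ground truth)."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    gt_used: List[Optional[int]] = [None] * len(gts)
    det_hit: List[Optional[int]] = []
    for di in order:
        d = dets[di]
        best, best_v = None, -1.0
        for j, g in enumerate(gts):
            if gt_used[j] is not None:
                continue
            if class_aware and g.label != d.label:
                continue
            v = ref_iou(d.box.corners(), g.box.corners())
            if v >= thr and v > best_v:
                best, best_v = j, v
        det_hit.append(best)
        if best is not None:
            gt_used[best] = di
    return det_hit, gt_used


def reference_ap(
    dets_by_image: Mapping[int, Sequence],
    gts_by_image: Mapping[int, Sequence[GroundTruthAnnotation]],
    thr: float,
    label: ClassLabel,
) -> Optional[float]:
    """101-point interpolated AP computed by direct definition (max precision
    at recall >= r for each grid point, via an explicit scan)."""
    pairs: List[Tuple[float, bool]] = []
    n_gt = 0
    for img in set(dets_by_image) | set(gts_by_image):
        gts = [g for g in gts_by_image.get(img, ()) if g.label == label]
        dets = [d for d in dets_by_image.get(img, ()) if d.label == label]
        n_gt += len(gts)
        det_hit, _ = _ref_match(dets, gts, thr, class_aware=True)
        order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
        for rank, di in enumerate(order):
            pairs.append((dets[di].confidence, det_hit[rank] is not None))
    if n_gt == 0:
        return None
    pairs.sort(key=lambda p: -p[0])
    precisions: List[float] = []
    recalls: List[float] = []
    tp = fp = 0
    for _, hit in pairs:
        if hit:
            tp += 1
        else:
            fp += 1
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_gt)
    total = 0.0
    for k in range(101):
        r = k / 100.0
        cands = [p for p, rec in zip(precisions, recalls) if rec >= r]
        total += max(cands) if cands else 0.0
    return total / 101.0


def reference_map(
    dets_by_image: Mapping[int, Sequence],
    gts_by_image: Mapping[int, Sequence[GroundTruthAnnotation]],
    thresholds: Sequence[float] = tuple(round(0.5 + 0.05 * i, 2) for i in range(10)),
) -> float:
    per_class = []
    for lab in ClassLabel:
        aps = [reference_ap(dets_by_image, gts_by_image, t, lab) for t in thresholds]
        if all(a is not None for a in aps):
            per_class.append(sum(aps) / len(aps))
    return sum(per_class) / len(per_class)


def reference_mar(
    dets_by_image: Mapping[int, Sequence],
    gts_by_image: Mapping[int, Sequence[GroundTruthAnnotation]],
    thresholds: Sequence[float] = tuple(round(0.5 + 0.05 * i, 2) for i in range(10)),
    max_detections: int = 100,
) -> float:
    per_class = []
    image_ids = set(dets_by_image) | set(gts_by_image)
    for lab in ClassLabel:
        n_gt = sum(1 for img in image_ids for g in gts_by_image.get(img, ()) if g.label == lab)
        if n_gt == 0:
            continue
        recs = []
        for t in thresholds:
            hit = 0
            for img in image_ids:
                gts = [g for g in gts_by_image.get(img, ()) if g.label == lab]
                dets = [d for d in dets_by_image.get(img, ()) if d.label == lab]
                dets = sorted(dets, key=lambda d: -d.confidence)[:max_detections]
                _, gt_used = _ref_match(dets, gts, t, class_aware=True)
                hit += sum(1 for u in gt_used if u is not None)
            recs.append(hit / n_gt)
        per_class.append(sum(recs) / len(recs))
    return sum(per_class) / len(per_class)
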