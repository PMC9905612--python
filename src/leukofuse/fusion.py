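"""Confidence-weighted, majority-vote fusion of multi-detector outputs.

Given per-model detection lists for one image, the ensemble

1. clusters cross-model detections that overlap (IoU against the cluster's
   running confidence-weighted mean box at join time, default threshold 0.55,
   the weighted-boxes-fusion convention);
2. discards clusters supported by fewer than half the models (a region that
   most detectors deem empty is treated as a false positive);
3. votes the class label by majority among cluster members;
4. fuses the box as the confidence-weighted mean of member corner vectors,

       L' = sum_i C_i * [x1_i, y1_i, x2_i, y2_i] / sum_i C_i

   and updates the confidence as ``C' = sum_i C_i / D``.

The divisor ``D`` is configurable. With ``D = M`` (the total model count,
the default) a model that emits no detection for the region acts like an
abstention and lowers the fused confidence. With ``D = T`` (the majority
count) the confidence is averaged over the models that voted with the
majority and can exceed 1 when minority-label members contribute to the sum;
such values are surfaced unchanged, never clipped.

Everything here is deterministic: ordering is content-based (confidence,
model id, coordinates), so permuting models or within-model detection order
leaves the output bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .core import Box, ClassLabel, Detection, ImageRecord

__all__ = [
    "FusionConfig",
    "Cluster",
    "FusedDetection",
    "EnsembleResult",
    "cluster_detections",
    "filter_clusters",
    "vote_type",
    "fuse_cluster",
    "ensemble",
]


@dataclass(frozen=True)
class FusionConfig:
    """Tunable constants of the ensemble scheme.

    cluster_iou_threshold
        Minimum IoU between a detection and a cluster's running fused box for
        the detection to join that cluster. Default 0.55.
    min_support_fraction
        A cluster is kept iff its size N satisfies ``N >= fraction * M`` where
        M is the model count; the default 0.5 realises the "discard when
        supported by fewer than half the models" rule, keeping exactly M/2.
    confidence_divisor_mode
        ``"models"`` divides the summed confidence by M (abstention penalty);
        ``"majority"`` divides by the majority count T.
    box_average_scope
        ``"all_members"`` averages every cluster member's box including
        minority-label ones; ``"majority_only"`` restricts the average to
        members carrying the voted label.
    tie_break_rule
        ``"summed_confidence"`` resolves majority ties in favour of the label
        with the larger summed confidence (residual ties by canonical class
        index); ``"class_index"`` goes straight to the canonical index.
    """

    cluster_iou_threshold: float = 0.55
    min_support_fraction: float = 0.5
    confidence_divisor_mode: str = "models"
    box_average_scope: str = "all_members"
    tie_break_rule: str = "summed_confidence"

    def __post_init__(self) -> None:
        if not (0.0 < self.cluster_iou_threshold < 1.0):
            raise ValueError(
                f"cluster_iou_threshold must be in (0, 1), got {self.cluster_iou_threshold}"
            )
        if not (0.0 < self.min_support_fraction <= 1.0):
            raise ValueError(
                f"min_support_fraction must be in (0, 1], got {self.min_support_fraction}"
            )
        if self.confidence_divisor_mode not in ("models", "majority"):
            raise ValueError(
                f"confidence_divisor_mode must be 'models' or 'majority', "
                f"got {self.confidence_divisor_mode!r}"
            )
        if self.box_average_scope not in ("all_members", "majority_only"):
            raise ValueError(
                f"box_average_scope must be 'all_members' or 'majority_only', "
                f"got {self.box_average_scope!r}"
            )
        if self.tie_break_rule not in ("summed_confidence", "class_index"):
            raise ValueError(
                f"tie_break_rule must be 'summed_confidence' or 'class_index', "
                f"got {self.tie_break_rule!r}"
            )


@dataclass
class Cluster:
    """A group of cross-model detections covering one candidate cell.

    ``N`` (the cluster size) counts the overlapping boxes; at most one member
    per model, so N also counts supporting models. ``T`` counts the members
    carrying the majority label; 1 <= T <= N.
    """

    members: List[Detection] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.members)

    def _weighted_mean_box(self) -> Box:
        sw = sum(d.confidence for d in self.members)
        if sw <= 0.0:
            # All-zero confidences cannot weight a mean; fall back to the
            # unweighted centroid for the running box used during clustering.
            k = len(self.members)
            return Box(
                sum(d.box.x1 for d in self.members) / k,
                sum(d.box.y1 for d in self.members) / k,
                sum(d.box.x2 for d in self.members) / k,
                sum(d.box.y2 for d in self.members) / k,
            )
        return Box(
            sum(d.confidence * d.box.x1 for d in self.members) / sw,
            sum(d.confidence * d.box.y1 for d in self.members) / sw,
            sum(d.confidence * d.box.x2 for d in self.members) / sw,
            sum(d.confidence * d.box.y2 for d in self.members) / sw,
        )


@dataclass(frozen=True)
class FusedDetection:
    """Ensemble output for one cell: fused box, updated confidence, voted
    label, cluster support N, majority count T, and whether the vote was
    settled by a tie-break."""

    box: Box
    confidence: float
    label: ClassLabel
    support: int
    majority: int
    tie_broken: bool = False


@dataclass(frozen=True)
class EnsembleResult:
    """Fused detections plus the audit trail of discarded clusters."""

    fused: Tuple[FusedDetection, ...]
    discarded: Tuple[Cluster, ...]


def _detection_sort_key(d: Detection):
    # Content-based ordering: descending confidence, then model id, then
    # coordinates and label. No dependence on input order, so clustering is
    # invariant under permutation of models or within-model lists.
    return (-d.confidence, str(d.model_id), d.box.corners(), int(d.label))


def cluster_detections(
    per_model_detections: Mapping[str, Sequence[Detection]] | Sequence[Sequence[Detection]],
    cfg: FusionConfig = FusionConfig(),
) -> List[Cluster]:
    """Greedily cluster cross-model detections for one image.

    Detections are visited in descending-confidence order; each joins the
    first existing cluster whose current confidence-weighted mean box has
    IoU >= ``cfg.cluster_iou_threshold`` and which has no member from the
    same model yet; otherwise it seeds a new cluster. Every input detection
    ends up in exactly one cluster.
    """
    if isinstance(per_model_detections, Mapping):
        lists: Iterable[Sequence[Detection]] = per_model_detections.values()
    else:
        lists = per_model_detections
    pool = [d for lst in lists for d in lst]
    pool.sort(key=_detection_sort_key)

    from .core import iou as _iou

    clusters: List[Cluster] = []
    running: List[Box] = []  # cached weighted-mean box per cluster
    taken: List[set] = []  # model ids already present per cluster
    for det in pool:
        placed = False
        for i, cl in enumerate(clusters):
            if det.model_id in taken[i]:
                continue
            if _iou(running[i], det.box) >= cfg.cluster_iou_threshold:
                cl.members.append(det)
                taken[i].add(det.model_id)
                running[i] = cl._weighted_mean_box()
                placed = True
                break
        if not placed:
            clusters.append(Cluster(members=[det]))
            running.append(det.box)
            taken.append({det.model_id})
    return clusters


def filter_clusters(
    clusters: Sequence[Cluster], model_count: int, cfg: FusionConfig = FusionConfig()
) -> Tuple[List[Cluster], List[Cluster]]:
    """Split clusters into (kept, discarded) by the majority-support rule.

    A cluster is kept iff ``N >= min_support_fraction * M`` — i.e. strictly
    fewer than M/2 supporting models is discarded, exactly M/2 survives.
    Discards are returned, never silently dropped.
    """
    if model_count < 1:
        raise ValueError(f"model_count must be >= 1, got {model_count}")
    cut = cfg.min_support_fraction * model_count
    kept = [c for c in clusters if c.n >= cut]
    discarded = [c for c in clusters if c.n < cut]
    return kept, discarded


def vote_type(
    cluster: Cluster, cfg: FusionConfig = FusionConfig()
) -> Tuple[ClassLabel, int, bool]:
    """Majority vote over member labels.

    Returns ``(voted_label, T, tie_broken)`` where T is the number of members
    carrying the winning label. Ties are resolved by the configured rule
    (largest summed confidence by default, residual ties by canonical class
    index) and flagged.
    """
    if cluster.n == 0:
        raise ValueError("cannot vote on an empty cluster")
    counts: Dict[ClassLabel, int] = {}
    conf_sums: Dict[ClassLabel, float] = {}
    for d in cluster.members:
        counts[d.label] = counts.get(d.label, 0) + 1
        conf_sums[d.label] = conf_sums.get(d.label, 0.0) + d.confidence
    top = max(counts.values())
    leaders = sorted(lab for lab, c in counts.items() if c == top)
    if len(leaders) == 1:
        return leaders[0], top, False
    if cfg.tie_break_rule == "summed_confidence":
        best = max(conf_sums[lab] for lab in leaders)
        leaders = [lab for lab in leaders if conf_sums[lab] == best]
    # residual (or configured) tie-break: canonical class index
    return min(leaders), top, True


def fuse_cluster(
    cluster: Cluster, model_count: int, cfg: FusionConfig = FusionConfig()
) -> FusedDetection:
    """Fuse one kept cluster into a single detection.

    The box is the confidence-weighted mean of member corner vectors over the
    configured scope; the confidence is the summed member confidence divided
    by M (``models`` mode) or by the majority count T (``majority`` mode).
    """
    if cluster.n == 0:
        raise ValueError("cannot fuse an empty cluster")
    label, t, tie_broken = vote_type(cluster, cfg)
    if cfg.box_average_scope == "majority_only":
        scope = [d for d in cluster.members if d.label == label]
    else:
        scope = list(cluster.members)
    sw = math.fsum(d.confidence for d in scope)
    if sw <= 0.0:
        raise ValueError(
            "all member confidences are zero; the weighted box average is undefined"
        )
    # Weighted mean computed around the first member's box:
    #   mean = ref + sum_i C_i (x_i - ref) / sum_i C_i,
    # algebraically identical to sum_i C_i x_i / sum_i C_i but exactly
    # reproducing the input when all member boxes coincide (the differences
    # vanish before any rounding), which the naive form does not.
    ref = scope[0].box
    box = Box(
        ref.x1 + math.fsum(d.confidence * (d.box.x1 - ref.x1) for d in scope) / sw,
        ref.y1 + math.fsum(d.confidence * (d.box.y1 - ref.y1) for d in scope) / sw,
        ref.x2 + math.fsum(d.confidence * (d.box.x2 - ref.x2) for d in scope) / sw,
        ref.y2 + math.fsum(d.confidence * (d.box.y2 - ref.y2) for d in scope) / sw,
    )
    divisor = model_count if cfg.confidence_divisor_mode == "models" else t
    # Same centering for C' = sum_i C_i / D: with n identical members and
    # D = n this yields the member confidence bit-exactly.
    ref_c = cluster.members[0].confidence
    confidence = ref_c * (cluster.n / divisor) + math.fsum(
        d.confidence - ref_c for d in cluster.members
    ) / divisor
    return FusedDetection(
        box=box,
        confidence=confidence,
        label=label,
        support=cluster.n,
        majority=t,
        tie_broken=tie_broken,
    )


def ensemble(
    image: ImageRecord, cfg: FusionConfig = FusionConfig()
) -> EnsembleResult:
    """Run the full fusion pipeline on one image's per-model detections.

    Composition: cluster -> support filter -> vote -> fuse. Fused detections
    are returned sorted by descending confidence (content-based tie-break);
    discarded clusters are reported alongside.
    """
    model_count = len(image.detections)
    if model_count < 1:
        raise ValueError(f"image {image.image_id} has no model detection lists")
    clusters = cluster_detections(image.detections, cfg)
    kept, discarded = filter_clusters(clusters, model_count, cfg)
    fused = [fuse_cluster(c, model_count, cfg) for c in kept]
    fused.sort(key=lambda f: (-f.confidence, int(f.label), f.box.corners()))
    return EnsembleResult(fused=tuple(fused), discarded=tuple(discarded))
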