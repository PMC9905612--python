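"""Synthetic multi-detector blood-smear benchmarks.

The generator works purely in annotation/detection space — no pixels are
rendered, because neither fusion nor evaluation touches image content. A
scene is a 600x600 canvas (the "mini" working resolution for blood-smear
fields at x1000 magnification) populated with one or more leukocyte bounding
boxes whose class frequencies default to the composition of the reference
dataset (NG:BG:EG:L:M = 4135:300:1100:1879:1181 cells). Images and cells
carry interference-factor tags from the closed vocabulary; tags act on the
simulated detectors as noise multipliers (e.g. overlapping cells are missed
more often, impurity-laden images attract more false positives), not as
image effects.

Each simulated detector is parameterised by a :class:`DetectorProfile`:
a miss (false-negative) probability, a per-image false-positive rate,
corner jitter as a fraction of box size, a row-stochastic 5x5 label-confusion
matrix, and a confidence model that links reported confidence to realised
localisation quality::

    C = clamp(base - slope * (1 - IoU(jittered, true)) + noise, floor, 1)

so that confidence-weighted fusion has a meaningful signal to exploit.

Everything is a pure function of (configuration, seed): the same seed yields
bit-identical benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    Box,
    BoxError,
    ClassLabel,
    DegenerateBoxError,
    Detection,
    GroundTruthAnnotation,
    ImageRecord,
    TAG_VOCABULARY,
    clip_box,
    iou,
)

__all__ = [
    "SceneConfig",
    "DetectorProfile",
    "Benchmark",
    "generate_scene",
    "simulate_detector",
    "generate_benchmark",
    "uniform_confusion",
]

#: Reference class composition (cells): NG, BG, EG, L, M.
REFERENCE_CLASS_COUNTS: Tuple[int, ...] = (4135, 300, 1100, 1879, 1181)

_DEFAULT_FREQS = tuple(c / sum(REFERENCE_CLASS_COUNTS) for c in REFERENCE_CLASS_COUNTS)

#: Default image-level tag probabilities. The per-factor prevalences of the
#: reference dataset are not published, so these are free parameters chosen to
#: give every factor non-trivial representation in a few hundred images.
_DEFAULT_IMAGE_TAG_PROBS: Dict[str, float] = {
    "color_cast": 0.05,
    "low_illumination": 0.05,
    "giant_platelets": 0.03,
    "wrong_focus": 0.05,
    "impurity": 0.06,
    "high_ph": 0.04,
    "low_ph": 0.04,
}

#: Default per-cell tag probabilities (applied independently per ground truth).
_DEFAULT_CELL_TAG_PROBS: Dict[str, float] = {
    "incomplete": 0.05,
    "degenerated": 0.04,
}


#: Sub-pixel grid for generated coordinates: 1/1024 px. Snapping every box to
#: a dyadic grid keeps corner <-> x/y/width/height conversions bit-exact (the
#: differences and sums involved are then exactly representable), so written
#: benchmarks round-trip losslessly; 1/1024 px is far below any meaningful
#: localisation precision.
_GRID: float = 1024.0


def _snap(v: float) -> float:
    return round(v * _GRID) / _GRID


def _snap_box(b: Box) -> Box:
    return Box(_snap(b.x1), _snap(b.y1), _snap(b.x2), _snap(b.y2))


def uniform_confusion(accuracy: float) -> np.ndarray:
    """Row-stochastic 5x5 confusion matrix with ``accuracy`` on the diagonal
    and the remaining mass spread evenly over the other four classes."""
    if not (0.0 <= accuracy <= 1.0):
        raise ValueError(f"accuracy must be in [0, 1], got {accuracy}")
    k = len(ClassLabel)
    off = (1.0 - accuracy) / (k - 1)
    mat = np.full((k, k), off)
    np.fill_diagonal(mat, accuracy)
    return mat


@dataclass
class SceneConfig:
    """Ground-truth scene generator configuration.

    The cells-per-image count is ``base_cells + Poisson(extra_cells_rate)``;
    the defaults (1 + Poisson(0.37)) reproduce both the reference dataset's mean cell count
    (~1.37 cells/image) and its fraction of multi-cell images (~32%). Cell
    boxes are near-square with side ~ Normal(size_mean, size_sd) clipped to
    [size_min, size_max]; placement retries until the new cell overlaps every
    existing one below ``max_cell_overlap`` IoU (cells that do overlap above
    ``overlap_tag_iou`` are tagged "overlapping").
    """

    width: float = 600.0
    height: float = 600.0
    base_cells: int = 1
    extra_cells_rate: float = 0.37
    class_frequencies: Tuple[float, ...] = _DEFAULT_FREQS
    size_mean: float = 100.0
    size_sd: float = 15.0
    size_min: float = 40.0
    size_max: float = 200.0
    aspect_jitter: float = 0.15
    max_cell_overlap: float = 0.30
    overlap_tag_iou: float = 0.05
    placement_retries: int = 50
    image_tag_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_IMAGE_TAG_PROBS)
    )
    cell_tag_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CELL_TAG_PROBS)
    )
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.class_frequencies)
        if len(freqs) != len(ClassLabel):
            raise ValueError(
                f"class_frequencies needs {len(ClassLabel)} entries, got {len(freqs)}"
            )
        total = sum(freqs)
        if total <= 0:
            raise ValueError("class frequencies must have positive mass")
        self.class_frequencies = tuple(f / total for f in freqs)
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        unknown = (set(self.image_tag_probs) | set(self.cell_tag_probs)) - TAG_VOCABULARY
        if unknown:
            raise ValueError(f"unknown tags in config: {sorted(unknown)}")
        if self.size_min >= min(self.width, self.height):
            raise ValueError("cells cannot be larger than the canvas")


@dataclass
class DetectorProfile:
    """Noise model for one simulated detector.

    miss_rate
        Per-cell false-negative probability.
    fp_rate
        Expected false positives per image (Poisson).
    jitter_scale
        Std. dev. of corner jitter as a fraction of the box's width (for x
        coordinates) or height (for y coordinates).
    confusion
        Row-stochastic 5x5 matrix; row = true class, column = emitted label.
    confidence_base / confidence_slope / confidence_noise_sd / confidence_floor
        Parameters of the localisation-linked confidence model.
    tag_multipliers
        tag -> {"miss": x, "fp": x, "confusion": x} multipliers applied when a
        cell or its image carries the tag; "confusion" scales the off-diagonal
        mass of the cell's confusion row.
    """

    miss_rate: float = 0.1
    fp_rate: float = 0.5
    jitter_scale: float = 0.05
    confusion: np.ndarray = field(default_factory=lambda: uniform_confusion(0.95))
    confidence_base: float = 0.95
    confidence_slope: float = 1.0
    confidence_noise_sd: float = 0.03
    confidence_floor: float = 0.05
    fp_size_range: Tuple[float, float] = (40.0, 160.0)
    fp_confidence_range: Tuple[float, float] = (0.05, 0.5)
    tag_multipliers: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "overlapping": {"miss": 2.0},
            "incomplete": {"miss": 1.5, "confusion": 1.5},
            "impurity": {"fp": 2.0},
            "high_ph": {"confusion": 2.0},
            "low_ph": {"confusion": 2.0},
            "degenerated": {"confusion": 2.0},
        }
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError(f"miss_rate must be in [0, 1], got {self.miss_rate}")
        if self.fp_rate < 0:
            raise ValueError(f"fp_rate must be >= 0, got {self.fp_rate}")
        if self.jitter_scale < 0:
            raise ValueError(f"jitter_scale must be >= 0, got {self.jitter_scale}")
        mat = np.asarray(self.confusion, dtype=float)
        if mat.shape != (len(ClassLabel), len(ClassLabel)):
            raise ValueError(f"confusion matrix must be 5x5, got {mat.shape}")
        if np.any(mat < 0) or not np.allclose(mat.sum(axis=1), 1.0):
            raise ValueError("confusion matrix rows must be non-negative and sum to 1")
        self.confusion = mat
        unknown = set(self.tag_multipliers) - TAG_VOCABULARY
        if unknown:
            raise ValueError(f"unknown tags in profile: {sorted(unknown)}")


def _scale_confusion_row(row: np.ndarray, true_idx: int, mult: float) -> np.ndarray:
    """Multiply a confusion row's off-diagonal mass by ``mult`` (capped so the
    row stays a probability vector)."""
    off = 1.0 - row[true_idx]
    new_off = min(off * mult, 1.0)
    out = row.copy()
    if off > 0:
        out *= new_off / off
    else:
        out[:] = new_off / (len(row) - 1)
    out[true_idx] = 1.0 - new_off
    return out


def generate_scene(cfg: SceneConfig, rng: np.random.Generator, image_id: int = 0) -> ImageRecord:
    """Generate one ground-truth scene.

    Boxes are placed by rejection sampling so no pair exceeds
    ``cfg.max_cell_overlap`` IoU; after ``placement_retries`` failures for a
    cell the scene raises (infeasible configuration — cells too large or too
    many for the canvas). Image-level tags apply to every cell in the image;
    cell-level tags are drawn independently per cell.
    """
    n_cells = cfg.base_cells + int(rng.poisson(cfg.extra_cells_rate))
    image_tags = {
        tag for tag, p in sorted(cfg.image_tag_probs.items()) if rng.random() < p
    }
    boxes: List[Box] = []
    labels: List[ClassLabel] = []
    for _ in range(n_cells):
        placed = None
        for _attempt in range(cfg.placement_retries):
            side = float(np.clip(rng.normal(cfg.size_mean, cfg.size_sd), cfg.size_min, cfg.size_max))
            aspect = float(np.exp(rng.uniform(-cfg.aspect_jitter, cfg.aspect_jitter)))
            w = min(side * aspect, cfg.width - 1.0)
            h = min(side / aspect, cfg.height - 1.0)
            x1 = rng.uniform(0.0, cfg.width - w)
            y1 = rng.uniform(0.0, cfg.height - h)
            cand = _snap_box(Box(x1, y1, x1 + w, y1 + h))
            if cand.x1 < 0 or cand.y1 < 0 or cand.x2 > cfg.width or cand.y2 > cfg.height:
                continue
            if all(iou(cand, b) <= cfg.max_cell_overlap for b in boxes):
                placed = cand
                break
        if placed is None:
            raise RuntimeError(
                f"could not place cell {len(boxes) + 1}/{n_cells} after "
                f"{cfg.placement_retries} retries; scene configuration infeasible"
            )
        boxes.append(placed)
        labels.append(ClassLabel(int(rng.choice(len(ClassLabel), p=cfg.class_frequencies))))

    gts: List[GroundTruthAnnotation] = []
    for i, (b, lab) in enumerate(zip(boxes, labels)):
        tags = set(image_tags)
        for tag, p in sorted(cfg.cell_tag_probs.items()):
            if rng.random() < p:
                tags.add(tag)
        if any(j != i and iou(b, boxes[j]) > cfg.overlap_tag_iou for j in range(len(boxes))):
            tags.add("overlapping")
        gts.append(
            GroundTruthAnnotation(box=b, label=lab, image_id=image_id, tags=frozenset(tags))
        )
    return ImageRecord(
        image_id=image_id, width=cfg.width, height=cfg.height, ground_truths=gts
    )


def _effective(
    profile: DetectorProfile, tags: frozenset, kind: str, base: float
) -> float:
    mult = 1.0
    for tag in tags:
        mult *= float(profile.tag_multipliers.get(tag, {}).get(kind, 1.0))
    return base * mult


def simulate_detector(
    image: ImageRecord,
    profile: DetectorProfile,
    rng: np.random.Generator,
    model_id: str = "model",
) -> List[Detection]:
    """Simulate one noisy detector over a scene's ground truths.

    For each cell: with probability ``1 - miss`` (tag-adjusted) emit a
    detection whose corners are jittered, whose label is drawn from the
    (tag-adjusted) confusion row, and whose confidence decreases with the
    realised localisation error. Additionally emit Poisson false positives
    with random boxes, uniform labels, and low confidences.
    """
    dets: List[Detection] = []
    for gt in image.ground_truths:
        miss = min(_effective(profile, gt.tags, "miss", profile.miss_rate), 1.0)
        if rng.random() < miss:
            continue
        b = gt.box
        jitter = None
        for _ in range(20):
            dx = rng.normal(0.0, profile.jitter_scale * b.width, size=2)
            dy = rng.normal(0.0, profile.jitter_scale * b.height, size=2)
            x1, x2 = b.x1 + dx[0], b.x2 + dx[1]
            y1, y2 = b.y1 + dy[0], b.y2 + dy[1]
            if x1 < x2 and y1 < y2:
                try:
                    jitter = _snap_box(
                        clip_box(Box(x1, y1, x2, y2), image.width, image.height)
                    )
                except (DegenerateBoxError, BoxError):
                    jitter = None
                if jitter is not None:
                    break
        if jitter is None:
            continue  # jitter pathologically destroyed the box: count as a miss
        conf_mult = _effective(profile, gt.tags, "confusion", 1.0)
        row = profile.confusion[int(gt.label)]
        if conf_mult != 1.0:
            row = _scale_confusion_row(row, int(gt.label), conf_mult)
        label = ClassLabel(int(rng.choice(len(ClassLabel), p=row)))
        quality = iou(jitter, gt.box)
        conf = (
            profile.confidence_base
            - profile.confidence_slope * (1.0 - quality)
            + rng.normal(0.0, profile.confidence_noise_sd)
        )
        conf = float(np.clip(conf, profile.confidence_floor, 1.0))
        dets.append(Detection(box=jitter, confidence=conf, label=label, model_id=model_id))

    image_tags = frozenset().union(*(g.tags for g in image.ground_truths)) if image.ground_truths else frozenset()
    fp_rate = _effective(profile, image_tags, "fp", profile.fp_rate)
    n_fp = int(rng.poisson(fp_rate))
    for _ in range(n_fp):
        w = rng.uniform(*profile.fp_size_range)
        h = rng.uniform(*profile.fp_size_range)
        w = min(w, image.width - 1.0)
        h = min(h, image.height - 1.0)
        x1 = rng.uniform(0.0, image.width - w)
        y1 = rng.uniform(0.0, image.height - h)
        label = ClassLabel(int(rng.integers(len(ClassLabel))))
        conf = float(rng.uniform(*profile.fp_confidence_range))
        box = _snap_box(Box(x1, y1, x1 + w, y1 + h))
        dets.append(Detection(box=box, confidence=conf, label=label, model_id=model_id))
    return dets


@dataclass
class Benchmark:
    """A complete synthetic benchmark: scenes with per-model detections, the
    train/test split, and the provenance (seed) it was generated from."""

    images: List[ImageRecord]
    train_ids: List[int]
    test_ids: List[int]
    seed: int

    def subset(self, ids: Sequence[int]) -> "Benchmark":
        keep = set(ids)
        return Benchmark(
            images=[im for im in self.images if im.image_id in keep],
            train_ids=[i for i in self.train_ids if i in keep],
            test_ids=[i for i in self.test_ids if i in keep],
            seed=self.seed,
        )

    def gts_by_image(self) -> Dict[int, List[GroundTruthAnnotation]]:
        return {im.image_id: im.ground_truths for im in self.images}

    def dets_by_image(self, model_id: str) -> Dict[int, List[Detection]]:
        return {im.image_id: im.detections.get(model_id, []) for im in self.images}

    @property
    def model_ids(self) -> List[str]:
        ids: List[str] = []
        for im in self.images:
            for m in im.detections:
                if m not in ids:
                    ids.append(m)
        return ids


def generate_benchmark(
    scene_cfg: SceneConfig,
    profiles: Sequence[DetectorProfile],
    n_images: int,
    seed: int,
    model_ids: Optional[Sequence[str]] = None,
) -> Benchmark:
    """Generate a self-consistent multi-detector benchmark.

    Scenes are generated first, then each detector is simulated over every
    scene with its own child random stream, so adding a detector never
    perturbs the ground truths. The train/test split (default 4:1) is a
    deterministic permutation of image ids under the same seed.
    """
    if len(profiles) < 1:
        raise ValueError("at least one detector profile is required")
    if model_ids is None:
        model_ids = [f"model_{i}" for i in range(len(profiles))]
    if len(model_ids) != len(profiles):
        raise ValueError("model_ids and profiles must have equal length")

    ss = np.random.SeedSequence(seed)
    scene_seed, det_seed, split_seed = ss.spawn(3)
    scene_rng = np.random.default_rng(scene_seed)
    images = [generate_scene(scene_cfg, scene_rng, image_id=i) for i in range(n_images)]

    det_rngs = [np.random.default_rng(s) for s in det_seed.spawn(len(profiles))]
    for mid, profile, rng in zip(model_ids, profiles, det_rngs):
        for im in images:
            im.detections[mid] = simulate_detector(im, profile, rng, model_id=mid)

    split_rng = np.random.default_rng(split_seed)
    order = split_rng.permutation(n_images)
    n_train = int(round(scene_cfg.train_fraction * n_images))
    train_ids = sorted(int(i) for i in order[:n_train])
    test_ids = sorted(int(i) for i in order[n_train:])
    return Benchmark(images=images, train_ids=train_ids, test_ids=test_ids, seed=seed)
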