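"""Domain types and box geometry for leukocyte detection ensembles.

Coordinate convention: continuous corner coordinates ``[x1, y1, x2, y2]``,
origin at the top-left of the image, y increasing downward, zero-based.
Areas are ``(x2 - x1) * (y2 - y1)`` with no +1 pixel correction, so IoU and
the fusion equations are invariant under joint translation and uniform
scaling. Coordinates may be fractional: confidence-weighted averaging of
boxes produces non-integer corners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, FrozenSet, Iterable, List, Tuple

__all__ = [
    "Box",
    "BoxError",
    "DegenerateBoxError",
    "ClassLabel",
    "LabelError",
    "parse_label",
    "Detection",
    "GroundTruthAnnotation",
    "ImageRecord",
    "TAG_VOCABULARY",
    "iou",
    "clip_box",
    "convert_box",
    "box_from_tuple",
]


class BoxError(ValueError):
    """A box violates the geometric contract (non-finite or non-positive area)."""


class DegenerateBoxError(BoxError):
    """A box lost all area, e.g. it lies entirely outside the image."""


class LabelError(ValueError):
    """A class label is outside the closed five-type leukocyte vocabulary."""


class ClassLabel(IntEnum):
    """The five peripheral-blood leukocyte types, in canonical index order.

    NG neutrophil, BG basophil, EG eosinophil, L lymphocyte, M monocyte.
    The integer values define the canonical order used for deterministic
    tie-breaking and for confusion-matrix axes.
    """

    NG = 0
    BG = 1
    EG = 2
    L = 3
    M = 4


#: Accepted spellings for each leukocyte type (case-insensitive at parse time).
LABEL_ALIASES: Dict[str, ClassLabel] = {
    "ng": ClassLabel.NG,
    "neutrophil": ClassLabel.NG,
    "neutrophil granulocyte": ClassLabel.NG,
    "bg": ClassLabel.BG,
    "basophil": ClassLabel.BG,
    "eg": ClassLabel.EG,
    "eosinophil": ClassLabel.EG,
    "l": ClassLabel.L,
    "lymphocyte": ClassLabel.L,
    "m": ClassLabel.M,
    "monocyte": ClassLabel.M,
}


def parse_label(name: str) -> ClassLabel:
    """Map a label string onto the closed five-type vocabulary.

    Raises :class:`LabelError` for anything outside the alias table; unknown
    strings are never coerced silently.
    """
    key = str(name).strip().lower()
    try:
        return LABEL_ALIASES[key]
    except KeyError:
        raise LabelError(
            f"unknown leukocyte class {name!r}; expected one of "
            f"{sorted({l.name for l in ClassLabel})} or a known alias"
        ) from None


#: Closed vocabulary of interference-factor tags. The first nine name the
#: clinically observed image-quality perturbations (staining colour cast, low
#: illumination, giant platelets, wrong focus, dye/debris impurities,
#: overlapping cells, degenerated cells, phosphate-buffer pH above 6.8 or
#: below 6.4); "incomplete" marks cells only partially inside the field.
TAG_VOCABULARY: FrozenSet[str] = frozenset(
    {
        "color_cast",
        "low_illumination",
        "giant_platelets",
        "wrong_focus",
        "impurity",
        "overlapping",
        "degenerated",
        "high_ph",
        "low_ph",
        "incomplete",
    }
)


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle by corner coordinates ``[x1, y1, x2, y2]``.

    Invariants: all coordinates finite, ``x1 < x2`` and ``y1 < y2`` (strictly
    positive area). Zero-area boxes are rejected at construction rather than
    repaired, because they poison IoU denominators and fusion weights.
    """

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        for name in ("x1", "y1", "x2", "y2"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise BoxError(f"box coordinate {name}={v!r} is not finite")
        if not self.x1 < self.x2:
            raise BoxError(
                f"box has non-positive width: x1={self.x1} must be < x2={self.x2}"
            )
        if not self.y1 < self.y2:
            raise BoxError(
                f"box has non-positive height: y1={self.y1} must be < y2={self.y2}"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    def corners(self) -> Tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when identical."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    if a.corners() == b.corners():
        return 1.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def clip_box(b: Box, width: float, height: float) -> Box:
    """Clamp a box to the image extent ``[0, width] x [0, height]``.

    Raises :class:`DegenerateBoxError` if clipping destroys all area (the box
    lies entirely outside the image).
    """
    if width <= 0 or height <= 0:
        raise ValueError(f"image extent must be positive, got {width}x{height}")
    x1 = min(max(b.x1, 0.0), width)
    x2 = min(max(b.x2, 0.0), width)
    y1 = min(max(b.y1, 0.0), height)
    y2 = min(max(b.y2, 0.0), height)
    if x1 >= x2 or y1 >= y2:
        raise DegenerateBoxError(
            f"box {b.corners()} has no area inside a {width}x{height} image"
        )
    return Box(x1, y1, x2, y2)


def convert_box(b: Box, dialect: str) -> Tuple[float, float, float, float]:
    """Express a box as a 4-tuple in the requested coordinate dialect.

    ``corners`` is ``(x1, y1, x2, y2)``; ``xywh`` is the COCO convention
    ``(x, y, width, height)``. Round trips through :func:`box_from_tuple` are
    bit-identical whenever the corner pair is exactly representable in the
    target dialect — always the case for coordinates on a dyadic sub-pixel
    grid such as the ones the synthetic generator emits.
    """
    if dialect == "corners":
        return b.corners()
    if dialect == "xywh":
        return (b.x1, b.y1, b.x2 - b.x1, b.y2 - b.y1)
    raise ValueError(f"unknown box dialect {dialect!r}; expected 'corners' or 'xywh'")


def box_from_tuple(values: Iterable[float], dialect: str) -> Box:
    """Build a :class:`Box` from a 4-tuple in the given dialect."""
    x, y, a, b = (float(v) for v in values)
    if dialect == "corners":
        return Box(x, y, a, b)
    if dialect == "xywh":
        return Box(x, y, x + a, y + b)
    raise ValueError(f"unknown box dialect {dialect!r}; expected 'corners' or 'xywh'")


@dataclass(frozen=True)
class Detection:
    """One detector's prediction: a box, a confidence in [0, 1], a class label,
    and the identifier of the source model."""

    box: Box
    confidence: float
    label: ClassLabel
    model_id: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(
                f"confidence must be in [0, 1], got {self.confidence!r} "
                f"(model {self.model_id!r})"
            )


@dataclass(frozen=True)
class GroundTruthAnnotation:
    """An expert-labelled cell: box, true class, owning image, and the set of
    interference-factor tags that apply to it (possibly empty)."""

    box: Box
    label: ClassLabel
    image_id: int
    tags: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.tags) - TAG_VOCABULARY
        if unknown:
            raise ValueError(
                f"annotation on image {self.image_id} carries unknown tags "
                f"{sorted(unknown)}; vocabulary is {sorted(TAG_VOCABULARY)}"
            )
        object.__setattr__(self, "tags", frozenset(self.tags))


@dataclass
class ImageRecord:
    """One image's worth of data: extent, ground truths, and the per-model
    detection lists keyed by model id."""

    image_id: int
    width: float
    height: float
    ground_truths: List[GroundTruthAnnotation] = field(default_factory=list)
    detections: Dict[str, List[Detection]] = field(default_factory=dict)
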