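import numpy as np
import pytest

from leukofuse.core import Box, ClassLabel, Detection, GroundTruthAnnotation, ImageRecord


def make_det(corners, conf, label=ClassLabel.NG, model="m0"):
    return Detection(box=Box(*corners), confidence=conf, label=label, model_id=model)


def make_gt(corners, label=ClassLabel.NG, image_id=0, tags=()):
    return GroundTruthAnnotation(
        box=Box(*corners), label=label, image_id=image_id, tags=frozenset(tags)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230207)


def random_instance(rng, n_models=None, max_boxes=12, canvas=200.0):
    """A random multi-model detection instance with clusterable geometry:
    boxes are jittered copies around a few shared anchors plus strays."""
    n_models = n_models or int(rng.integers(2, 7))
    n_anchors = int(rng.integers(1, 4))
    anchors = []
    for _ in range(n_anchors):
        w = rng.uniform(20, 60)
        h = rng.uniform(20, 60)
        x = rng.uniform(0, canvas - w)
        y = rng.uniform(0, canvas - h)
        anchors.append((x, y, x + w, y + h))
    per_model = {}
    total = 0
    for m in range(n_models):
        dets = []
        for ax in anchors:
            if total >= max_boxes:
                break
            if rng.random() < 0.75:
                jit = rng.normal(0, 2.0, size=4)
                x1, y1, x2, y2 = (c + j for c, j in zip(ax, jit))
                if x1 >= x2 or y1 >= y2:
                    continue
                dets.append(
                    Detection(
                        box=Box(x1, y1, x2, y2),
                        confidence=float(rng.uniform(0.05, 1.0)),
                        label=ClassLabel(int(rng.integers(5))),
                        model_id=f"m{m}",
                    )
                )
                total += 1
        if total < max_boxes and rng.random() < 0.3:
            w = rng.uniform(10, 40)
            h = rng.uniform(10, 40)
            x = rng.uniform(0, canvas - w)
            y = rng.uniform(0, canvas - h)
            dets.append(
                Detection(
                    box=Box(x, y, x + w, y + h),
                    confidence=float(rng.uniform(0.05, 1.0)),
                    label=ClassLabel(int(rng.integers(5))),
                    model_id=f"m{m}",
                )
            )
            total += 1
        per_model[f"m{m}"] = dets
    return per_model
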