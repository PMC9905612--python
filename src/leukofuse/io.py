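"""Readers and writers for the standard detection formats.

Supported formats:

* COCO annotation JSON (``images`` / ``annotations`` / ``categories``) with
  ``bbox`` in ``[x, y, width, height]``;
* COCO results JSON — a flat array of
  ``{image_id, category_id, bbox, score}`` records, one file per detector;
* Pascal VOC XML — one file per image with ``object/bndbox`` entries. VOC
  corners are 1-based inclusive pixel indices; conversion to the internal
  0-based continuous convention subtracts 1 from xmin/ymin only, so VOC round
  trips are lossless up to that documented shift;
* a JSON tag sidecar mapping image ids and annotation ids to
  interference-factor tags;
* evaluation reports as JSON or CSV with the column order
  mAP, mAP@IoU0.50, mAP@IoU0.75, mAR, AP-BG, AP-EG, AP-NG, AP-M, AP-L.

All readers reject malformed records with an error naming the offending
record; nothing is silently repaired. The category-id <-> class-label mapping
is explicit configuration, never inferred from name order.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import (
    Box,
    BoxError,
    ClassLabel,
    Detection,
    GroundTruthAnnotation,
    ImageRecord,
    TAG_VOCABULARY,
    box_from_tuple,
    convert_box,
    parse_label,
)
from .evaluation import EvalReport, PRCurve

__all__ = [
    "ParseError",
    "CategoryMap",
    "DEFAULT_CATEGORY_MAP",
    "DatasetBundle",
    "read_coco_annotations",
    "write_coco_annotations",
    "read_coco_results",
    "write_coco_results",
    "read_voc_xml",
    "write_voc_xml",
    "read_tag_sidecar",
    "write_tag_sidecar",
    "read_dataset_bundle",
    "write_benchmark",
    "write_report",
    "write_pr_curves",
]

#: Column order of the tabular report.
REPORT_COLUMNS = [
    "mAP",
    "mAP@IoU0.50",
    "mAP@IoU0.75",
    "mAR",
    "AP-BG",
    "AP-EG",
    "AP-NG",
    "AP-M",
    "AP-L",
]

_REPORT_CLASS_ORDER = [ClassLabel.BG, ClassLabel.EG, ClassLabel.NG, ClassLabel.M, ClassLabel.L]


class ParseError(ValueError):
    """A record in an input file violates the format contract."""


@dataclass(frozen=True)
class CategoryMap:
    """Explicit bijection between COCO category ids and the five leukocyte
    labels."""

    id_to_label: Mapping[int, ClassLabel]

    def __post_init__(self) -> None:
        labels = set(self.id_to_label.values())
        if labels != set(ClassLabel):
            raise ValueError(
                "category map must be a bijection onto the five leukocyte classes; "
                f"covered: {sorted(l.name for l in labels)}"
            )
        if len(self.id_to_label) != len(ClassLabel):
            raise ValueError("category map has duplicate labels")

    def label(self, category_id: int, where: str = "") -> ClassLabel:
        try:
            return self.id_to_label[int(category_id)]
        except KeyError:
            raise ParseError(
                f"unknown category id {category_id}{' in ' + where if where else ''}"
            ) from None

    def category_id(self, label: ClassLabel) -> int:
        for cid, lab in self.id_to_label.items():
            if lab == label:
                return cid
        raise KeyError(label)


DEFAULT_CATEGORY_MAP = CategoryMap(
    id_to_label={1: ClassLabel.NG, 2: ClassLabel.BG, 3: ClassLabel.EG, 4: ClassLabel.L, 5: ClassLabel.M}
)


@dataclass
class DatasetBundle:
    """In-memory dataset: images with ground truths, plus per-model detections
    keyed by model id, resolved against a category map."""

    images: Dict[int, ImageRecord]
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP

    def gts_by_image(self) -> Dict[int, List[GroundTruthAnnotation]]:
        return {i: im.ground_truths for i, im in self.images.items()}

    def dets_by_image(self, model_id: str) -> Dict[int, List[Detection]]:
        return {i: im.detections.get(model_id, []) for i, im in self.images.items()}


def _corner_box(bbox: Sequence[float], where: str) -> Box:
    if len(bbox) != 4:
        raise ParseError(f"bbox must have 4 entries in {where}, got {bbox!r}")
    try:
        return box_from_tuple(bbox, "xywh")
    except (BoxError, TypeError, ValueError) as e:
        raise ParseError(f"invalid bbox {bbox!r} in {where}: {e}") from None


def read_coco_annotations(
    path: str | Path,
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
    tags: Optional[Mapping] = None,
) -> DatasetBundle:
    """Read a COCO annotation file into a :class:`DatasetBundle`.

    ``tags`` may carry a pre-loaded tag sidecar (see
    :func:`read_tag_sidecar`); annotation tags are the union of the owning
    image's tags and the annotation's own.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("images", "annotations"):
        if key not in doc:
            raise ParseError(f"{path} is missing the COCO '{key}' section")
    images: Dict[int, ImageRecord] = {}
    for rec in doc["images"]:
        try:
            iid = int(rec["id"])
            images[iid] = ImageRecord(
                image_id=iid, width=float(rec["width"]), height=float(rec["height"])
            )
        except KeyError as e:
            raise ParseError(f"image record {rec!r} is missing key {e}") from None
    img_tags = (tags or {}).get("images", {})
    ann_tags = (tags or {}).get("annotations", {})
    for rec in doc["annotations"]:
        where = f"annotation id {rec.get('id', '?')}"
        try:
            iid = int(rec["image_id"])
            box = _corner_box(rec["bbox"], where)
            label = category_map.label(rec["category_id"], where)
        except KeyError as e:
            raise ParseError(f"{where} is missing key {e}") from None
        if iid not in images:
            raise ParseError(f"{where} references unknown image_id {iid}")
        merged = set(img_tags.get(iid, ())) | set(ann_tags.get(rec.get("id"), ()))
        images[iid].ground_truths.append(
            GroundTruthAnnotation(box=box, label=label, image_id=iid, tags=frozenset(merged))
        )
    return DatasetBundle(images=images, category_map=category_map)


def write_coco_annotations(
    images: Sequence[ImageRecord],
    path: str | Path,
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
) -> None:
    """Write ground truths as a COCO annotation file."""
    doc = {
        "images": [
            {
                "id": im.image_id,
                "width": im.width,
                "height": im.height,
                "file_name": f"{im.image_id}.png",
            }
            for im in images
        ],
        "annotations": [],
        "categories": [
            {"id": cid, "name": lab.name}
            for cid, lab in sorted(category_map.id_to_label.items())
        ],
    }
    ann_id = 1
    for im in images:
        for gt in im.ground_truths:
            x, y, w, h = convert_box(gt.box, "xywh")
            doc["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": im.image_id,
                    "category_id": category_map.category_id(gt.label),
                    "bbox": [x, y, w, h],
                    "area": w * h,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_coco_results(
    path: str | Path,
    model_id: str,
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
    known_image_ids: Optional[Sequence[int]] = None,
) -> Dict[int, List[Detection]]:
    """Read a COCO results array into per-image detection lists.

    Scores outside [0, 1] and degenerate boxes are rejected with the record's
    position; when ``known_image_ids`` is given, dangling image ids are too.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, list):
        raise ParseError(f"{path} is not a COCO results array")
    known = set(known_image_ids) if known_image_ids is not None else None
    out: Dict[int, List[Detection]] = {}
    for i, rec in enumerate(doc):
        where = f"result record #{i} in {path.name}"
        try:
            iid = int(rec["image_id"])
            score = float(rec["score"])
            box = _corner_box(rec["bbox"], where)
            label = category_map.label(rec["category_id"], where)
        except KeyError as e:
            raise ParseError(f"{where} is missing key {e}") from None
        if not (0.0 <= score <= 1.0) or not math.isfinite(score):
            raise ParseError(f"{where} has score {score} outside [0, 1]")
        if known is not None and iid not in known:
            raise ParseError(f"{where} references unknown image_id {iid}")
        out.setdefault(iid, []).append(
            Detection(box=box, confidence=score, label=label, model_id=model_id)
        )
    return out


def write_coco_results(
    dets_by_image: Mapping[int, Sequence],
    path: str | Path,
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
) -> None:
    """Write per-image detections (or fused detections) as a COCO results
    array."""
    doc = []
    for iid in sorted(dets_by_image):
        for d in dets_by_image[iid]:
            x, y, w, h = convert_box(d.box, "xywh")
            doc.append(
                {
                    "image_id": iid,
                    "category_id": category_map.category_id(d.label),
                    "bbox": [x, y, w, h],
                    "score": d.confidence,
                }
            )
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_voc_xml(directory: str | Path) -> DatasetBundle:
    """Read a directory of Pascal VOC XML annotation files.

    VOC stores 1-based inclusive pixel corners; the internal 0-based
    continuous convention is recovered by subtracting 1 from xmin/ymin only.
    Object names are resolved through the label alias table (e.g.
    "neutrophil" -> NG).
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.xml"))
    if not files:
        raise ParseError(f"no VOC XML files found in {directory}")
    images: Dict[int, ImageRecord] = {}
    for fp in files:
        try:
            root = ET.parse(fp).getroot()
        except ET.ParseError as e:
            raise ParseError(f"malformed XML in {fp.name}: {e}") from None
        try:
            iid = int(root.findtext("image_id", default=str(len(images))))
            width = float(root.findtext("size/width"))
            height = float(root.findtext("size/height"))
        except (TypeError, ValueError):
            raise ParseError(f"{fp.name} is missing size/width or size/height") from None
        rec = ImageRecord(image_id=iid, width=width, height=height)
        for obj in root.iter("object"):
            name = obj.findtext("name")
            bnd = obj.find("bndbox")
            if name is None or bnd is None:
                raise ParseError(f"object in {fp.name} lacks a name or bndbox")
            try:
                xmin = float(bnd.findtext("xmin"))
                ymin = float(bnd.findtext("ymin"))
                xmax = float(bnd.findtext("xmax"))
                ymax = float(bnd.findtext("ymax"))
            except (TypeError, ValueError):
                raise ParseError(f"bndbox in {fp.name} has non-numeric corners") from None
            try:
                box = Box(xmin - 1.0, ymin - 1.0, xmax, ymax)
            except BoxError as e:
                raise ParseError(f"degenerate bndbox in {fp.name}: {e}") from None
            rec.ground_truths.append(
                GroundTruthAnnotation(box=box, label=parse_label(name), image_id=iid)
            )
        images[iid] = rec
    return DatasetBundle(images=images)


def write_voc_xml(images: Sequence[ImageRecord], directory: str | Path) -> None:
    """Write ground truths as one VOC XML file per image (corners converted
    back to the 1-based inclusive convention: +1 on xmin/ymin)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for im in images:
        root = ET.Element("annotation")
        ET.SubElement(root, "image_id").text = str(im.image_id)
        ET.SubElement(root, "filename").text = f"{im.image_id}.png"
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(im.width)
        ET.SubElement(size, "height").text = str(im.height)
        ET.SubElement(size, "depth").text = "3"
        for gt in im.ground_truths:
            obj = ET.SubElement(root, "object")
            ET.SubElement(obj, "name").text = gt.label.name
            bnd = ET.SubElement(obj, "bndbox")
            ET.SubElement(bnd, "xmin").text = repr(gt.box.x1 + 1.0)
            ET.SubElement(bnd, "ymin").text = repr(gt.box.y1 + 1.0)
            ET.SubElement(bnd, "xmax").text = repr(gt.box.x2)
            ET.SubElement(bnd, "ymax").text = repr(gt.box.y2)
        ET.ElementTree(root).write(directory / f"{im.image_id}.xml")


def read_tag_sidecar(path: str | Path) -> Dict[str, Dict[int, List[str]]]:
    """Read the JSON tag sidecar ({"images": {...}, "annotations": {...}})."""
    with open(path) as fh:
        doc = json.load(fh)
    out: Dict[str, Dict[int, List[str]]] = {"images": {}, "annotations": {}}
    for section in ("images", "annotations"):
        for key, tags in doc.get(section, {}).items():
            bad = set(tags) - TAG_VOCABULARY
            if bad:
                raise ParseError(
                    f"sidecar {section} entry {key} has unknown tags {sorted(bad)}"
                )
            out[section][int(key)] = list(tags)
    return out


def write_tag_sidecar(
    images: Sequence[ImageRecord], path: str | Path
) -> None:
    """Write per-annotation tags (keyed by the COCO annotation ids assigned by
    :func:`write_coco_annotations`, i.e. 1-based in writing order)."""
    ann_tags: Dict[int, List[str]] = {}
    ann_id = 1
    for im in images:
        for gt in im.ground_truths:
            if gt.tags:
                ann_tags[ann_id] = sorted(gt.tags)
            ann_id += 1
    with open(path, "w") as fh:
        json.dump({"images": {}, "annotations": ann_tags}, fh)


def read_dataset_bundle(
    annotations: str | Path,
    results: Mapping[str, str | Path] = (),
    sidecar: Optional[str | Path] = None,
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
) -> DatasetBundle:
    """Load annotations, an optional tag sidecar, and any number of per-model
    COCO results files into one validated bundle."""
    tags = read_tag_sidecar(sidecar) if sidecar else None
    bundle = read_coco_annotations(annotations, category_map, tags=tags)
    for model_id, path in dict(results).items():
        dets = read_coco_results(
            path, model_id, category_map, known_image_ids=list(bundle.images)
        )
        for iid, lst in dets.items():
            bundle.images[iid].detections[model_id] = lst
    return bundle


def write_benchmark(
    benchmark,
    directory: str | Path,
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
) -> Dict[str, Path]:
    """Write a synthetic benchmark as COCO annotations + one results file per
    model + tag sidecar + split file. Returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    ann = directory / "annotations.json"
    write_coco_annotations(benchmark.images, ann, category_map)
    paths["annotations"] = ann
    sidecar = directory / "tags.json"
    write_tag_sidecar(benchmark.images, sidecar)
    paths["tags"] = sidecar
    for mid in benchmark.model_ids:
        p = directory / f"results_{mid}.json"
        write_coco_results(benchmark.dets_by_image(mid), p, category_map)
        paths[f"results:{mid}"] = p
    split = directory / "split.json"
    with open(split, "w") as fh:
        json.dump(
            {"seed": benchmark.seed, "train": benchmark.train_ids, "test": benchmark.test_ids},
            fh,
        )
    paths["split"] = split
    return paths


def _report_row(report: EvalReport) -> Dict[str, object]:
    row: Dict[str, object] = {
        "mAP": report.map_50_95,
        "mAP@IoU0.50": report.map_50,
        "mAP@IoU0.75": report.map_75,
        "mAR": report.mar_50_95,
    }
    for lab in _REPORT_CLASS_ORDER:
        v = report.per_class_ap.get(lab)
        row[f"AP-{lab.name}"] = v if v is not None else "NA"
    return row


def write_report(report: EvalReport, path: str | Path, format: str = "csv") -> None:
    """Serialize an evaluation report.

    CSV follows the canonical column order; undefined per-class APs are
    written as the explicit token ``NA``, never as 0. JSON additionally
    carries the confusion matrix and per-tag accuracies.
    """
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame([_report_row(report)], columns=REPORT_COLUMNS)
        df.to_csv(path, index=False)
    elif format == "json":
        row = _report_row(report)
        row["confusion_matrix"] = report.confusion.tolist()
        row["confusion_axes"] = [l.name for l in ClassLabel] + ["background"]
        row["tag_accuracy"] = {
            t: (v if v is not None else "NA") for t, v in report.tag_accuracy.items()
        }
        with open(path, "w") as fh:
            json.dump(row, fh, indent=2)
    else:
        raise ValueError(f"unknown report format {format!r}; expected 'csv' or 'json'")


def write_pr_curves(curves: Sequence[PRCurve], path: str | Path) -> None:
    """Export PR curves as long-format CSV (one row per recall grid point)."""
    rows = []
    for c in curves:
        name = c.label.name if c.label is not None else "all"
        for r, p in zip(c.recall, c.precision):
            rows.append(
                {"class": name, "iou_threshold": c.iou_threshold, "recall": r, "precision": p}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
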