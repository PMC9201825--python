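"""Reading and writing detection annotations and predictions.

Three dialects:

* ``gwhd_csv`` — the Kaggle Global Wheat Head CSV: columns
  ``image_id,width,height,bbox`` with ``bbox`` serialized as
  ``[x, y, w, h]`` (single spaces). Prediction files add a ``score`` column.
  One row per box; an image with no boxes is listed once with an empty bbox
  cell so empty images round-trip.
* ``coco_json`` — a COCO-style dict with ``images`` / ``annotations`` /
  ``categories``; annotation ``bbox`` is ``[x, y, w, h]``, predictions carry
  a ``score`` field.
* ``voc_xml`` — one Pascal-VOC XML file per image inside a directory.

Rows are written in deterministic order: image_id, then (y_min, x_min).
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .boxes import Box, BoxValidationError, DetectionSet

__all__ = ["read_annotations", "write_annotations", "DIALECTS"]

DIALECTS = ("gwhd_csv", "coco_json", "voc_xml")

_BBOX_RE = re.compile(r"^\[\s*([^,\]]+)\s*,\s*([^,\]]+)\s*,\s*([^,\]]+)\s*,\s*([^,\]]+)\s*\]$")


def _format_num(v: float) -> str:
    """Render 10.0 as '10' (the GWHD files mix ints and floats) else repr."""
    return str(int(v)) if float(v).is_integer() and abs(v) < 1e15 else repr(float(v))


def _parse_bbox(s: str) -> tuple[float, float, float, float]:
    m = _BBOX_RE.match(s.strip())
    if not m:
        raise ValueError(f"malformed bbox string: {s!r}")
    x, y, w, h = (float(g) for g in m.groups())
    if w < 0 or h < 0:
        raise BoxValidationError(f"negative width/height in bbox {s!r}")
    return x, y, w, h


def _sorted_sets(sets: Iterable[DetectionSet]) -> list[DetectionSet]:
    return sorted(sets, key=lambda d: d.image_id)


# ---------------------------------------------------------------------------
# GWHD CSV
# ---------------------------------------------------------------------------


def _read_gwhd(path: Path) -> list[DetectionSet]:
    df = pd.read_csv(path, dtype={"image_id": str})
    has_score = "score" in df.columns
    sets: dict[str, DetectionSet] = {}
    for row in df.itertuples(index=False):
        image_id = row.image_id
        if image_id not in sets:
            sets[image_id] = DetectionSet(
                image_id=image_id,
                image_width=float(row.width),
                image_height=float(row.height),
                source="prediction:unknown" if has_score else "ground_truth",
            )
        bbox = getattr(row, "bbox", None)
        if bbox is None or (isinstance(bbox, float) and pd.isna(bbox)) or str(bbox).strip() == "":
            continue  # row marks an empty image
        x, y, w, h = _parse_bbox(str(bbox))
        score = None
        if has_score and not pd.isna(row.score):
            score = float(row.score)
        sets[image_id].boxes.append(Box.from_xywh(x, y, w, h, score=score))
    return _sorted_sets(sets.values())


def _write_gwhd(sets: Sequence[DetectionSet], path: Path) -> None:
    scored = any(b.score is not None for s in sets for b in s.boxes)
    rows = []
    for s in _sorted_sets(sets):
        ordered = sorted(s.boxes, key=lambda b: (b.y_min, b.x_min, b.y_max, b.x_max))
        if not ordered:
            row = {
                "image_id": s.image_id,
                "width": _format_num(s.image_width),
                "height": _format_num(s.image_height),
                "bbox": "",
            }
            if scored:
                row["score"] = ""
            rows.append(row)
            continue
        for b in ordered:
            x, y, w, h = b.to_xywh()
            row = {
                "image_id": s.image_id,
                "width": _format_num(s.image_width),
                "height": _format_num(s.image_height),
                "bbox": f"[{_format_num(x)}, {_format_num(y)}, {_format_num(w)}, {_format_num(h)}]",
            }
            if scored:
                row["score"] = "" if b.score is None else repr(float(b.score))
            rows.append(row)
    cols = ["image_id", "width", "height", "bbox"] + (["score"] if scored else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# COCO JSON
# ---------------------------------------------------------------------------


def _read_coco(path: Path) -> list[DetectionSet]:
    data = json.loads(Path(path).read_text())
    cats = {c["id"]: c["name"] for c in data.get("categories", [])}
    sets: dict[int, DetectionSet] = {}
    has_score = any("score" in a for a in data.get("annotations", []))
    for img in data["images"]:
        sets[img["id"]] = DetectionSet(
            image_id=str(img.get("file_name", img["id"])).removesuffix(".png").removesuffix(".jpg"),
            image_width=float(img["width"]),
            image_height=float(img["height"]),
            source="prediction:unknown" if has_score else "ground_truth",
        )
    for ann in data.get("annotations", []):
        x, y, w, h = ann["bbox"]
        if w < 0 or h < 0:
            raise BoxValidationError(f"negative width/height in bbox {ann['bbox']}")
        sets[ann["image_id"]].boxes.append(
            Box.from_xywh(
                float(x),
                float(y),
                float(w),
                float(h),
                score=float(ann["score"]) if "score" in ann else None,
                label=cats.get(ann.get("category_id", 1), "wheat_head"),
            )
        )
    return _sorted_sets(sets.values())


def _write_coco(sets: Sequence[DetectionSet], path: Path) -> None:
    labels = sorted({b.label for s in sets for b in s.boxes}) or ["wheat_head"]
    cat_ids = {name: i + 1 for i, name in enumerate(labels)}
    images, annotations = [], []
    ann_id = 1
    for img_id, s in enumerate(_sorted_sets(sets), start=1):
        images.append(
            {
                "id": img_id,
                "file_name": f"{s.image_id}.png",
                "width": s.image_width,
                "height": s.image_height,
            }
        )
        for b in sorted(s.boxes, key=lambda b: (b.y_min, b.x_min, b.y_max, b.x_max)):
            ann = {
                "id": ann_id,
                "image_id": img_id,
                "category_id": cat_ids[b.label],
                "bbox": list(b.to_xywh()),
                "area": b.area,
                "iscrowd": 0,
            }
            if b.score is not None:
                ann["score"] = b.score
            annotations.append(ann)
            ann_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": n} for n, i in cat_ids.items()],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Pascal-VOC XML (a directory of per-image files)
# ---------------------------------------------------------------------------


def _read_voc(path: Path) -> list[DetectionSet]:
    p = Path(path)
    files = sorted(p.glob("*.xml")) if p.is_dir() else [p]
    sets = []
    for f in files:
        root = ET.parse(f).getroot()
        size = root.find("size")
        ds = DetectionSet(
            image_id=root.findtext("filename", f.stem).rsplit(".", 1)[0],
            image_width=float(size.findtext("width")),
            image_height=float(size.findtext("height")),
        )
        for obj in root.iter("object"):
            bb = obj.find("bndbox")
            score_text = obj.findtext("score")
            ds.boxes.append(
                Box(
                    float(bb.findtext("xmin")),
                    float(bb.findtext("ymin")),
                    float(bb.findtext("xmax")),
                    float(bb.findtext("ymax")),
                    score=float(score_text) if score_text is not None else None,
                    label=obj.findtext("name", "wheat_head"),
                )
            )
        if any(b.score is not None for b in ds.boxes):
            ds.source = "prediction:unknown"
        sets.append(ds)
    return _sorted_sets(sets)


def _write_voc(sets: Sequence[DetectionSet], path: Path) -> None:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for s in _sorted_sets(sets):
        root = ET.Element("annotation")
        ET.SubElement(root, "filename").text = f"{s.image_id}.png"
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = _format_num(s.image_width)
        ET.SubElement(size, "height").text = _format_num(s.image_height)
        ET.SubElement(size, "depth").text = "3"
        for b in sorted(s.boxes, key=lambda b: (b.y_min, b.x_min, b.y_max, b.x_max)):
            obj = ET.SubElement(root, "object")
            ET.SubElement(obj, "name").text = b.label
            bb = ET.SubElement(obj, "bndbox")
            ET.SubElement(bb, "xmin").text = repr(float(b.x_min))
            ET.SubElement(bb, "ymin").text = repr(float(b.y_min))
            ET.SubElement(bb, "xmax").text = repr(float(b.x_max))
            ET.SubElement(bb, "ymax").text = repr(float(b.y_max))
            if b.score is not None:
                ET.SubElement(obj, "score").text = repr(float(b.score))
        ET.ElementTree(root).write(out / f"{s.image_id}.xml")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

_READERS = {"gwhd_csv": _read_gwhd, "coco_json": _read_coco, "voc_xml": _read_voc}
_WRITERS = {"gwhd_csv": _write_gwhd, "coco_json": _write_coco, "voc_xml": _write_voc}


def read_annotations(path: str | Path, dialect: str = "gwhd_csv") -> list[DetectionSet]:
    """Read annotations/predictions; one DetectionSet per image, sorted by id."""
    if dialect not in _READERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    return _READERS[dialect](Path(path))


def write_annotations(
    sets: Sequence[DetectionSet], path: str | Path, dialect: str = "gwhd_csv"
) -> None:
    """Write annotations in deterministic order (image_id, then y_min, x_min)."""
    if dialect not in _WRITERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    _WRITERS[dialect](sets, Path(path))
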