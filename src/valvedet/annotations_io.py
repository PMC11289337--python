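"""Bounding-box geometry and annotation file formats.

Boxes live in image coordinates with the origin at the top-left corner,
x growing right and y growing down; (x1, y1) is the min corner and
(x2, y2) the max corner.  The normalized record used by YOLO-style
label files stores class id, the box centre as a fraction of image
width/height, and the box width/height as fractions:

    b = ((x1 + x2) / 2) / w      c = ((y1 + y2) / 2) / h
    d = (x2 - x1) / w            e = (y2 - y1) / h

Readers/writers for YOLO txt and PASCAL-VOC XML annotations, IoU, and
the deterministic train/val/test splitter all live here.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BBox", "NormalizedBox", "AnnotationError",
    "encode_yolo_box", "decode_yolo_box",
    "read_label_file", "write_label_file",
    "voc_to_yolo", "yolo_to_voc", "iou", "split_dataset",
]


class AnnotationError(ValueError):
    """Malformed box or annotation input."""


@dataclass(frozen=True)
class BBox:
    """Corner-form box: (x1, y1) min corner, (x2, y2) max corner, pixels."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise AnnotationError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class NormalizedBox:
    """YOLO label record: class id + fractional centre/size."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise AnnotationError(f"{name}={v} outside (0, 1]")
        eps = 1e-6
        if (self.cx - self.w / 2 < -eps or self.cx + self.w / 2 > 1 + eps
                or self.cy - self.h / 2 < -eps or self.cy + self.h / 2 > 1 + eps):
            raise AnnotationError(f"box extends outside the unit square: {self}")
        if self.class_id < 0:
            raise AnnotationError("class_id must be non-negative")


def encode_yolo_box(box: BBox, img_w: float, img_h: float, class_id: int = 0) -> NormalizedBox:
    """Normalize a pixel box to the fractional centre/size record."""
    if box.x1 < 0 or box.y1 < 0 or box.x2 > img_w or box.y2 > img_h:
        raise AnnotationError(f"box {box} outside {img_w}x{img_h} image")
    return NormalizedBox(
        class_id=class_id,
        cx=((box.x1 + box.x2) / 2.0) / img_w,
        cy=((box.y1 + box.y2) / 2.0) / img_h,
        w=(box.x2 - box.x1) / img_w,
        h=(box.y2 - box.y1) / img_h,
    )


def decode_yolo_box(n: NormalizedBox, img_w: float, img_h: float) -> BBox:
    """Exact algebraic inverse of :func:`encode_yolo_box`."""
    cx, cy = n.cx * img_w, n.cy * img_h
    w, h = n.w * img_w, n.h * img_h
    return BBox(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


def write_label_file(path, boxes) -> None:
    """Write one ``class cx cy w h`` record per line at 6-decimal precision."""
    lines = [f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}" for b in boxes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_label_file(path) -> list:
    """Parse a YOLO label file; an empty file means no objects."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 5:
            raise AnnotationError(f"{path}:{ln}: expected 5 fields, got {len(fields)}")
        try:
            cls = int(fields[0])
            vals = [float(v) for v in fields[1:]]
        except ValueError as e:
            raise AnnotationError(f"{path}:{ln}: {e}") from e
        try:
            out.append(NormalizedBox(cls, *vals))
        except AnnotationError as e:
            raise AnnotationError(f"{path}:{ln}: {e}") from e
    return out


def voc_to_yolo(xml_doc: str, img_w: float | None = None, img_h: float | None = None,
                class_map: dict | None = None) -> list:
    """Convert a PASCAL-VOC XML annotation document to normalized boxes.

    Image size is read from the document's ``<size>`` element unless
    given explicitly.  ``class_map`` maps object names to class ids;
    by default the single class ``aortic_valve`` maps to 0.
    """
    class_map = class_map if class_map is not None else {"aortic_valve": 0}
    try:
        root = ET.fromstring(xml_doc)
    except ET.ParseError as e:
        raise AnnotationError(f"invalid XML: {e}") from e
    if img_w is None or img_h is None:
        size = root.find("size")
        if size is None:
            raise AnnotationError("no image size in document and none provided")
        img_w = float(size.findtext("width"))
        img_h = float(size.findtext("height"))
    out = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if name not in class_map:
            raise AnnotationError(f"unknown class name {name!r}")
        bb = obj.find("bndbox")
        box = BBox(float(bb.findtext("xmin")), float(bb.findtext("ymin")),
                   float(bb.findtext("xmax")), float(bb.findtext("ymax")))
        out.append(encode_yolo_box(box, img_w, img_h, class_map[name]))
    return out


def yolo_to_voc(boxes, img_w: float, img_h: float,
                class_names: list | None = None, filename: str = "image.png") -> str:
    """Render normalized boxes as a PASCAL-VOC XML document."""
    class_names = class_names or ["aortic_valve"]
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(int(img_w))
    ET.SubElement(size, "height").text = str(int(img_h))
    ET.SubElement(size, "depth").text = "1"
    for n in boxes:
        b = decode_yolo_box(n, img_w, img_h)
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = class_names[n.class_id]
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = repr(b.x1)
        ET.SubElement(bb, "ymin").text = repr(b.y1)
        ET.SubElement(bb, "xmax").text = repr(b.x2)
        ET.SubElement(bb, "ymax").text = repr(b.y2)
    return ET.tostring(root, encoding="unicode")


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes (0 when disjoint)."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def split_dataset(items, ratios=(0.80, 0.05, 0.15), seed: int = 0):
    """Deterministic shuffled train/val/test partition.

    Val and test sizes are floored; the remainder goes to train, so
    260 items at 80/5/15 split as (208, 13, 39).
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise AnnotationError(f"split ratios must sum to 1, got {ratios}")
    items = list(items)
    if not items:
        raise AnnotationError("cannot split an empty item list")
    n = len(items)
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    n_train = n - n_val - n_test
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [items[i] for i in order]
    return (shuffled[:n_train],
            shuffled[n_train:n_train + n_val],
            shuffled[n_train + n_val:])
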