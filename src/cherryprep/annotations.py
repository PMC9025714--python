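"""Annotation containers and format conversion: labelimg VOC XML and YOLO txt.

Two coordinate currencies coexist in detection tooling:

* Pascal VOC XML as written by the labelimg tool: 1-based *inclusive* pixel
  coordinates (``xmin=1, xmax=W`` spans the full width).
* YOLO label files: one ``class cx cy w h`` line per object, all four
  geometry fields normalized by image width/height, center + extent.

Internally every box is 0-based half-open, ``[x0, x1) x [y0, y1)`` in pixels,
so widths are simply ``x1 - x0`` and conversions are exact arithmetic:
``x0 = xmin - 1, x1 = xmax``.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "BoundingBox",
    "YoloLabel",
    "GradeMap",
    "DEFAULT_GRADES",
    "parse_voc",
    "write_voc",
    "to_yolo",
    "from_yolo",
    "read_yolo_file",
    "write_yolo_file",
    "write_dataset_yaml",
]

logger = logging.getLogger(__name__)

#: Default names for the four quality grades.
DEFAULT_GRADES = ("grade_1", "grade_2", "grade_3", "grade_4")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based half-open pixel coordinates, with its grade."""

    grade: str
    x0: float
    x1: float
    y0: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(
                f"degenerate box: x [{self.x0},{self.x1}) y [{self.y0},{self.y1})"
            )

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class YoloLabel:
    """One YOLO label line: class index + normalized center/extent."""

    class_index: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.class_index < 0:
            raise ValueError(f"class_index must be >= 0, got {self.class_index}")
        if not (0 < self.w <= 1 and 0 < self.h <= 1):
            raise ValueError(f"normalized extent out of (0,1]: w={self.w} h={self.h}")


class GradeMap:
    """Bijective mapping between grade names and YOLO class indices."""

    def __init__(self, names=DEFAULT_GRADES):
        names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate grade names: {names}")
        self.names = names
        self._index = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.names)

    def index(self, grade: str) -> int:
        try:
            return self._index[grade]
        except KeyError:
            raise KeyError(f"grade {grade!r} not in grade map {self.names}") from None

    def name(self, class_index: int) -> str:
        if not 0 <= class_index < len(self.names):
            raise KeyError(
                f"class index {class_index} outside grade map of size {len(self.names)}"
            )
        return self.names[class_index]


# ---------------------------------------------------------------------------
# Pascal VOC (labelimg dialect)


def parse_voc(source) -> tuple[str, int, int, list[BoundingBox]]:
    """Parse a labelimg-style VOC XML document.

    ``source`` is a path or file-like object.  Returns
    ``(image filename, width, height, boxes)`` with boxes converted from
    VOC's 1-based inclusive pixels to 0-based half-open.  Boxes overflowing
    the image are clipped with a warning; an inverted extent is an error.
    """
    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise ValueError("VOC XML missing <size> with <width>/<height>")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    filename = root.findtext("filename", default="")

    boxes = []
    for obj in root.iter("object"):
        grade = obj.findtext("name")
        bb = obj.find("bndbox")
        if grade is None or bb is None:
            raise ValueError("VOC <object> missing <name> or <bndbox>")
        xmin = float(bb.findtext("xmin"))
        ymin = float(bb.findtext("ymin"))
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        if xmin >= xmax or ymin >= ymax:
            raise ValueError(
                f"invalid VOC box: xmin={xmin} xmax={xmax} ymin={ymin} ymax={ymax}"
            )
        x0, x1, y0, y1 = xmin - 1, xmax, ymin - 1, ymax
        cx0, cx1 = max(x0, 0), min(x1, width)
        cy0, cy1 = max(y0, 0), min(y1, height)
        if (cx0, cx1, cy0, cy1) != (x0, x1, y0, y1):
            logger.warning(
                "box %s overflows %dx%d image; clipped", (x0, x1, y0, y1), width, height
            )
        boxes.append(BoundingBox(grade=grade, x0=cx0, x1=cx1, y0=cy0, y1=cy1))
    return filename, width, height, boxes


def write_voc(
    filename: str,
    width: int,
    height: int,
    boxes,
    path=None,
) -> str:
    """Serialize an annotation to labelimg-compatible VOC XML.

    Inverse of :func:`parse_voc`: half-open ``[x0, x1)`` becomes
    ``xmin = x0 + 1, xmax = x1``.  Returns the XML string; also writes it to
    ``path`` when given.  Grade names are written verbatim (the grade map
    applies only at YOLO conversion).
    """
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(int(width))
    ET.SubElement(size, "height").text = str(int(height))
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"
    for b in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.grade
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(int(round(b.x0 + 1)))
        ET.SubElement(bb, "ymin").text = str(int(round(b.y0 + 1)))
        ET.SubElement(bb, "xmax").text = str(int(round(b.x1)))
        ET.SubElement(bb, "ymax").text = str(int(round(b.y1)))
    ET.indent(root)
    xml = ET.tostring(root, encoding="unicode")
    if path is not None:
        Path(path).write_text(xml + "\n")
    return xml


# ---------------------------------------------------------------------------
# YOLO


def to_yolo(box: BoundingBox, width: int, height: int, grades: GradeMap) -> YoloLabel:
    """Convert a pixel box to a normalized YOLO label."""
    return YoloLabel(
        class_index=grades.index(box.grade),
        cx=(box.x0 + box.x1) / (2 * width),
        cy=(box.y0 + box.y1) / (2 * height),
        w=(box.x1 - box.x0) / width,
        h=(box.y1 - box.y0) / height,
    )


def from_yolo(label: YoloLabel, width: int, height: int, grades: GradeMap) -> BoundingBox:
    """Convert a YOLO label back to a pixel box, clipped to image bounds."""
    grade = grades.name(label.class_index)
    x0 = (label.cx - label.w / 2) * width
    x1 = (label.cx + label.w / 2) * width
    y0 = (label.cy - label.h / 2) * height
    y1 = (label.cy + label.h / 2) * height
    return BoundingBox(
        grade=grade,
        x0=max(x0, 0.0),
        x1=min(x1, float(width)),
        y0=max(y0, 0.0),
        y1=min(y1, float(height)),
    )


def write_yolo_file(labels, path) -> None:
    """Write YOLO labels, 6-decimal floats, one line per object.

    A zero-object annotation is an empty file (the YOLO convention).
    """
    lines = [
        f"{l.class_index} {l.cx:.6f} {l.cy:.6f} {l.w:.6f} {l.h:.6f}" for l in labels
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_file(path) -> list[YoloLabel]:
    labels = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        labels.append(
            YoloLabel(
                class_index=int(fields[0]),
                cx=float(fields[1]),
                cy=float(fields[2]),
                w=float(fields[3]),
                h=float(fields[4]),
            )
        )
    return labels


def write_dataset_yaml(path, root: str, grades: GradeMap) -> None:
    """Write a YOLOv5-style dataset descriptor YAML."""
    import yaml

    doc = {
        "path": str(root),
        "train": "images/train",
        "val": "images/test",
        "nc": len(grades),
        "names": list(grades.names),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
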