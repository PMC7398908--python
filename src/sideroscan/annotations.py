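"""Core domain types and annotation file I/O.

Single graded cells (:class:`CellAnnotation`) live on slides
(:class:`SlideRecord`); per-grade tallies (:class:`GradeCounts`) are the unit
all hemosiderin scoring operates on.  Annotations are stored box-center +
size in 0-based pixel coordinates (origin top-left, x rightward, y downward,
half-open intervals) and can be exchanged as the package's own JSON schema,
as flat CSV, or as a COCO-style export for interoperability with object
detection tooling.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

GRADES = (0, 1, 2, 3, 4)
STAININGS = ("prussian", "turnbull")

JSON_SCHEMA_VERSION = "sideroscan-annotations/1"

#: COCO category ids are 1-based; grade g maps to category id g + 1.
COCO_CATEGORIES = [
    {"id": g + 1, "name": f"grade_{g}", "supercategory": "hemosiderophage"}
    for g in GRADES
]


class ValidationError(ValueError):
    """An annotation or slide record violates a schema invariant."""


class SchemaError(ValueError):
    """A file does not parse under the declared annotation schema."""


@dataclass(frozen=True)
class CellAnnotation:
    """One graded hemosiderophage: box center, size and Golde grade 0-4."""

    slide_id: str
    cx: float
    cy: float
    w: float
    h: float
    grade: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(
                f"cell on slide {self.slide_id!r} at ({self.cx}, {self.cy}) "
                f"has non-positive box size {self.w} x {self.h}"
            )
        if self.grade not in GRADES:
            raise ValidationError(
                f"cell on slide {self.slide_id!r} at ({self.cx}, {self.cy}) "
                f"has grade {self.grade!r} outside 0..4"
            )

    @property
    def box_xywh(self) -> tuple[float, float, float, float]:
        """Corner-form box ``(x_min, y_min, w, h)`` as used by COCO."""
        return (self.cx - self.w / 2, self.cy - self.h / 2, self.w, self.h)

    @classmethod
    def from_xywh(
        cls, slide_id: str, x: float, y: float, w: float, h: float, grade: int
    ) -> "CellAnnotation":
        return cls(slide_id, x + w / 2, y + h / 2, w, h, grade)


@dataclass
class SlideRecord:
    """A slide with its pixel geometry, staining and cell annotations.

    ``width``/``height`` may be ``None`` when the source format does not
    carry slide geometry (flat CSV); bounds checks then do not apply.
    """

    slide_id: str
    width: int | None = None
    height: int | None = None
    staining: str = "prussian"
    mpp: float = 0.25
    annotations: list[CellAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.staining not in STAININGS:
            raise ValidationError(
                f"slide {self.slide_id!r}: unknown staining {self.staining!r}"
            )
        if self.mpp <= 0:
            raise ValidationError(f"slide {self.slide_id!r}: mpp must be > 0")
        for cell in self.annotations:
            self._check_cell(cell)

    def _check_cell(self, cell: CellAnnotation) -> None:
        if cell.slide_id != self.slide_id:
            raise ValidationError(
                f"cell carries slide_id {cell.slide_id!r} but belongs to "
                f"slide {self.slide_id!r}"
            )
        if self.width is not None and not (0 <= cell.cx < self.width):
            raise ValidationError(
                f"slide {self.slide_id!r}: cell center x={cell.cx} outside "
                f"[0, {self.width})"
            )
        if self.height is not None and not (0 <= cell.cy < self.height):
            raise ValidationError(
                f"slide {self.slide_id!r}: cell center y={cell.cy} outside "
                f"[0, {self.height})"
            )

    def add(self, cell: CellAnnotation) -> None:
        self._check_cell(cell)
        self.annotations.append(cell)


@dataclass(frozen=True)
class GradeCounts:
    """Per-grade cell tallies — the unit of all hemosiderin scoring."""

    n0: int = 0
    n1: int = 0
    n2: int = 0
    n3: int = 0
    n4: int = 0

    def __post_init__(self) -> None:
        for g, n in enumerate(self.as_tuple()):
            if n < 0 or int(n) != n:
                raise ValidationError(f"count for grade {g} must be a non-negative integer")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.n0, self.n1, self.n2, self.n3, self.n4)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())

    def __add__(self, other: "GradeCounts") -> "GradeCounts":
        return GradeCounts(*(a + b for a, b in zip(self.as_tuple(), other.as_tuple())))


def counts_from_annotations(cells: Iterable[CellAnnotation]) -> GradeCounts:
    """Tally cells by grade into a :class:`GradeCounts`."""
    n = [0, 0, 0, 0, 0]
    for cell in cells:
        n[cell.grade] += 1
    return GradeCounts(*n)


# ---------------------------------------------------------------------------
# I/O


def _record_to_jsonable(record: SlideRecord) -> dict:
    return {
        "slide_id": record.slide_id,
        "width": record.width,
        "height": record.height,
        "staining": record.staining,
        "mpp": record.mpp,
        "cells": [
            {"cx": c.cx, "cy": c.cy, "w": c.w, "h": c.h, "grade": c.grade}
            for c in record.annotations
        ],
    }


def _record_from_jsonable(obj: dict, index: int) -> SlideRecord:
    try:
        slide_id = obj["slide_id"]
        cells = obj["cells"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"slide record #{index}: missing field {exc}") from None
    record = SlideRecord(
        slide_id=slide_id,
        width=obj.get("width"),
        height=obj.get("height"),
        staining=obj.get("staining", "prussian"),
        mpp=obj.get("mpp", 0.25),
    )
    for j, c in enumerate(cells):
        try:
            cell = CellAnnotation(
                slide_id, c["cx"], c["cy"], c["w"], c["h"], c["grade"]
            )
        except KeyError as exc:
            raise SchemaError(
                f"slide {slide_id!r} cell #{j}: missing field {exc}"
            ) from None
        record.add(cell)
    return record


def _write_json(records: Sequence[SlideRecord]) -> str:
    doc = {
        "schema": JSON_SCHEMA_VERSION,
        "slides": [_record_to_jsonable(r) for r in records],
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def _read_json(text: str) -> list[SlideRecord]:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from None
    if not isinstance(doc, dict) or doc.get("schema") != JSON_SCHEMA_VERSION:
        raise SchemaError(
            f"missing or unknown schema marker (expected {JSON_SCHEMA_VERSION!r})"
        )
    return [_record_from_jsonable(o, i) for i, o in enumerate(doc.get("slides", []))]


CSV_HEADER = ["slide_id", "cx", "cy", "w", "h", "grade"]


def _write_csv(records: Sequence[SlideRecord]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for record in records:
        for c in record.annotations:
            writer.writerow([record.slide_id, repr(c.cx), repr(c.cy), repr(c.w), repr(c.h), c.grade])
    return buf.getvalue()


def _read_csv(text: str) -> list[SlideRecord]:
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError("empty CSV file") from None
    if header != CSV_HEADER:
        raise SchemaError(f"CSV header {header!r} != {CSV_HEADER!r}")
    records: dict[str, SlideRecord] = {}
    for i, row in enumerate(reader):
        if not row:
            continue
        if len(row) != 6:
            raise SchemaError(f"CSV row #{i + 1}: expected 6 fields, got {len(row)}")
        slide_id = row[0]
        try:
            cx, cy, w, h = (float(v) for v in row[1:5])
            grade = int(row[5])
        except ValueError as exc:
            raise SchemaError(f"CSV row #{i + 1}: {exc}") from None
        record = records.setdefault(slide_id, SlideRecord(slide_id=slide_id))
        record.add(CellAnnotation(slide_id, cx, cy, w, h, grade))
    return list(records.values())


def _write_coco(records: Sequence[SlideRecord]) -> str:
    images, anns = [], []
    ann_id = 1
    for img_id, record in enumerate(records, start=1):
        images.append(
            {
                "id": img_id,
                "file_name": f"{record.slide_id}.png",
                "width": record.width,
                "height": record.height,
            }
        )
        for c in record.annotations:
            x, y, w, h = c.box_xywh
            anns.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": c.grade + 1,
                    "bbox": [x, y, w, h],
                    "area": w * h,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {"images": images, "annotations": anns, "categories": COCO_CATEGORIES}
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def _read_coco(text: str) -> list[SlideRecord]:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from None
    if not isinstance(doc, dict) or "images" not in doc or "annotations" not in doc:
        raise SchemaError("not a COCO annotation document")
    cat_to_grade = {}
    for cat in doc.get("categories", COCO_CATEGORIES):
        name = cat.get("name", "")
        if name.startswith("grade_"):
            cat_to_grade[cat["id"]] = int(name.split("_", 1)[1])
        else:
            cat_to_grade[cat["id"]] = cat["id"] - 1
    records: dict[int, SlideRecord] = {}
    for img in doc["images"]:
        slide_id = str(img.get("file_name", img["id"]))
        if slide_id.endswith(".png"):
            slide_id = slide_id[: -len(".png")]
        records[img["id"]] = SlideRecord(
            slide_id=slide_id, width=img.get("width"), height=img.get("height")
        )
    for i, ann in enumerate(doc["annotations"]):
        try:
            record = records[ann["image_id"]]
            grade = cat_to_grade[ann["category_id"]]
            x, y, w, h = ann["bbox"]
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"COCO annotation #{i}: {exc}") from None
        record.add(CellAnnotation.from_xywh(record.slide_id, x, y, w, h, grade))
    return list(records.values())


_WRITERS = {"json": _write_json, "csv": _write_csv, "coco": _write_coco}
_READERS = {"json": _read_json, "csv": _read_csv, "coco": _read_coco}


def write_annotations(records: Sequence[SlideRecord], path, format: str = "json") -> None:
    """Serialize slide records to ``path`` (``json``, ``csv`` or ``coco``).

    Field ordering is deterministic, so writing the same records twice
    produces byte-identical files.
    """
    try:
        writer = _WRITERS[format]
    except KeyError:
        raise ValueError(f"unknown annotation format {format!r}") from None
    text = writer(records)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(text)


def read_annotations(path, format: str = "json") -> list[SlideRecord]:
    """Parse an annotation file into validated :class:`SlideRecord` objects."""
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown annotation format {format!r}") from None
    with open(path, "r", encoding="utf-8") as fh:
        return reader(fh.read())
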