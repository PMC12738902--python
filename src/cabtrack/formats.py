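"""Domain vocabulary, box geometry and readers/writers for the pipeline's file formats.

The external formats are deliberately minimal plain text:

* DarkLabel annotation CSV — headerless rows ``frame,cname,id,x1,y1,x2,y2``,
  the ground-truth trajectory format produced by the DarkLabel video
  annotation tool.
* detections CSV — header ``frame,cname,conf,x1,y1,x2,y2``, the per-frame
  output of any object detector (the tracker's input contract).
* count report JSON — ``{"counts": {state: int}, "total": int,
  "rates": {state: float}}``.

Coordinates are continuous pixels, origin at the top-left corner, y growing
downward; sub-pixel values are preserved on round-trip.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


class TransplantState(enum.Enum):
    """Transplanting status of a single seedling.

    ``NORMAL``: planted at proper depth, root zone covered, leaves exposed.
    ``BURIED_SEEDLING``: planted too deep, leaves partly or fully soil-covered.
    ``BARE_ROOT``: planted too shallow, root substrate exposed to air.
    """

    NORMAL = "normal"
    BURIED_SEEDLING = "buried_seedling"
    BARE_ROOT = "bare_root"

    def __str__(self) -> str:  # canonical lower-snake label
        return self.value

    @classmethod
    def parse(cls, label: str) -> "TransplantState":
        """Map a class-name string to a state, case-insensitively.

        Accepts a few common spelling variants seen in annotation exports
        (``buried``, ``bareroot`` ...); anything else raises ``ValueError``.
        """
        key = label.strip().lower().replace("-", "_").replace(" ", "_")
        aliases = {
            "normal": cls.NORMAL,
            "buried_seedling": cls.BURIED_SEEDLING,
            "buried": cls.BURIED_SEEDLING,
            "barried_seedling": cls.BURIED_SEEDLING,
            "bare_root": cls.BARE_ROOT,
            "bareroot": cls.BARE_ROOT,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(
                f"unknown transplant state {label!r}; expected one of "
                f"{[s.value for s in cls]}"
            ) from None


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box given by top-left (x1, y1) and bottom-right (x2, y2)."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(
                f"degenerate box ({self.x1}, {self.y1}, {self.x2}, {self.y2}): "
                "need x1 < x2 and y1 < y2"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def center(self) -> tuple[float, float]:
        return (self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0

    @property
    def area(self) -> float:
        return self.width * self.height

    def to_xyah(self) -> tuple[float, float, float, float]:
        """Center-x, center-y, aspect ratio (w/h), height — the Kalman measurement."""
        cx, cy = self.center
        return cx, cy, self.width / self.height, self.height

    @classmethod
    def from_xyah(cls, cx: float, cy: float, a: float, h: float) -> "BoundingBox":
        w = a * h
        return cls(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


@dataclass(frozen=True)
class Detection:
    """One classified detector output in one frame — the tracker's input unit."""

    frame: int
    state: TransplantState
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"negative frame index {self.frame}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class AnnotationRecord:
    """One DarkLabel ground-truth row: an identified box in one frame."""

    frame: int
    state: TransplantState
    id: int
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"negative frame index {self.frame}")
        if self.id < 0:
            raise ValueError(f"negative track id {self.id}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]; 0 for disjoint boxes."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _fmt(v: float) -> str:
    # integers print without a trailing .0 so integer-annotated files round-trip
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


class ParseError(ValueError):
    """Raised for rows that violate a file's grammar; names the offending line."""


def read_darklabel_csv(path: str | Path) -> list[AnnotationRecord]:
    """Read DarkLabel annotations: headerless ``frame,cname,id,x1,y1,x2,y2`` rows."""
    records: list[AnnotationRecord] = []
    seen: set[tuple[int, int]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 comma-separated fields, got {len(parts)}"
                )
            try:
                frame = int(parts[0])
                state = TransplantState.parse(parts[1])
                obj_id = int(parts[2])
                coords = [float(p) for p in parts[3:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if (frame, obj_id) in seen:
                raise ParseError(f"{path}:{lineno}: duplicate (frame={frame}, id={obj_id})")
            seen.add((frame, obj_id))
            records.append(AnnotationRecord(frame, state, obj_id, BoundingBox(*coords)))
    return records


def write_darklabel_csv(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    """Write DarkLabel annotation rows; output re-parses to an equal sequence."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            b = r.box
            fh.write(
                f"{r.frame},{r.state},{r.id},"
                f"{_fmt(b.x1)},{_fmt(b.y1)},{_fmt(b.x2)},{_fmt(b.y2)}\n"
            )


_DET_HEADER = "frame,cname,conf,x1,y1,x2,y2"


def read_detections(path: str | Path) -> dict[int, list[Detection]]:
    """Read a detections CSV, returning detections grouped by ascending frame."""
    grouped: dict[int, list[Detection]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != _DET_HEADER:
            raise ParseError(f"{path}:1: expected header {_DET_HEADER!r}, got {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 comma-separated fields, got {len(parts)}"
                )
            try:
                frame = int(parts[0])
                state = TransplantState.parse(parts[1])
                conf = float(parts[2])
                coords = [float(p) for p in parts[3:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            det = Detection(frame, state, BoundingBox(*coords), conf)
            grouped.setdefault(frame, []).append(det)
    return dict(sorted(grouped.items()))


def write_detections(detections: Iterable[Detection], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_DET_HEADER + "\n")
        for d in detections:
            b = d.box
            fh.write(
                f"{d.frame},{d.state},{_fmt(d.confidence)},"
                f"{_fmt(b.x1)},{_fmt(b.y1)},{_fmt(b.x2)},{_fmt(b.y2)}\n"
            )


def write_count_report(report, path: str | Path) -> None:
    """Serialize a counting.CountReport to the JSON schema above."""
    payload = {
        "counts": {str(s): int(c) for s, c in report.counts.items()},
        "total": int(report.total),
        "rates": (
            {str(s): float(r) for s, r in report.rates.items()}
            if report.rates is not None
            else None
        ),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_count_report(path: str | Path):
    from .counting import CountReport  # local import to avoid a cycle

    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    counts = {TransplantState.parse(k): int(v) for k, v in payload["counts"].items()}
    return CountReport(counts=counts)


def track_rows_to_records(
    rows: Sequence[tuple[int, int, TransplantState, BoundingBox]],
) -> list[AnnotationRecord]:
    """Convert tracker output rows (frame, id, state, box) to annotation records.

    The result is DarkLabel-compatible, so tracker output can be written with
    :func:`write_darklabel_csv` and evaluated against ground-truth annotations.
    """
    return [AnnotationRecord(frame, state, tid, box) for frame, tid, state, box in rows]
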