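"""Annotation data model and file I/O.

The measurement pipeline consumes *annotations*: manually traced bone
contours and manually marked points from an AP pelvis radiograph. Per hip
these are

* an acetabular arc — an open polyline from the lateral (outer upper)
  acetabular margin to the floor of the acetabular fossa,
* a femoral arc — an open polyline running from the femoral head onto the
  neck,
* the medial edge of the sourcil (acetabular weight-bearing area), marked
  by the reader,
* the inferior edge of the radiographic teardrop.

Coordinates are pixels in image convention: origin top-left, y increases
inferiorly. Angles are scale-invariant, so no mm conversion is applied;
``pixel_spacing`` is carried for display only.

Annotation container format (JSON, one file per radiograph)::

    {
      "image_id": "case-001",
      "pixel_spacing": 0.143,            # optional, mm/pixel
      "hips": [
        {
          "side": "right",
          "acetabular_arc": [[x, y], ...],
          "femoral_arc": [[x, y], ...],
          "sourcil_medial": [x, y],
          "teardrop_inferior": [x, y]
        },
        { "side": "left", ... }
      ]
    }

Measurement output is CSV with columns
``image_id, side, tonnis_deg, sharp_deg, ce_deg, head_cx, head_cy, head_r``
(plus one ``label_<rule>`` column per classification rule present); angles
are reported to three decimals.
"""

from __future__ import annotations

import json
import math
import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

Side = Literal["left", "right"]
Role = Literal["acetabular_arc", "femoral_arc"]

SIDES = ("left", "right")
ROLES = ("acetabular_arc", "femoral_arc")

#: Margin (pixels) by which the acetabular-arc bounding box is expanded when
#: checking that the marked sourcil medial point is plausibly located.
SOURCIL_BBOX_MARGIN = 10.0

MEASUREMENT_COLUMNS = (
    "image_id", "side", "tonnis_deg", "sharp_deg", "ce_deg",
    "head_cx", "head_cy", "head_r",
)


@dataclass(frozen=True)
class Point2D:
    """A point in pixel coordinates (image convention, y down)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise SchemaError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    @classmethod
    def of(cls, p: "Point2D | Sequence[float] | np.ndarray") -> "Point2D":
        if isinstance(p, Point2D):
            return p
        seq = np.asarray(p, dtype=float).ravel()
        if seq.size != 2:
            raise SchemaError(f"a point needs exactly 2 coordinates, got {seq.size}")
        return cls(float(seq[0]), float(seq[1]))


def _check_side(side: str) -> str:
    if side not in SIDES:
        raise SchemaError(f"unknown side token {side!r}; expected one of {SIDES}")
    return side


class ContourTrace:
    """An ordered open polyline tracing one bony arc.

    Parameters
    ----------
    points
        Sequence of (x, y) pixel coordinates; at least 3 vertices, no two
        consecutive vertices identical, first and last vertex distinct
        (open polyline).
    role
        ``"acetabular_arc"`` or ``"femoral_arc"``.
    side
        Anatomical side, ``"left"`` or ``"right"``.
    """

    __slots__ = ("points", "role", "side")

    def __init__(self, points: Sequence | np.ndarray, role: str, side: str):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise SchemaError(f"contour points must be an (n, 2) array, got shape {pts.shape}")
        if pts.shape[0] < 3:
            raise SchemaError(f"a contour needs >= 3 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise SchemaError("contour contains non-finite coordinates")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise SchemaError("contour has two identical consecutive points")
        if np.linalg.norm(pts[0] - pts[-1]) < 1e-9:
            raise SchemaError("contour must be an open polyline (first == last point)")
        if role not in ROLES:
            raise SchemaError(f"unknown contour role {role!r}; expected one of {ROLES}")
        self.points = pts
        self.points.setflags(write=False)
        self.role = role
        self.side = _check_side(side)

    def __len__(self) -> int:
        return self.points.shape[0]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContourTrace)
            and self.role == other.role
            and self.side == other.side
            and self.points.shape == other.points.shape
            and np.array_equal(self.points, other.points)
        )

    def __repr__(self) -> str:
        return f"ContourTrace({len(self)} pts, role={self.role!r}, side={self.side!r})"


@dataclass(frozen=True)
class HipAnnotation:
    """All traced/marked input for one hip."""

    side: str
    acetabular_arc: ContourTrace
    femoral_arc: ContourTrace
    sourcil_medial: Point2D
    teardrop_inferior: Point2D

    def __post_init__(self) -> None:
        _check_side(self.side)
        if self.acetabular_arc.role != "acetabular_arc":
            raise SchemaError("acetabular_arc trace has wrong role")
        if self.femoral_arc.role != "femoral_arc":
            raise SchemaError("femoral_arc trace has wrong role")
        for trace in (self.acetabular_arc, self.femoral_arc):
            if trace.side != self.side:
                raise SchemaError(
                    f"trace side {trace.side!r} does not match hip side {self.side!r}"
                )
        lo = self.acetabular_arc.points.min(axis=0) - SOURCIL_BBOX_MARGIN
        hi = self.acetabular_arc.points.max(axis=0) + SOURCIL_BBOX_MARGIN
        m = self.sourcil_medial.as_array()
        if not (np.all(m >= lo) and np.all(m <= hi)):
            raise SchemaError(
                "sourcil_medial lies outside the acetabular arc bounding box "
                f"(expanded by {SOURCIL_BBOX_MARGIN} px)"
            )


@dataclass(frozen=True)
class PelvisAnnotation:
    """One annotated radiograph: exactly one hip per side."""

    image_id: str
    left: HipAnnotation
    right: HipAnnotation
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        if not self.image_id:
            raise SchemaError("image_id must be a non-empty string")
        if self.left.side != "left" or self.right.side != "right":
            raise SchemaError("hips assigned to the wrong side slots")
        if (
            self.left.teardrop_inferior.x == self.right.teardrop_inferior.x
            and self.left.teardrop_inferior.y == self.right.teardrop_inferior.y
        ):
            raise SchemaError("the two teardrop_inferior points must be distinct")
        if self.pixel_spacing is not None and not (
            math.isfinite(self.pixel_spacing) and self.pixel_spacing > 0
        ):
            raise SchemaError("pixel_spacing must be a positive number")

    def hips(self) -> tuple[HipAnnotation, HipAnnotation]:
        return (self.left, self.right)


@dataclass(frozen=True)
class MeasurementRecord:
    """Angles and head geometry measured for one hip."""

    image_id: str
    side: str
    tonnis_deg: float
    sharp_deg: float
    ce_deg: float
    head_center: Point2D
    head_radius: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_side(self.side)
        for name in ("tonnis_deg", "sharp_deg", "ce_deg"):
            if not math.isfinite(getattr(self, name)):
                raise SchemaError(f"{name} must be finite")
        if not (math.isfinite(self.head_radius) and self.head_radius > 0):
            raise SchemaError("head_radius must be positive and finite")


# ---------------------------------------------------------------------------
# JSON annotation I/O
# ---------------------------------------------------------------------------

def _require(mapping: dict, key: str, ctx: str):
    if key not in mapping:
        raise SchemaError(f"missing required field {key!r} in {ctx}")
    return mapping[key]


def _hip_from_dict(d: dict) -> HipAnnotation:
    side = _check_side(_require(d, "side", "hip"))
    ctx = f"{side} hip"
    return HipAnnotation(
        side=side,
        acetabular_arc=ContourTrace(_require(d, "acetabular_arc", ctx), "acetabular_arc", side),
        femoral_arc=ContourTrace(_require(d, "femoral_arc", ctx), "femoral_arc", side),
        sourcil_medial=Point2D.of(_require(d, "sourcil_medial", ctx)),
        teardrop_inferior=Point2D.of(_require(d, "teardrop_inferior", ctx)),
    )


def read_annotation(path: str | Path) -> PelvisAnnotation:
    """Read one annotation JSON file.

    Raises
    ------
    SchemaError
        If a required field is missing or a token/invariant is invalid; the
        message names the offending field.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    image_id = _require(doc, "image_id", "annotation")
    hips = _require(doc, "hips", "annotation")
    if not isinstance(hips, list) or len(hips) != 2:
        raise SchemaError("annotation must contain exactly 2 hips")
    by_side: dict[str, HipAnnotation] = {}
    for entry in hips:
        hip = _hip_from_dict(entry)
        if hip.side in by_side:
            raise SchemaError(f"duplicate hip side {hip.side!r}")
        by_side[hip.side] = hip
    for side in SIDES:
        if side not in by_side:
            raise SchemaError(f"annotation is missing the {side} hip")
    return PelvisAnnotation(
        image_id=image_id,
        left=by_side["left"],
        right=by_side["right"],
        pixel_spacing=doc.get("pixel_spacing"),
    )


def _hip_to_dict(hip: HipAnnotation) -> dict:
    return {
        "side": hip.side,
        "acetabular_arc": hip.acetabular_arc.points.tolist(),
        "femoral_arc": hip.femoral_arc.points.tolist(),
        "sourcil_medial": [hip.sourcil_medial.x, hip.sourcil_medial.y],
        "teardrop_inferior": [hip.teardrop_inferior.x, hip.teardrop_inferior.y],
    }


def write_annotation(ann: PelvisAnnotation, path: str | Path) -> None:
    """Write an annotation to JSON, losslessly (floats at full repr precision)."""
    doc: dict = {"image_id": ann.image_id}
    if ann.pixel_spacing is not None:
        doc["pixel_spacing"] = ann.pixel_spacing
    doc["hips"] = [_hip_to_dict(ann.right), _hip_to_dict(ann.left)]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Measurement CSV I/O
# ---------------------------------------------------------------------------

def write_measurements(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    """Write measurement records to CSV, one row per hip.

    Angles are written to three decimals; head geometry to six. Label
    columns (``label_<rule>``) are appended for every rule present on any
    record.
    """
    records = list(records)
    if not records:
        raise SchemaError("no measurement records to write")
    label_keys = sorted({k for r in records for k in r.labels})
    header = list(MEASUREMENT_COLUMNS) + [f"label_{k}" for k in label_keys]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            row = [
                r.image_id, r.side,
                f"{r.tonnis_deg:.3f}", f"{r.sharp_deg:.3f}", f"{r.ce_deg:.3f}",
                f"{r.head_center.x:.6f}", f"{r.head_center.y:.6f}", f"{r.head_radius:.6f}",
            ]
            row += [r.labels.get(k, "") for k in label_keys]
            writer.writerow(row)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV back as a DataFrame (numeric angle columns)."""
    df = pd.read_csv(path, dtype={"image_id": str, "side": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement CSV is missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Optional DICOM support (display only)
# ---------------------------------------------------------------------------

def read_dicom_image(path: str | Path):
    """Load a DICOM radiograph for overlay display.

    Returns ``(pixel_array, pixel_spacing_mm)`` where spacing may be None.
    Requires the optional ``pydicom`` dependency; no measurement ever
    depends on pixel data.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "reading DICOM files requires the optional 'pydicom' dependency"
        ) from exc
    ds = pydicom.dcmread(str(path))
    spacing = getattr(ds, "PixelSpacing", None)
    return ds.pixel_array, (float(spacing[0]) if spacing else None)
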