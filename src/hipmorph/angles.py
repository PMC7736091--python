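"""Hip development indices: Tönnis, Sharp and center-edge (CE) angles.

All three are measured relative to the pelvic frame (line *a* through the
teardrop inferior points), which makes them invariant to in-plane image
rotation and uniform scaling:

* **Tönnis angle** — inclination of the sourcil (acetabular weight-bearing
  area) against line *a*: the angle of the medial-to-lateral sourcil chord
  above the pelvic horizontal. Signed: positive when the lateral edge is
  superior (upsloping sourcil), negative when inferior.
* **Sharp angle** — the acute angle between line *a* and the line from the
  teardrop inferior point to the lateral acetabular margin.
* **CE angle (Wiberg)** — at the femoral head center, between the pelvic
  vertical (perpendicular to line *a* by default) and the line to the
  lateral acetabular margin. Signed: positive when the margin lies lateral
  to the vertical, negative when medial (deficient coverage).

The paper-style dysplasia reading: Tönnis > 10°, Sharp > 45°, CE < 20°
(20–25° borderline); see :mod:`hipmorph.classification`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .annotation_io import MeasurementRecord, PelvisAnnotation
from .errors import DegenerateGeometryError, HipmorphError
from .geometry import ZERO_VECTOR_EPS, PelvisFrame, build_frame, vertex_angle
from .landmarks import LandmarkSet, extract_landmarks

logger = logging.getLogger(__name__)

Vertical = Literal["pelvic", "image"]

#: Decimals used when formatting angles for reports/CSV.
ANGLE_DECIMALS = 3


@dataclass(frozen=True)
class AngleTriple:
    """The three indices for one hip."""

    tonnis_deg: float
    sharp_deg: float
    ce_deg: float
    side: str
    source: str = "cad"

    def __post_init__(self) -> None:
        if not 0.0 < self.sharp_deg < 90.0:
            raise DegenerateGeometryError(
                f"sharp_deg {self.sharp_deg} outside (0, 90)"
            )
        for name in ("tonnis_deg", "ce_deg"):
            v = getattr(self, name)
            if not -90.0 < v < 90.0:
                raise DegenerateGeometryError(f"{name} {v} outside (-90, 90)")


def _signed_from_components(superior_comp: float, lateral_comp: float) -> float:
    return math.degrees(math.atan2(superior_comp, lateral_comp))


def tonnis_angle(lm: LandmarkSet, frame: PelvisFrame) -> float:
    """Signed sourcil inclination in degrees."""
    w = lm.sourcil_lateral.as_array() - lm.sourcil_medial.as_array()
    if np.linalg.norm(w) < ZERO_VECTOR_EPS:
        raise DegenerateGeometryError("sourcil medial and lateral points coincide")
    sup = float(w @ frame.superior_unit)
    lat = float(w @ frame.lateral_unit(lm.side))
    return _signed_from_components(sup, lat)


def sharp_angle(lm: LandmarkSet, frame: PelvisFrame) -> float:
    """Acute acetabular inclination (teardrop to lateral margin vs line a)."""
    d = lm.acetabular_lateral_margin.as_array() - lm.teardrop_inferior.as_array()
    angle = vertex_angle(d, frame.axis_unit)
    return min(angle, 180.0 - angle)


def ce_angle(
    lm: LandmarkSet, frame: PelvisFrame, *, vertical: Vertical = "pelvic"
) -> float:
    """Signed center-edge angle of Wiberg in degrees.

    ``vertical="pelvic"`` (default) measures against the perpendicular to
    line *a*; ``vertical="image"`` uses the literal image column direction.
    """
    v = lm.acetabular_lateral_margin.as_array() - lm.head_center.as_array()
    if np.linalg.norm(v) < ZERO_VECTOR_EPS:
        raise DegenerateGeometryError("lateral margin coincides with the head center")
    if vertical == "pelvic":
        up = frame.superior_unit
    elif vertical == "image":
        up = np.array([0.0, -1.0])
    else:
        raise ValueError(f"unknown vertical convention {vertical!r}")
    sup = float(v @ up)
    lat = float(v @ lm_lateral(lm, frame, up))
    return _signed_from_components(lat, sup)


def lm_lateral(lm: LandmarkSet, frame: PelvisFrame, up: np.ndarray) -> np.ndarray:
    """Lateral unit for the hip, orthogonal to the chosen vertical."""
    lat = frame.lateral_unit(lm.side)
    # remove any component along the chosen vertical (only relevant for
    # vertical="image" on a tilted pelvis), then renormalize
    lat = lat - (lat @ up) * up
    n = np.linalg.norm(lat)
    if n < ZERO_VECTOR_EPS:
        raise DegenerateGeometryError("degenerate lateral direction")
    return lat / n


def measure_hip(
    lm: LandmarkSet, frame: PelvisFrame, *, vertical: Vertical = "pelvic"
) -> AngleTriple:
    """All three indices for one landmarked hip."""
    return AngleTriple(
        tonnis_deg=tonnis_angle(lm, frame),
        sharp_deg=sharp_angle(lm, frame),
        ce_deg=ce_angle(lm, frame, vertical=vertical),
        side=lm.side,
    )


def measure_pelvis(
    ann: PelvisAnnotation,
    *,
    vertical: Vertical = "pelvic",
    infer_sides: bool = True,
    strict: bool = False,
) -> list[MeasurementRecord]:
    """Measure both hips of one annotated radiograph.

    The pelvic frame is built once from the two teardrop points; each hip
    is then landmarked and measured independently. A failure on one hip is
    logged (or raised when ``strict=True``) and does not abort the other;
    records are returned in (left, right) order for the sides that
    succeeded.
    """
    frame = build_frame(
        ann.left.teardrop_inferior, ann.right.teardrop_inferior,
        infer_sides=infer_sides,
    )
    records: list[MeasurementRecord] = []
    for hip in (ann.left, ann.right):
        try:
            lm = extract_landmarks(hip, frame)
            triple = measure_hip(lm, frame, vertical=vertical)
        except HipmorphError as exc:
            if strict:
                raise
            logger.warning("%s: %s hip failed: %s", ann.image_id, hip.side, exc)
            continue
        records.append(
            MeasurementRecord(
                image_id=ann.image_id,
                side=hip.side,
                tonnis_deg=triple.tonnis_deg,
                sharp_deg=triple.sharp_deg,
                ce_deg=triple.ce_deg,
                head_center=lm.head_center,
                head_radius=lm.head_radius,
            )
        )
    if not records:
        raise DegenerateGeometryError(
            f"{ann.image_id}: measurement failed on both hips"
        )
    return records
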