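"""Automatic landmark extraction from traced hip contours.

The femoral head center is found geometrically: three non-collinear points
covering as much of the head as possible are taken from the traced femoral
arc — its most superior vertex, its most lateral vertex, and the point
where the chord from the lateral vertex to the teardrop inferior point
re-crosses the arc medially — and their circumcircle is the fitted head.
The acetabular lateral margin (outer upper acetabular edge) anchors both
the Sharp and the center-edge measurement; the sourcil medial point is a
manual input carried through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annotation_io import ContourTrace, HipAnnotation, Point2D
from .errors import DegenerateGeometryError, HipmorphError, LandmarkExtractionError
from .geometry import (
    COLLINEARITY_EPS,
    Circle,
    PelvisFrame,
    circumcircle,
    extremal_point,
    segment_polyline_intersections,
)

#: Projection difference (pixels) below which the two acetabular-arc
#: endpoints are considered tied for "most lateral".
ENDPOINT_TIE_EPS = 1.0
#: The head-circle plausibility check warns when the median residual of
#: head-region arc vertices exceeds this fraction of the radius.
HEAD_RESIDUAL_WARN_FRACTION = 0.05


@dataclass(frozen=True)
class LandmarkSet:
    """Derived points feeding the angle computations for one hip."""

    head_center: Point2D
    head_radius: float
    head_pts: tuple[Point2D, Point2D, Point2D]  # (superior, lateral, medial)
    acetabular_lateral_margin: Point2D
    teardrop_inferior: Point2D
    sourcil_medial: Point2D
    sourcil_lateral: Point2D
    side: str

    def __post_init__(self) -> None:
        if self.head_radius <= 0:
            raise DegenerateGeometryError("head_radius must be positive")
        c = self.head_center.as_array()
        for p in self.head_pts:
            if abs(np.linalg.norm(p.as_array() - c) - self.head_radius) > 1e-6:
                raise DegenerateGeometryError(
                    "head point does not lie on the fitted head circle"
                )


def locate_femoral_points(
    femoral_arc: ContourTrace,
    teardrop: Point2D,
    frame: PelvisFrame,
    side: str,
) -> tuple[Point2D, Point2D, Point2D]:
    """The three head points: superior, lateral, and medial.

    Superior and lateral are the arc vertices extremal along the frame's
    superior and lateral directions. The medial point is where the chord
    from the lateral vertex to the teardrop inferior point re-crosses the
    arc; of multiple crossings the one closest to the teardrop is taken.
    """
    superior = extremal_point(femoral_arc, frame.superior_unit)
    lateral = extremal_point(femoral_arc, frame.lateral_unit(side))
    hits = segment_polyline_intersections(lateral, teardrop, femoral_arc)
    if not hits:
        raise LandmarkExtractionError(
            "the lateral-to-teardrop chord does not re-cross the femoral arc"
        )
    medial = hits[-1]  # ordered by distance from the lateral point
    pts = np.array([p.as_array() for p in (superior, lateral, medial)])
    u = pts[1] - pts[0]
    v = pts[2] - pts[0]
    span = max(np.linalg.norm(u), np.linalg.norm(v), np.linalg.norm(pts[2] - pts[1]))
    if span == 0.0 or abs(u[0] * v[1] - u[1] * v[0]) < 2 * COLLINEARITY_EPS * span * span:
        raise DegenerateGeometryError("the three femoral head points are collinear")
    return superior, lateral, medial


def fit_femoral_head(
    superior: Point2D,
    lateral: Point2D,
    medial: Point2D,
    femoral_arc: ContourTrace | None = None,
) -> Circle:
    """Circumcircle of the three head points.

    When the femoral arc is supplied, a plausibility check computes the
    median absolute residual of head-region vertices (those within 1.5
    radii of the fitted center) and warns if it exceeds
    ``HEAD_RESIDUAL_WARN_FRACTION`` of the radius — a sign that the traced
    head is far from circular or the three points were misplaced.
    """
    circle = circumcircle(superior, lateral, medial)
    if femoral_arc is not None:
        c = circle.center.as_array()
        dist = np.linalg.norm(femoral_arc.points - c, axis=1)
        head_region = dist <= 1.5 * circle.radius
        if np.any(head_region):
            med = float(np.median(np.abs(dist[head_region] - circle.radius)))
            if med > HEAD_RESIDUAL_WARN_FRACTION * circle.radius:
                warnings.warn(
                    f"femoral head fit is implausible: median residual {med:.2f} px "
                    f"exceeds {HEAD_RESIDUAL_WARN_FRACTION:.0%} of radius "
                    f"{circle.radius:.2f} px",
                    stacklevel=2,
                )
    return circle


def locate_acetabular_lateral_margin(
    acetabular_arc: ContourTrace, frame: PelvisFrame, side: str
) -> Point2D:
    """The outer upper acetabular margin.

    Of the two arc endpoints, the one projecting further laterally; when
    the endpoints are nearly tied (within ``ENDPOINT_TIE_EPS`` px) the
    whole arc is scanned in the superolateral direction instead.
    """
    lat = frame.lateral_unit(side)
    first = acetabular_arc.points[0]
    last = acetabular_arc.points[-1]
    diff = float((first - last) @ lat)
    if abs(diff) < ENDPOINT_TIE_EPS:
        direction = lat + frame.superior_unit
        return extremal_point(acetabular_arc, direction / np.linalg.norm(direction))
    pick = first if diff > 0 else last
    return Point2D(float(pick[0]), float(pick[1]))


def extract_landmarks(hip: HipAnnotation, frame: PelvisFrame) -> LandmarkSet:
    """Assemble the full landmark set for one annotated hip.

    The teardrop inferior and sourcil medial points come straight from the
    annotation; the sourcil lateral edge is identified with the acetabular
    lateral margin (a single anchor point serves the Tönnis, Sharp and CE
    measurements). Lower-level failures are re-raised with the hip side
    attached.
    """
    try:
        superior, lateral, medial = locate_femoral_points(
            hip.femoral_arc, hip.teardrop_inferior, frame, hip.side
        )
        head = fit_femoral_head(superior, lateral, medial, hip.femoral_arc)
        margin = locate_acetabular_lateral_margin(hip.acetabular_arc, frame, hip.side)
    except HipmorphError as exc:
        raise type(exc)(f"[{hip.side} hip] {exc}") from exc
    return LandmarkSet(
        head_center=head.center,
        head_radius=head.radius,
        head_pts=(superior, lateral, medial),
        acetabular_lateral_margin=margin,
        teardrop_inferior=hip.teardrop_inferior,
        sourcil_medial=hip.sourcil_medial,
        sourcil_lateral=margin,
        side=hip.side,
    )
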