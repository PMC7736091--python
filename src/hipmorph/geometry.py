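"""Pure 2-D geometric primitives for landmark and angle extraction.

Everything here works in pixel image coordinates (y increases inferiorly)
but is written frame-relatively: the pelvic horizontal is the line through
the two teardrop inferior points (line *a*), and "superior"/"lateral" are
defined against that line, not against the image axes. This makes every
downstream measurement invariant to in-plane rotation of the radiograph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation_io import Point2D, ContourTrace
from .errors import DegenerateGeometryError

#: Relative area tolerance below which three points are treated as collinear.
COLLINEARITY_EPS = 1e-9
#: Distance (pixels) within which a segment-polyline intersection is treated
#: as coincident with the segment start and discarded (self-intersection guard).
SELF_INTERSECTION_EPS = 1e-6
#: Norm below which a vector is treated as zero in angle computations.
ZERO_VECTOR_EPS = 1e-12


@dataclass(frozen=True)
class Circle:
    """A circle in pixel coordinates."""

    center: Point2D
    radius: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise DegenerateGeometryError(f"circle radius must be positive, got {self.radius}")


def circumcircle(p1: Point2D, p2: Point2D, p3: Point2D) -> Circle:
    """Unique circle through three non-collinear points.

    Solves the 2x2 perpendicular-bisector system. Raises
    :class:`DegenerateGeometryError` when the points are pairwise
    coincident or collinear (triangle area below
    ``COLLINEARITY_EPS * span**2``, with span the largest pairwise
    distance).
    """
    a1, a2, a3 = (Point2D.of(p).as_array() for p in (p1, p2, p3))
    u = a2 - a1
    v = a3 - a1
    span = max(
        np.linalg.norm(u), np.linalg.norm(v), np.linalg.norm(a3 - a2)
    )
    if span == 0.0:
        raise DegenerateGeometryError("circumcircle of three coincident points")
    cross = u[0] * v[1] - u[1] * v[0]
    area = 0.5 * abs(cross)
    if area < COLLINEARITY_EPS * span * span:
        raise DegenerateGeometryError(
            f"points are collinear within tolerance (area {area:.3e}, span {span:.3e})"
        )
    rhs = 0.5 * np.array([u @ u, v @ v])
    center = a1 + np.linalg.solve(np.array([u, v]), rhs)
    radius = float(np.linalg.norm(center - a1))
    return Circle(Point2D(float(center[0]), float(center[1])), radius)


@dataclass(frozen=True, eq=False)
class PelvisFrame:
    """The pelvic coordinate frame anchored on line *a*.

    ``axis_unit`` points along line *a* from the anatomical-right teardrop
    toward the anatomical-left teardrop (i.e. toward increasing image x on
    a properly oriented AP view, where the patient's right hip appears on
    the image left). ``superior_unit`` is the perpendicular obtained by
    rotating ``axis_unit`` so that it points toward decreasing y on an
    un-rotated image; the construction is rotation-equivariant.
    """

    teardrop_left: Point2D
    teardrop_right: Point2D
    axis_unit: np.ndarray = field(init=False)
    superior_unit: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        tl = self.teardrop_left.as_array()
        tr = self.teardrop_right.as_array()
        d = tl - tr
        n = np.linalg.norm(d)
        if n < ZERO_VECTOR_EPS:
            raise DegenerateGeometryError("coincident teardrop points")
        axis = d / n
        superior = np.array([axis[1], -axis[0]])
        object.__setattr__(self, "axis_unit", axis)
        object.__setattr__(self, "superior_unit", superior)
        self.axis_unit.setflags(write=False)
        self.superior_unit.setflags(write=False)

    def lateral_unit(self, side: str) -> np.ndarray:
        """Unit vector along line *a* pointing away from the pelvic midline."""
        if side == "left":
            return self.axis_unit
        if side == "right":
            return -self.axis_unit
        raise ValueError(f"unknown side {side!r}")

    def teardrop(self, side: str) -> Point2D:
        return self.teardrop_left if side == "left" else self.teardrop_right


def build_frame(
    teardrop_left: Point2D, teardrop_right: Point2D, *, infer_sides: bool = True
) -> PelvisFrame:
    """Build the pelvic frame from the two teardrop inferior points.

    With ``infer_sides=True`` (default) the anatomical sides are inferred
    from image x-order — on an AP radiograph the patient's right hip
    appears on the image left, so the smaller-x teardrop is the right one
    regardless of the argument labels, and the frame is invariant under
    swapping the arguments. Pass ``infer_sides=False`` to trust the labels
    (needed e.g. for heavily rotated inputs).
    """
    tl = Point2D.of(teardrop_left)
    tr = Point2D.of(teardrop_right)
    if infer_sides and tl.x < tr.x:
        tl, tr = tr, tl
    return PelvisFrame(teardrop_left=tl, teardrop_right=tr)


def extremal_point(trace: ContourTrace, direction: np.ndarray) -> Point2D:
    """Vertex of the trace with the largest scalar projection on ``direction``.

    Ties (projections equal within 1e-9 of the span) are broken by the
    larger projection onto the clockwise perpendicular of ``direction``
    (clockwise as seen on screen, i.e. ``(-dy, dx)`` in image coordinates),
    which is deterministic.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n < ZERO_VECTOR_EPS:
        raise DegenerateGeometryError("extremal_point needs a nonzero direction")
    d = d / n
    pts = trace.points
    proj = pts @ d
    span = float(proj.max() - proj.min())
    tol = 1e-9 * max(span, 1.0)
    candidates = np.flatnonzero(proj >= proj.max() - tol)
    if candidates.size > 1:
        perp = np.array([-d[1], d[0]])
        candidates = candidates[np.argsort(pts[candidates] @ perp, kind="stable")]
    best = candidates[-1]
    return Point2D(float(pts[best, 0]), float(pts[best, 1]))


def segment_polyline_intersections(
    a: Point2D, b: Point2D, trace: ContourTrace
) -> list[Point2D]:
    """All intersections of segment [a, b] with an open polyline.

    Returned points are ordered by distance from ``a``. Intersections
    within ``SELF_INTERSECTION_EPS`` pixels of ``a`` are dropped so a
    segment anchored on the polyline does not report its own anchor.
    Near-duplicate hits at shared polyline vertices are merged.
    """
    pa = Point2D.of(a).as_array()
    pb = Point2D.of(b).as_array()
    seg = pb - pa
    seg_len = np.linalg.norm(seg)
    if seg_len < ZERO_VECTOR_EPS:
        raise DegenerateGeometryError("segment endpoints coincide")
    pts = trace.points
    p = pts[:-1]
    q = pts[1:]
    e = q - p
    denom = seg[0] * e[:, 1] - seg[1] * e[:, 0]  # cross(seg, edge)
    w = p - pa
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom  # along [a, b]
        s = (w[:, 0] * seg[1] - w[:, 1] * seg[0]) / denom    # along edge
    eps = 1e-12
    ok = (np.abs(denom) > ZERO_VECTOR_EPS * seg_len) \
        & (t >= -eps) & (t <= 1 + eps) & (s >= -eps) & (s <= 1 + eps)
    hits = sorted(float(tv) for tv in t[ok])
    out: list[Point2D] = []
    last_t = -np.inf
    for tv in hits:
        if tv * seg_len < SELF_INTERSECTION_EPS:
            continue  # coincides with the segment start
        if (tv - last_t) * seg_len < SELF_INTERSECTION_EPS:
            continue  # duplicate hit at a shared polyline vertex
        point = pa + tv * seg
        out.append(Point2D(float(point[0]), float(point[1])))
        last_t = tv
    return out


def vertex_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < ZERO_VECTOR_EPS or nv < ZERO_VECTOR_EPS:
        raise DegenerateGeometryError("vertex angle of a zero vector is undefined")
    c = float(np.clip((u @ v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))
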