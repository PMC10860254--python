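"""Planar geometry primitives for cephalometric constructions.

All operations work in the image coordinate frame of a lateral
cephalogram: x increases rightward (anteriorly; the patient faces
right), y increases downward.  Angles are returned in degrees.

Signed distances follow the two clinical conventions used by the
measurement engine:

* ``anterior_positive`` — the line is given cranial→caudal (e.g. the
  facial plane N→Po); points anterior to it (larger x) get positive
  sign.
* ``inferior_positive`` — the line is given posterior→anterior (e.g.
  the palatal plane Spp→Spa); points caudal to it (larger y) get
  positive sign.

Both are expressed through the z-component of a 2-D cross product, so
the sign is invariant under rigid motions applied jointly to the line's
defining points and the query point.
"""

from __future__ import annotations

import math
from typing import Literal, NamedTuple

__all__ = [
    "Point2D",
    "Line",
    "angle_at_vertex",
    "angle_between_lines",
    "inclination_difference",
    "signed_point_line_distance",
    "project_along",
    "line_intersection",
    "construct_xi",
]

#: |sin| of the angle between two lines below which they are treated as
#: parallel when intersecting.
PARALLEL_TOL = 1e-9


class GeometryError(ValueError):
    """Degenerate geometric input (zero-length direction, parallel lines...)."""


class Point2D(NamedTuple):
    """A point in image pixel coordinates (y-down frame)."""

    x: float
    y: float

    def __add__(self, other):  # type: ignore[override]
        return Point2D(self.x + other[0], self.y + other[1])

    def __sub__(self, other):
        return Point2D(self.x - other[0], self.y - other[1])

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other[0], self.y - other[1])


class Line(NamedTuple):
    """A directed line through ``origin`` along ``direction`` (pixels).

    The direction need not be unit length but must have nonzero norm.
    """

    origin: Point2D
    direction: tuple[float, float]

    @classmethod
    def through(cls, p: Point2D, q: Point2D) -> "Line":
        """The line from ``p`` to ``q``, directed p→q."""
        d = (q[0] - p[0], q[1] - p[1])
        if d == (0.0, 0.0):
            raise GeometryError("line through two identical points")
        return cls(Point2D(*p), d)

    @property
    def norm(self) -> float:
        n = math.hypot(*self.direction)
        if n == 0.0:
            raise GeometryError("line with zero-length direction")
        return n

    def unit(self) -> tuple[float, float]:
        n = self.norm
        return (self.direction[0] / n, self.direction[1] / n)

    def perpendicular(self) -> "Line":
        """The line through the same origin rotated +90° (y-down frame)."""
        dx, dy = self.direction
        return Line(self.origin, (-dy, dx))


def angle_at_vertex(a: Point2D, v: Point2D, b: Point2D) -> float:
    """Angle a-v-b at vertex ``v`` in degrees, in [0, 180]."""
    ax, ay = a[0] - v[0], a[1] - v[1]
    bx, by = b[0] - v[0], b[1] - v[1]
    if (ax == 0.0 and ay == 0.0) or (bx == 0.0 and by == 0.0):
        raise GeometryError("zero-length arm at angle vertex")
    # atan2 form: well conditioned near 0 and 180 degrees
    cross = ax * by - ay * bx
    dot = ax * bx + ay * by
    return math.degrees(math.atan2(abs(cross), dot))


def angle_between_lines(
    l1: Line, l2: Line, convention: Literal["acute", "obtuse"] = "acute"
) -> float:
    """Angle between two undirected lines.

    ``acute`` returns a value in [0, 90]; ``obtuse`` its supplement.
    """
    u1 = l1.unit()
    u2 = l2.unit()
    cross = u1[0] * u2[1] - u1[1] * u2[0]
    dot = u1[0] * u2[0] + u1[1] * u2[1]
    acute = math.degrees(math.atan2(abs(cross), abs(dot)))
    if convention == "acute":
        return acute
    if convention == "obtuse":
        return 180.0 - acute
    raise ValueError(f"unknown convention {convention!r}")


def inclination_difference(l_ref: Line, l: Line) -> float:
    """Signed inclination of ``l_ref`` minus that of ``l`` in degrees.

    Inclinations are atan2 angles of the direction vectors in the y-down
    frame; the difference is wrapped to (-180, 180].  With both lines
    directed anteriorly this is negative when ``l`` dips caudally more
    steeply than the reference.
    """
    a_ref = math.atan2(l_ref.direction[1], l_ref.direction[0])
    a = math.atan2(l.direction[1], l.direction[0])
    diff = math.degrees(a_ref - a)
    # wrap to (-180, 180]
    diff = (diff + 180.0) % 360.0 - 180.0
    if diff == -180.0:
        diff = 180.0
    return diff


def signed_point_line_distance(
    p: Point2D,
    l: Line,
    sign_convention: Literal["anterior_positive", "inferior_positive"],
) -> float:
    """Signed perpendicular distance of ``p`` from ``l`` in pixels.

    The magnitude is |cross(direction, p - origin)| / |direction|; the
    sign depends on the convention and on the stated direction of the
    line (see module docstring).
    """
    dx, dy = l.direction
    n = l.norm
    px, py = p[0] - l.origin[0], p[1] - l.origin[1]
    if sign_convention == "anterior_positive":
        return (dy * px - dx * py) / n
    if sign_convention == "inferior_positive":
        return (dx * py - dy * px) / n
    raise ValueError(f"unknown sign convention {sign_convention!r}")


def project_along(p: Point2D, origin: Point2D, axis: Line) -> float:
    """Scalar projection of ``p - origin`` on the unit direction of ``axis``."""
    ux, uy = axis.unit()
    return (p[0] - origin[0]) * ux + (p[1] - origin[1]) * uy


def line_intersection(l1: Line, l2: Line) -> Point2D:
    """Intersection point of two non-parallel lines (2x2 linear solve)."""
    d1x, d1y = l1.unit()
    d2x, d2y = l2.unit()
    det = d1x * d2y - d1y * d2x  # = sin of the angle between unit directions
    if abs(det) < PARALLEL_TOL:
        raise GeometryError("lines are parallel or nearly parallel")
    bx = l2.origin[0] - l1.origin[0]
    by = l2.origin[1] - l1.origin[1]
    # l1.origin + t * u1 = l2.origin + s * u2
    t = (bx * d2y - by * d2x) / det
    return Point2D(l1.origin[0] + t * d1x, l1.origin[1] + t * d1y)


def construct_xi(
    r1: Point2D, r2: Point2D, r3: Point2D, r4: Point2D, fh: Line
) -> Point2D:
    """Center of the mandibular ramus from the four ramal border points.

    Working in the Frankfurt-horizontal-aligned frame (u along FH, n
    perpendicular to it), Xi is the center of the FH-oriented rectangle
    bounded laterally by R1/R2 (anterior/posterior ramal borders) and
    vertically by R3/R4 (semilunar incisure / lower ramal border):
    u(Xi) = (u(R1)+u(R2))/2 and n(Xi) = (n(R3)+n(R4))/2, mapped back to
    image coordinates.
    """
    ux, uy = fh.unit()
    nx, ny = -uy, ux  # +90° rotation, y-down frame

    def u_of(p):
        return p[0] * ux + p[1] * uy

    def n_of(p):
        return p[0] * nx + p[1] * ny

    u_c = 0.5 * (u_of(r1) + u_of(r2))
    n_c = 0.5 * (n_of(r3) + n_of(r4))
    return Point2D(u_c * ux + n_c * nx, u_c * uy + n_c * ny)
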