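"""Geometry primitives: worked examples, independent oracles, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cephmetrics.geometry import (
    GeometryError,
    Line,
    Point2D,
    angle_at_vertex,
    angle_between_lines,
    construct_xi,
    inclination_difference,
    line_intersection,
    project_along,
    signed_point_line_distance,
)

coords = st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False)


def pt(x, y):
    return Point2D(x, y)


def rigid(p, theta, tx, ty):
    c, s = math.cos(theta), math.sin(theta)
    return Point2D(c * p[0] - s * p[1] + tx, s * p[0] + c * p[1] + ty)


class TestAngleAtVertex:
    @pytest.mark.parametrize(
        "a,v,b,expected",
        [
            (pt(1, 0), pt(0, 0), pt(0, 1), 90.0),
            (pt(1, 0), pt(0, 0), pt(-1, 0), 180.0),
            (pt(1, 0), pt(0, 0), pt(1, 0), 0.0),
            (pt(2, 0), pt(0, 0), pt(2, 2), 45.0),
        ],
    )
    def test_known_angles(self, a, v, b, expected):
        assert angle_at_vertex(a, v, b) == pytest.approx(expected, abs=1e-12)

    def test_sna_on_reference(self, ref_a):
        """S-N-A on the expert reference, against a law-of-cosines oracle."""
        s, n, a = ref_a["S"], ref_a["N"], ref_a["A"]
        sn = s.distance_to(n)
        na = n.distance_to(a)
        sa = s.distance_to(a)
        oracle = math.degrees(
            math.acos((sn**2 + na**2 - sa**2) / (2 * sn * na))
        )
        value = angle_at_vertex(s, n, a)
        assert value == pytest.approx(oracle, abs=1e-9)
        assert value == pytest.approx(79.85, abs=0.01)

    def test_zero_arm_rejected(self):
        with pytest.raises(GeometryError):
            angle_at_vertex(pt(0, 0), pt(0, 0), pt(1, 1))


class TestAngleBetweenLines:
    def test_parallel_acute_zero(self):
        l1 = Line(pt(0, 0), (1, 1))
        l2 = Line(pt(5, -3), (2, 2))
        assert angle_between_lines(l1, l2, "acute") == pytest.approx(0, abs=1e-9)

    def test_perpendicular_obtuse(self):
        l1 = Line(pt(0, 0), (1, 0))
        l2 = Line(pt(0, 0), (0, 1))
        assert angle_between_lines(l1, l2, "obtuse") == pytest.approx(90)

    def test_facial_depth_on_reference(self, ref_a):
        """N-Po against Frankfurt horizontal reproduces the printed 86.03."""
        l1 = Line.through(ref_a["N"], ref_a["Po"])
        l2 = Line.through(ref_a["P"], ref_a["Or"])
        assert angle_between_lines(l1, l2, "acute") == pytest.approx(86.03, abs=0.05)

    def test_direction_sign_irrelevant(self, rng):
        for _ in range(50):
            p = rng.normal(size=(4, 2)) * 100
            l1 = Line.through(pt(*p[0]), pt(*p[1]))
            l2 = Line.through(pt(*p[2]), pt(*p[3]))
            l1r = Line.through(pt(*p[1]), pt(*p[0]))
            assert angle_between_lines(l1, l2) == pytest.approx(
                angle_between_lines(l1r, l2), abs=1e-9
            )


class TestInclinationDifference:
    def test_identical_lines_zero(self):
        l = Line(pt(0, 0), (3, 1))
        assert inclination_difference(l, l) == 0.0

    def test_downward_anterior_slope_is_negative(self):
        # y-down frame: a line dipping caudally toward anterior has
        # positive atan2, so reference-minus-line is negative
        ref = Line(pt(0, 0), (1, 0))
        l = Line(pt(0, 0), (1, 1))
        assert inclination_difference(ref, l) == pytest.approx(-45.0)

    def test_palatal_plane_on_reference(self, ref_a):
        fh = Line.through(ref_a["P"], ref_a["Or"])
        pal = Line.through(ref_a["Spp"], ref_a["Spa"])
        assert inclination_difference(fh, pal) == pytest.approx(-4.09, abs=0.05)


class TestSignedDistance:
    def test_point_on_line_is_zero(self):
        l = Line(pt(0, 0), (1, 2))
        assert signed_point_line_distance(pt(2, 4), l, "anterior_positive") == (
            pytest.approx(0, abs=1e-12)
        )

    def test_convexity_of_point_a(self, ref_a):
        """A to the facial plane: +15.91 px, against a cross-product oracle."""
        l = Line.through(ref_a["N"], ref_a["Po"])
        d = signed_point_line_distance(ref_a["A"], l, "anterior_positive")
        # oracle: cross product of direction with offset, explicit numpy
        v = np.array(ref_a["Po"]) - np.array(ref_a["N"])
        w = np.array(ref_a["A"]) - np.array(ref_a["N"])
        oracle = float(w[0] * v[1] - w[1] * v[0]) / float(np.hypot(*v))
        assert d == pytest.approx(oracle, rel=1e-12)
        assert d == pytest.approx(15.91, abs=0.01)

    def test_vertical_molar_offset_sign(self, ref_a):
        l = Line.through(ref_a["Spp"], ref_a["Spa"])
        d = signed_point_line_distance(ref_a["1UpMma"], l, "inferior_positive")
        assert d == pytest.approx(-4.59, abs=0.01)

    def test_reflection_flips_sign(self, rng):
        l = Line(pt(0, 0), (1, 0))
        for _ in range(20):
            x, y = rng.normal(size=2) * 10
            d1 = signed_point_line_distance(pt(x, y), l, "anterior_positive")
            d2 = signed_point_line_distance(pt(x, -y), l, "anterior_positive")
            assert d1 == pytest.approx(-d2, abs=1e-9)

    @given(coords, coords, st.floats(0.1, 10))
    @settings(derandomize=True, max_examples=50)
    def test_scales_linearly(self, x, y, scale):
        l = Line(pt(0, 0), (3, 4))
        d1 = signed_point_line_distance(pt(x, y), l, "anterior_positive")
        l2 = Line(pt(0, 0), (3 * scale, 4 * scale))
        d2 = signed_point_line_distance(
            pt(x * scale, y * scale), l2, "anterior_positive"
        )
        assert d2 == pytest.approx(scale * d1, rel=1e-9, abs=1e-9)


class TestProjection:
    def test_origin_projects_to_zero(self):
        axis = Line(pt(0, 0), (1, 1))
        assert project_along(pt(5, 5), pt(5, 5), axis) == 0.0

    def test_axis_aligned(self):
        axis = Line(pt(0, 0), (1, 0))
        assert project_along(pt(3, 4), pt(0, 0), axis) == pytest.approx(3)

    def test_sagittal_molar_on_reference(self, ref_a):
        fh = Line.through(ref_a["P"], ref_a["Or"])
        d = project_along(ref_a["1UpMdc"], ref_a["Pt"], fh)
        assert d == pytest.approx(89.41, abs=0.02)


class TestLineIntersection:
    def test_axes_cross_at_origin(self):
        p = line_intersection(Line(pt(0, 5), (0, 1)), Line(pt(5, 0), (1, 0)))
        assert p.x == pytest.approx(0, abs=1e-12)
        assert p.y == pytest.approx(0, abs=1e-12)

    def test_parallel_raises(self):
        with pytest.raises(GeometryError):
            line_intersection(Line(pt(0, 0), (1, 1)), Line(pt(1, 0), (2, 2)))

    def test_matches_linear_solve_oracle(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(4, 2)) * 100
            l1 = Line.through(pt(*pts[0]), pt(*pts[1]))
            l2 = Line.through(pt(*pts[2]), pt(*pts[3]))
            d1 = np.array(l1.direction)
            d2 = np.array(l2.direction)
            denom = float(d1[0] * d2[1] - d1[1] * d2[0])
            if abs(denom / (np.hypot(*d1) * np.hypot(*d2))) < 1e-6:
                continue
            # oracle: solve [d1, -d2] [t, s]^T = o2 - o1 with numpy
            A = np.column_stack([d1, -d2])
            ts = np.linalg.solve(A, np.array(pts[2]) - np.array(pts[0]))
            expect = np.array(pts[0]) + ts[0] * d1
            got = line_intersection(l1, l2)
            assert np.allclose(got, expect, atol=1e-6)

    def test_gnk_on_reference(self, ref_a):
        got = line_intersection(
            Line.through(ref_a["hT"], ref_a["Me"]),
            Line.through(ref_a["N"], ref_a["Po"]),
        )
        assert got.distance_to(Point2D(854.28, 621.05)) < 0.05


class TestConstructXi:
    def test_square_center(self):
        fh = Line(pt(0, 0), (1, 0))
        xi = construct_xi(pt(2, 1), pt(0, 1), pt(1, 0), pt(1, 2), fh)
        assert xi.x == pytest.approx(1)
        assert xi.y == pytest.approx(1)

    def test_reference_xi(self, ref_a):
        fh = Line.through(ref_a["P"], ref_a["Or"])
        xi = construct_xi(ref_a["R1"], ref_a["R2"], ref_a["R3"], ref_a["R4"], fh)
        assert xi.distance_to(Point2D(609.52, 404.73)) < 0.2

    def test_rotation_equivariance(self, rng):
        for _ in range(20):
            pts = [pt(*p) for p in rng.normal(size=(6, 2)) * 50]
            fh = Line.through(pts[4], pts[5])
            xi = construct_xi(*pts[:4], fh)
            theta, tx, ty = rng.uniform(-math.pi, math.pi), *rng.normal(size=2)
            rpts = [rigid(p, theta, tx, ty) for p in pts]
            rfh = Line.through(rpts[4], rpts[5])
            rxi = construct_xi(*rpts[:4], rfh)
            assert rxi.distance_to(rigid(xi, theta, tx, ty)) < 1e-8


@given(
    st.lists(st.tuples(coords, coords), min_size=3, max_size=3, unique=True),
    st.floats(-math.pi, math.pi),
    st.tuples(coords, coords),
    st.floats(0.5, 2.0),
)
@settings(derandomize=True, max_examples=100)
def test_angle_invariant_under_similarity(points, theta, shift, scale):
    """Angles are invariant under rotation, translation and uniform scaling."""
    a, v, b = (pt(*p) for p in points)
    if a.distance_to(v) < 1e-6 or b.distance_to(v) < 1e-6:
        return
    base = angle_at_vertex(a, v, b)

    def sim(p):
        r = rigid(p, theta, *shift)
        return Point2D(r.x * scale, r.y * scale)

    assert angle_at_vertex(sim(a), sim(v), sim(b)) == pytest.approx(
        base, abs=1e-6
    )
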