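"""Geometric primitives: areas, containment, contacts, downward rays."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point as ShPoint

from intuifluids.geometry2d import (
    BOUNDARY_EPS,
    Circle,
    Contact,
    InvalidGeometryError,
    Point2,
    Polygon,
    circle_obstacle_contact,
    point_in_polygon,
    polygon_area,
    ray_down_first_hit,
)

UNIT_SQUARE = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])


def random_convex_polygon(rng, n=8):
    """Convex n-gon as the radial hull of sorted random angles."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = rng.uniform(0.5, 1.5, n)
    return Polygon(np.column_stack([rad * np.cos(ang), rad * np.sin(ang)]))


class TestPolygonArea:
    @pytest.mark.parametrize("verts,expected", [
        ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
        ([(0, 0), (1, 0), (0, 1)], 0.5),
    ])
    def test_known_areas(self, verts, expected):
        assert polygon_area(Polygon(verts)) == pytest.approx(expected)

    def test_matches_fan_triangulation(self, rng):
        poly = random_convex_polygon(rng, 8)
        v = poly.vertices
        # fan triangulation from vertex 0: sum of signed triangle areas
        fan = 0.0
        for i in range(1, len(v) - 1):
            a, b, c = v[0], v[i], v[i + 1]
            fan += 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
        assert polygon_area(poly) == pytest.approx(fan, abs=1e-12)

    def test_reversal_flips_sign(self, rng):
        poly = random_convex_polygon(rng)
        assert polygon_area(poly.vertices[::-1]) == pytest.approx(-polygon_area(poly))

    def test_rigid_motion_invariance(self, rng):
        poly = random_convex_polygon(rng)
        a0 = polygon_area(poly)
        for _ in range(5):
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            moved = poly.vertices @ R.T + rng.uniform(-3, 3, 2)
            assert abs(polygon_area(moved)) == pytest.approx(abs(a0), abs=1e-10)

    def test_degenerate_rejected(self):
        with pytest.raises(InvalidGeometryError):
            Polygon([(0, 0), (1, 1)])
        with pytest.raises(InvalidGeometryError):
            polygon_area([(0, 0), (1, 1)])


def _winding_number_inside(p, verts):
    """Independent winding-number oracle."""

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    w = 0
    n = len(verts)
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        if a[1] <= p[1]:
            if b[1] > p[1] and cross2(b - a, p - a) > 0:
                w += 1
        elif b[1] <= p[1] and cross2(b - a, p - a) < 0:
            w -= 1
    return w != 0


class TestPointInPolygon:
    def test_center_inside(self):
        assert point_in_polygon(Point2(0.5, 0.5), UNIT_SQUARE)

    def test_far_point_outside(self):
        assert not point_in_polygon(Point2(2.0, 2.0), UNIT_SQUARE)

    def test_boundary_counts_as_inside(self):
        assert point_in_polygon(Point2(1.0, 0.5), UNIT_SQUARE)

    def test_matches_winding_number_oracle(self, rng):
        poly = random_convex_polygon(rng, 9)
        pts = rng.uniform(-2, 2, size=(1000, 2))
        for p in pts:
            # skip the ambiguous boundary band
            if poly.shapely.exterior.distance(ShPoint(*p)) < 1e-7:
                continue
            assert point_in_polygon(p, poly) == _winding_number_inside(p, poly.vertices)


class TestCircleObstacleContact:
    def test_flat_edge_penetration(self):
        # particle centered 0.005 above the top edge of the unit square
        c = Circle(Point2(0.5, 1.005), 0.01)
        ct = circle_obstacle_contact(c, UNIT_SQUARE)
        assert ct is not None
        assert ct.normal == pytest.approx((0.0, 1.0))
        assert ct.penetration == pytest.approx(0.005)

    def test_far_particle_no_contact(self):
        assert circle_obstacle_contact(Circle(Point2(5, 5), 0.01), UNIT_SQUARE) is None

    def test_circle_circle(self):
        ob = Circle(Point2(0, 0), 1.0)
        ct = circle_obstacle_contact(Circle(Point2(1.05, 0), 0.1), ob)
        assert ct.normal == pytest.approx((1.0, 0.0))
        assert ct.penetration == pytest.approx(0.05)

    def test_corner_contact_matches_boundary_sampling(self, rng):
        poly = UNIT_SQUARE
        # particle near the (1, 1) corner, outside both edges
        c = Circle(Point2(1.004, 1.003), 0.01)
        ct = circle_obstacle_contact(c, poly)
        # dense boundary sampling oracle for the closest surface point
        ring = poly.shapely.exterior
        ts = np.linspace(0, ring.length, 400001)
        pts = np.array([ring.interpolate(t).coords[0] for t in ts[::400]])
        d = np.hypot(pts[:, 0] - 1.004, pts[:, 1] - 1.003)
        best = pts[np.argmin(d)]
        assert ct.point.x == pytest.approx(best[0], abs=1e-5)
        assert ct.point.y == pytest.approx(best[1], abs=1e-5)

    def test_translation_invariance(self, rng):
        c = Circle(Point2(0.5, 1.004), 0.01)
        ct0 = circle_obstacle_contact(c, UNIT_SQUARE)
        for _ in range(5):
            dx, dy = rng.uniform(-3, 3, 2)
            ct = circle_obstacle_contact(c.translated(dx, dy),
                                         UNIT_SQUARE.translated(dx, dy))
            assert ct.normal == pytest.approx(ct0.normal, abs=1e-9)
            assert ct.penetration == pytest.approx(ct0.penetration, abs=1e-9)


class TestRayDownFirstHit:
    def test_empty_floor(self):
        pt, desc = ray_down_first_hit(Point2(0.3, 1.0), [])
        assert desc == ("floor", None)
        assert (pt.x, pt.y) == (0.3, 0.0)

    def test_square_top_edge(self):
        sq = Polygon([(0.4, 0.5), (0.6, 0.5), (0.6, 0.8), (0.4, 0.8)])
        pt, desc = ray_down_first_hit(Point2(0.5, 1.2), [sq])
        assert desc[0] == "polygon"
        assert pt.y == pytest.approx(0.8)

    def test_stacked_obstacles_match_all_edges_oracle(self, rng):
        obstacles = []
        for _ in range(6):
            cx, cy = rng.uniform(0.2, 0.8), rng.uniform(0.2, 1.2)
            s = rng.uniform(0.03, 0.12)
            obstacles.append(Polygon([(cx - s, cy - s), (cx + s, cy - s),
                                      (cx + s, cy + s), (cx - s, cy + s)]))
        for _ in range(50):
            x, y = rng.uniform(0, 1), 1.45
            pt, _ = ray_down_first_hit(Point2(x, y), obstacles)
            # brute force: intersect every edge, take the max y below origin
            best = 0.0
            for ob in obstacles:
                v = ob.vertices
                for i in range(len(v)):
                    a, b = v[i], v[(i + 1) % len(v)]
                    if a[0] == b[0]:
                        continue
                    lo, hi = min(a[0], b[0]), max(a[0], b[0])
                    if lo <= x <= hi:
                        yi = a[1] + (x - a[0]) / (b[0] - a[0]) * (b[1] - a[1])
                        if y > yi > best:
                            best = yi
            assert pt.y == pytest.approx(best, abs=1e-12)

    @given(x=st.floats(0, 1), y=st.floats(0.1, 1.5))
    @settings(max_examples=30, deadline=None)
    def test_hit_never_above_origin(self, x, y):
        sq = Polygon([(0.3, 0.4), (0.7, 0.4), (0.7, 0.7), (0.3, 0.7)])
        pt, _ = ray_down_first_hit(Point2(x, y), [sq])
        assert pt.y <= y


class TestContactValidation:
    def test_non_unit_normal_rejected(self):
        with pytest.raises(InvalidGeometryError):
            Contact(Point2(0, 0), (0.5, 0.5), 0.01)

    def test_negative_penetration_rejected(self):
        with pytest.raises(InvalidGeometryError):
            Contact(Point2(0, 0), (0.0, 1.0), -0.01)
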