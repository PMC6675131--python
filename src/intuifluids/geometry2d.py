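"""Exact 2D geometric primitives shared by every simulator and the scene generators.

Coordinate frame: origin at the scene's bottom-left corner, x rightward,
y upward, gravity acting along (0, -9.81) m/s^2.  All lengths are in meters,
double precision.  Scenes are strictly planar.

Obstacles are simple CCW polygons or circles.  Particles are circles; the
``Contact`` record carries the outward obstacle normal and penetration depth
used by the inelastic collision response of the particle engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import shapely
from shapely.geometry import Point as _ShPoint
from shapely.geometry import Polygon as _ShPolygon
from shapely.ops import nearest_points

__all__ = [
    "Point2",
    "Polygon",
    "Circle",
    "Contact",
    "InvalidGeometryError",
    "polygon_area",
    "point_in_polygon",
    "circle_obstacle_contact",
    "ray_down_first_hit",
]

#: half-width of the boundary band that still counts as "inside" a polygon.
BOUNDARY_EPS = 1e-9


class InvalidGeometryError(ValueError):
    """Raised for degenerate or self-intersecting shapes."""


@dataclass(frozen=True)
class Point2:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise InvalidGeometryError("Point2 coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _as_xy(p) -> np.ndarray:
    """Accept Point2, tuple or array-like and return a (2,) float array."""
    if isinstance(p, Point2):
        return p.as_array()
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise InvalidGeometryError(f"expected a 2D point, got shape {a.shape}")
    return a


class Polygon:
    """Simple polygon with CCW-ordered vertices and positive area.

    Vertices are stored as an (n, 2) float array; the ring is closed
    implicitly (the last vertex connects back to the first).
    """

    __slots__ = ("vertices", "_shapely")

    def __init__(self, vertices) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidGeometryError("polygon needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise InvalidGeometryError("polygon vertices must be finite")
        signed = _shoelace(v)
        if abs(signed) < 1e-14:
            raise InvalidGeometryError("polygon has zero area")
        if signed < 0:
            raise InvalidGeometryError("polygon vertices must be CCW ordered")
        sh = _ShPolygon(v)
        if not sh.is_valid:
            raise InvalidGeometryError("polygon is self-intersecting or invalid")
        self.vertices = v
        self._shapely = sh

    @property
    def shapely(self) -> _ShPolygon:
        return self._shapely

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def translated(self, dx: float, dy: float) -> "Polygon":
        return Polygon(self.vertices + np.array([dx, dy]))

    def mirrored_x(self, axis_x: float) -> "Polygon":
        v = self.vertices.copy()
        v[:, 0] = 2.0 * axis_x - v[:, 0]
        return Polygon(v[::-1])  # reversing restores CCW order

    def __repr__(self) -> str:  # pragma: no cover
        return f"Polygon(n={self.n_vertices}, area={polygon_area(self):.4f})"


@dataclass(frozen=True)
class Circle:
    center: Point2
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InvalidGeometryError("circle radius must be > 0")

    @property
    def shapely(self):
        return _ShPoint(self.center.x, self.center.y).buffer(self.radius, quad_segs=64)

    def translated(self, dx: float, dy: float) -> "Circle":
        return Circle(Point2(self.center.x + dx, self.center.y + dy), self.radius)

    def mirrored_x(self, axis_x: float) -> "Circle":
        return Circle(Point2(2.0 * axis_x - self.center.x, self.center.y), self.radius)


Obstacle = Union[Polygon, Circle]


@dataclass(frozen=True)
class Contact:
    """Particle-obstacle overlap: contact point on the obstacle surface,
    outward unit normal, penetration depth (>= 0)."""

    point: Point2
    normal: tuple
    penetration: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(float(np.hypot(n[0], n[1])) - 1.0) > 1e-9:
            raise InvalidGeometryError("contact normal must be a unit vector")
        if self.penetration < 0:
            raise InvalidGeometryError("penetration must be >= 0")


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(poly) -> float:
    """Signed shoelace area; positive for CCW vertex order.

    Accepts a ``Polygon`` (always positive by the class invariant) or a raw
    (n, 2) vertex array, whose orientation is preserved in the sign.
    """
    if isinstance(poly, Polygon):
        return _shoelace(poly.vertices)
    v = np.asarray(poly, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise InvalidGeometryError("polygon needs >= 3 (x, y) vertices")
    return _shoelace(v)


def point_in_polygon(p, poly: Polygon) -> bool:
    """True if p is inside the polygon; boundary points (within a 1e-9 m
    band) count as inside — conservative for collision handling."""
    pt = _ShPoint(*_as_xy(p))
    return bool(poly.shapely.contains(pt)) or poly.shapely.exterior.distance(pt) <= BOUNDARY_EPS


def circle_obstacle_contact(c: Circle, obstacle: Obstacle) -> Optional[Contact]:
    """Contact between a particle disc and a solid obstacle, or None.

    The normal points out of the obstacle (the direction in which the
    particle must move to resolve the overlap).
    """
    p = np.array([c.center.x, c.center.y])
    if isinstance(obstacle, Circle):
        q = np.array([obstacle.center.x, obstacle.center.y])
        d = float(np.hypot(*(p - q)))
        pen = obstacle.radius + c.radius - d
        if pen <= 0:
            return None
        n = (p - q) / d if d > 1e-12 else np.array([0.0, 1.0])
        surf = q + n * obstacle.radius
        return Contact(Point2(*surf), (float(n[0]), float(n[1])), pen)

    sh = obstacle.shapely
    pt = _ShPoint(*p)
    boundary = sh.exterior
    d = float(boundary.distance(pt))
    inside = sh.contains(pt)
    if not inside and d >= c.radius:
        return None
    cp = nearest_points(boundary, pt)[0]
    surf = np.array([cp.x, cp.y])
    delta = p - surf
    nd = float(np.hypot(*delta))
    if nd > 1e-12:
        n = delta / nd
        if inside:
            n = -n
    else:
        n = np.array([0.0, 1.0])  # center exactly on boundary: degenerate
    pen = c.radius + d if inside else c.radius - d
    return Contact(Point2(*surf), (float(n[0]), float(n[1])), float(pen))


def _vertical_hits_segment(x: float, y: float, a: np.ndarray, b: np.ndarray):
    """Intersection of the downward ray from (x, y) with segment ab, or None."""
    ax, ay = a
    bx, by = b
    if ax == bx:  # vertical edge: grazing, no unique crossing
        return None
    lo, hi = (ax, bx) if ax < bx else (bx, ax)
    if not (lo <= x <= hi):
        return None
    t = (x - ax) / (bx - ax)
    yi = ay + t * (by - ay)
    if yi < y - 1e-12:
        return yi
    return None


def _vertical_hits_circle(x: float, y: float, circ: Circle):
    cx, cy, r = circ.center.x, circ.center.y, circ.radius
    dx = x - cx
    if abs(dx) > r:
        return None
    dy = np.sqrt(max(r * r - dx * dx, 0.0))
    for yi in (cy + dy, cy - dy):
        if yi < y - 1e-12:
            return yi  # upper intersection first (it is the larger y)
    return None


def ray_down_first_hit(origin, obstacles, floor_y: float = 0.0):
    """First intersection of the straight-down ray from origin with any
    obstacle boundary, else the floor.

    Returns ``(Point2, descriptor)`` where the descriptor is
    ``("floor", None)``, ``("polygon", (obstacle_index, edge_index))`` or
    ``("circle", obstacle_index)``.  Among all candidate intersections the
    one with the highest y strictly below the origin wins.
    """
    x, y = _as_xy(origin)
    best_y = floor_y
    best = ("floor", None)
    for oi, ob in enumerate(obstacles):
        if isinstance(ob, Circle):
            yi = _vertical_hits_circle(x, y, ob)
            if yi is not None and yi > best_y:
                best_y, best = yi, ("circle", oi)
        else:
            v = ob.vertices
            n = v.shape[0]
            for ei in range(n):
                yi = _vertical_hits_segment(x, y, v[ei], v[(ei + 1) % n])
                if yi is not None and yi > best_y:
                    best_y, best = yi, ("polygon", (oi, ei))
    return Point2(x, best_y), best
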