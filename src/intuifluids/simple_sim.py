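"""SimpleSim: a heuristic path tracer for liquid prediction, and the
gravity heuristic as its noise-free special case.

Each of ``n_particles`` independent "particles" starts on the midline of
the liquid start region and traces a purely geometric path: straight down
until an obstacle is met, then along the obstacle surface following the
local downhill gradient until it can fall straight down again.  Two
parameters produce a family of liquids:

* ``g`` in [0, 1]: probability of choosing the *wrong* (against-gravity)
  direction at the first collision with an obstacle, traversing over the
  obstacle to its far silhouette before descending;
* ``m`` in [0, 0.2] m: "momentum" — on leaving an obstacle the particle
  carries on horizontally for distance m in its direction of travel before
  dropping.

The prediction J is the fraction of terminal points right of the divider
(or inside the cup).  Uncertainty over m averages deterministic
predictions over an evenly sampled window [m - sigma_m, m + sigma_m].
The gravity heuristic is SimpleSim with m = 0 and g = 0: deterministic,
identical for every liquid.

Perfectly horizontal edges leave the downhill direction undefined; ties
break toward the edge endpoint nearer the contact point, and an exact
midpoint contact goes right.  A terminal point landing exactly on the
divider counts as left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry2d import Circle, Point2, Polygon
from .scenes import Cup, Divider, Scene

__all__ = [
    "HeuristicParams",
    "ParticlePath",
    "TracingError",
    "trace_particle",
    "predict_simplesim",
    "gravity_heuristic",
    "M_MIN",
    "M_MAX",
]

EPS = 1e-9
M_MIN, M_MAX = 0.0, 0.2
MAX_SEGMENTS = 1000
M_WINDOW_POINTS = 9  # samples across [m - sigma_m, m + sigma_m]


class TracingError(RuntimeError):
    pass


@dataclass(frozen=True)
class HeuristicParams:
    g: float = 0.0
    m: float = 0.0
    sigma_m: float = 0.0
    n_particles: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("g must lie in [0, 1]")
        if not M_MIN <= self.m <= M_MAX:
            raise ValueError(f"m must lie in [{M_MIN}, {M_MAX}]")
        if self.sigma_m < 0:
            raise ValueError("sigma_m must be >= 0")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")


@dataclass
class ParticlePath:
    points: List[Tuple[float, float]]
    terminal_x: float
    terminal_y: float
    decisions: Dict[int, bool] = field(default_factory=dict)

    @property
    def segments(self) -> List[Tuple[float, float]]:
        return self.points


# ---------------------------------------------------------------------------
# low-level ray / clip helpers


def _drop_hit(x: float, y: float, obstacles, cup: Optional[Cup], width: float):
    """Highest intersection of the downward ray from (x, y).

    Returns (kind, obstacle_index, hit_y, extra) where kind is
    'floor', 'cup_base', 'polygon' (extra = edge index) or 'circle'.
    """
    best_y = 0.0
    best = ("floor", -1, 0.0, None)
    if cup is not None:
        lo = cup.center_x - cup.width / 2
        hi = cup.center_x + cup.width / 2
        if lo - EPS <= x <= hi + EPS and cup.wall_thickness < y - EPS:
            best_y = cup.wall_thickness
            best = ("cup_base", -1, best_y, None)
    for oi, ob in enumerate(obstacles):
        if isinstance(ob, Circle):
            cx, cy, r = ob.center.x, ob.center.y, ob.radius
            dx = x - cx
            if abs(dx) >= r - 1e-12:
                continue
            yi = cy + np.sqrt(r * r - dx * dx)
            if yi >= y - EPS:
                yi = cy - np.sqrt(r * r - dx * dx)  # dropping from inside the span
            if y - EPS > yi > best_y:
                best_y = yi
                best = ("circle", oi, yi, None)
        else:
            v = ob.vertices
            n = v.shape[0]
            for ei in range(n):
                ax, ay = v[ei]
                bx, by = v[(ei + 1) % n]
                if abs(bx - ax) < 1e-15:
                    continue  # vertical edge: grazing only
                lo, hi = (ax, bx) if ax < bx else (bx, ax)
                if not (lo <= x <= hi):
                    continue
                t = (x - ax) / (bx - ax)
                yi = ay + t * (by - ay)
                if y - EPS > yi > best_y:
                    best_y = yi
                    best = ("polygon", oi, yi, ei)
    return best


def _clip_horizontal(x0: float, y0: float, direction: int, dist: float,
                     obstacles, width: float) -> float:
    """End x of a horizontal run of length dist, clipped at the first
    obstacle boundary or scene wall (backed off by a hair)."""
    if direction == 0 or dist <= 0:
        return x0
    x_target = x0 + direction * dist
    x_target = min(max(x_target, 0.0), width)
    best = x_target
    for ob in obstacles:
        if isinstance(ob, Circle):
            cx, cy, r = ob.center.x, ob.center.y, ob.radius
            dy = y0 - cy
            if abs(dy) >= r:
                continue
            half = np.sqrt(r * r - dy * dy)
            for xi in (cx - half, cx + half):
                if direction * (xi - x0) > EPS and direction * (best - xi) > 0:
                    best = xi - direction * EPS
        else:
            v = ob.vertices
            n = v.shape[0]
            for ei in range(n):
                ax, ay = v[ei]
                bx, by = v[(ei + 1) % n]
                if abs(by - ay) < 1e-15:
                    continue
                t = (y0 - ay) / (by - ay)
                if not (0.0 <= t <= 1.0):
                    continue
                xi = ax + t * (bx - ax)
                if direction * (xi - x0) > EPS and direction * (best - xi) > 0:
                    best = xi - direction * EPS
    return best


def _horizontal_tie_direction(q: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Downhill is undefined on a flat edge: go toward the endpoint nearer
    the contact point; an exact midpoint goes right."""
    da = abs(q[0] - a[0])
    db = abs(q[0] - b[0])
    if abs(da - db) < 1e-12:
        return a if a[0] > b[0] else b
    return a if da < db else b


# ---------------------------------------------------------------------------
# surface walking


def _walk_polygon(poly: Polygon, edge_idx: int, q: np.ndarray, wrong: bool,
                  path: List[Tuple[float, float]]):
    """Follow the polygon surface from hit point q on edge edge_idx.

    Downhill mode hugs successive edges while they strictly descend and
    departs at the first vertex whose next edge does not.  The
    against-gravity branch walks toward the higher endpoint, keeps
    ascending to the far silhouette (the last vertex before the boundary
    turns downward), then descends by the same hugging rule.

    Returns (departure_point, x_direction_of_travel).
    """
    v = poly.vertices
    n = v.shape[0]
    a = v[edge_idx]
    b = v[(edge_idx + 1) % n]
    if abs(a[1] - b[1]) < 1e-12:
        down_target = _horizontal_tie_direction(q, a, b)
    else:
        down_target = a if a[1] < b[1] else b
    target = (b if down_target is a else a) if wrong else down_target
    if np.array_equal(target, a):
        cur, step = edge_idx, -1
    else:
        cur, step = (edge_idx + 1) % n, +1
    last_dx = float(v[cur][0] - q[0])
    path.append((float(v[cur][0]), float(v[cur][1])))
    ascending = wrong
    for _ in range(4 * n + 8):
        nxt = (cur + step) % n
        if ascending:
            if v[nxt][1] > v[cur][1] + 1e-12:
                last_dx = float(v[nxt][0] - v[cur][0]) or last_dx
                cur = nxt
                path.append((float(v[cur][0]), float(v[cur][1])))
                continue
            ascending = False  # crested the silhouette; descend from here
        if v[nxt][1] < v[cur][1] - 1e-12:
            last_dx = float(v[nxt][0] - v[cur][0]) or last_dx
            cur = nxt
            path.append((float(v[cur][0]), float(v[cur][1])))
        else:
            break
    direction = 0 if last_dx == 0.0 else (1 if last_dx > 0 else -1)
    return v[cur].astype(float).copy(), direction


def _walk_circle(circ: Circle, x_hit: float, wrong: bool,
                 path: List[Tuple[float, float]]):
    """Slide along a circular surface from the upper-half hit point.

    Downhill departs at the near side extremum (cx +/- r, cy); the
    against-gravity branch goes over the top and departs at the far
    extremum.  Returns (departure_point, x_direction)."""
    cx, cy, r = circ.center.x, circ.center.y, circ.radius
    d = 1 if x_hit > cx + 1e-12 else (-1 if x_hit < cx - 1e-12 else 1)
    if wrong:
        d = -d
    theta_hit = float(np.arccos(np.clip((x_hit - cx) / r, -1.0, 1.0)))  # from +x axis
    theta_end = 0.0 if d > 0 else np.pi
    # sample the traversed arc (over the top for the wrong branch)
    if wrong:
        via = np.pi / 2
        thetas = np.concatenate([np.linspace(theta_hit, via, 6), np.linspace(via, theta_end, 7)[1:]])
    else:
        thetas = np.linspace(theta_hit, theta_end, 8)
    for t in thetas[1:]:
        path.append((cx + r * np.cos(t), cy + r * np.sin(t)))
    return np.array([cx + d * r, cy]), d


# ---------------------------------------------------------------------------
# public tracer


def trace_particle(x0: float, scene: Scene, params: HeuristicParams,
                   rng: np.random.Generator) -> ParticlePath:
    """Trace one particle from the top of the liquid start region down to
    the floor or cup base.  Deterministic given the rng state; with g = 0
    no randomness is consumed."""
    if not (0.0 <= x0 <= scene.width):
        raise ValueError("x0 outside the scene width")
    cup = scene.receptacle if isinstance(scene.receptacle, Cup) else None
    obstacles = list(scene.obstacles)
    n_real = len(obstacles)
    if cup is not None:
        obstacles.extend(cup.wall_polygons()[:2])  # walls slide; base terminates
    x = float(x0)
    y = scene.liquid_start.center.y + scene.liquid_start.radius
    path: List[Tuple[float, float]] = [(x, y)]
    decisions: Dict[int, bool] = {}
    for _ in range(MAX_SEGMENTS):
        kind, oi, hit_y, extra = _drop_hit(x, y, obstacles, cup, scene.width)
        if kind in ("floor", "cup_base"):
            path.append((x, hit_y))
            return ParticlePath(path, terminal_x=x, terminal_y=hit_y,
                                decisions=decisions)
        path.append((x, hit_y))
        wrong = False
        if oi < n_real and oi not in decisions:
            # noise decision once per (real) obstacle, upon initial collision
            wrong = (params.g > 0.0) and (rng.random() < params.g)
            decisions[oi] = wrong
        ob = obstacles[oi]
        if kind == "circle":
            dep, direction = _walk_circle(ob, x, wrong, path)
        else:
            dep, direction = _walk_polygon(ob, extra, np.array([x, hit_y]), wrong, path)
        x, y = float(dep[0]), float(dep[1])
        if params.m > 0 and direction != 0:
            x_end = _clip_horizontal(x, y, direction, params.m, obstacles, scene.width)
            if x_end != x:
                path.append((x_end, y))
                x = x_end
        # nudge off the silhouette so the vertical ray does not re-enter
        x = min(max(x + direction * EPS, 0.0), scene.width)
    raise TracingError(f"path exceeded {MAX_SEGMENTS} segments (cycle?)")


def _judged_fraction(terminals: List[Tuple[float, float]], scene: Scene) -> float:
    rec = scene.receptacle
    if isinstance(rec, Divider):
        n_right = sum(1 for tx, _ in terminals if tx > rec.x)  # exact tie -> left
        return n_right / len(terminals)
    n_in = sum(1 for tx, ty in terminals if rec.contains(tx, ty + 1e-6))
    return n_in / len(terminals)


def _deterministic_J(scene: Scene, g: float, m: float, n_particles: int,
                     seed: int) -> float:
    params = HeuristicParams(g=g, m=m, sigma_m=0.0, n_particles=n_particles, seed=seed)
    rng = np.random.default_rng(seed)
    c = scene.liquid_start.center.x
    R = scene.liquid_start.radius
    xs = np.linspace(c - R, c + R, n_particles)
    terminals = []
    for x0 in xs:
        p = trace_particle(float(x0), scene, params, rng)
        terminals.append((p.terminal_x, p.terminal_y))
    return _judged_fraction(terminals, scene)


def predict_simplesim(scene: Scene, params: HeuristicParams) -> float:
    """SimpleSim judgment J in [0, 1].

    With sigma_m > 0, J is the mean of deterministic predictions over
    ``M_WINDOW_POINTS`` evenly spaced m values in [m - sigma_m, m + sigma_m]
    clipped to the explored range [0, 0.2]; the same seed (hence the same
    noise decisions) is shared across the window."""
    if params.sigma_m == 0.0:
        return _deterministic_J(scene, params.g, params.m, params.n_particles,
                                params.seed)
    lo = max(M_MIN, params.m - params.sigma_m)
    hi = min(M_MAX, params.m + params.sigma_m)
    ms = np.linspace(lo, hi, M_WINDOW_POINTS)
    js = [_deterministic_J(scene, params.g, float(mv), params.n_particles,
                           params.seed) for mv in ms]
    return float(np.mean(js))


def gravity_heuristic(scene: Scene, n_particles: int = 100) -> float:
    """SimpleSim with m = 0 and g = 0: fully deterministic, identical for
    every liquid type."""
    return predict_simplesim(scene, HeuristicParams(g=0.0, m=0.0, sigma_m=0.0,
                                                    n_particles=n_particles))
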