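"""Scene data model, random scene generators, filters, and JSON I/O.

Two stimulus families are generated, mirroring the two judgment tasks:

* *Voronoi scenes* — a plane is divided into polygonal cells by a 2D
  Voronoi tessellation and a random subset of cells is solidified as
  obstacles until their total area reaches a target (0.12 m^2 by default).
  The receptacle is a divider at the scene midline and the judgment is the
  fraction of liquid ending on its right.
* *Shape scenes* — exactly three obstacles drawn from {equilateral
  triangle, square, circle} of random size and position, with a cup one
  third of the scene width at one of five evenly spaced floor positions;
  the judgment is the fraction of liquid ending inside the cup.

Default scene is 1.0 m wide by 1.50 m tall with a liquid start disc of
diameter 0.148 m centered near the top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon as _ShPolygon, box as _sh_box
from shapely.geometry.polygon import orient as _sh_orient

from .geometry2d import (
    Circle,
    InvalidGeometryError,
    Obstacle,
    Point2,
    Polygon,
    polygon_area,
)

__all__ = [
    "Divider",
    "Cup",
    "Scene",
    "SceneSet",
    "SceneGenerationError",
    "generate_voronoi_scene",
    "generate_shape_scene",
    "coarse_filter",
    "CoarseFilterParams",
    "select_contrastive_scenes",
    "mirror_scene",
    "save_scene",
    "load_scene",
]

DEFAULT_WIDTH = 1.0
DEFAULT_HEIGHT = 1.50
LIQUID_DIAMETER = 0.148

# obstacle band for the Voronoi generator: keeps the top clear for the
# liquid start and the bottom clear for the basins
BAND_Y_LO = 0.25
BAND_Y_HI = 1.15
VORONOI_SHRINK = 0.01  # inward offset so channels exist between obstacles
MIN_CELL_AREA = 0.004  # discard sliver cells below this area

CUP_WALL_THICKNESS = 0.02
CUP_WALL_HEIGHT = 0.2


class SceneGenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its constraints after bounded retries."""


@dataclass(frozen=True)
class Divider:
    """Vertical divider at the bottom of the scene; classification only
    (particles with final x > x are 'right')."""

    x: float


@dataclass(frozen=True)
class Cup:
    """Open-top U-shaped cup sitting on the floor: two walls plus a base slab."""

    center_x: float
    width: float
    wall_height: float = CUP_WALL_HEIGHT
    wall_thickness: float = CUP_WALL_THICKNESS

    def wall_polygons(self) -> List[Polygon]:
        cx, w, t, h = self.center_x, self.width, self.wall_thickness, self.wall_height
        left = Polygon([(cx - w / 2, t), (cx - w / 2 + t, t),
                        (cx - w / 2 + t, t + h), (cx - w / 2, t + h)])
        right = Polygon([(cx + w / 2 - t, t), (cx + w / 2, t),
                         (cx + w / 2, t + h), (cx + w / 2 - t, t + h)])
        base = Polygon([(cx - w / 2, 0.0), (cx + w / 2, 0.0),
                        (cx + w / 2, t), (cx - w / 2, t)])
        return [left, right, base]

    def interior_x(self) -> tuple:
        """Open x-interval of the cup interior (between inner wall faces)."""
        return (self.center_x - self.width / 2 + self.wall_thickness,
                self.center_x + self.width / 2 - self.wall_thickness)

    def contains(self, x: float, y: float) -> bool:
        lo, hi = self.interior_x()
        return lo < x < hi and self.wall_thickness <= y <= self.wall_thickness + self.wall_height


Receptacle = Union[Divider, Cup]


@dataclass
class Scene:
    width: float = DEFAULT_WIDTH
    height: float = DEFAULT_HEIGHT
    obstacles: List[Obstacle] = field(default_factory=list)
    liquid_start: Circle = None
    receptacle: Receptacle = None
    seed: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.liquid_start is None:
            self.liquid_start = Circle(
                Point2(self.width / 2, self.height - 0.15), LIQUID_DIAMETER / 2
            )
        if self.receptacle is None:
            self.receptacle = Divider(self.width / 2)
        self.validate()

    def validate(self) -> None:
        for ob in self.obstacles:
            sh = ob.shapely
            minx, miny, maxx, maxy = sh.bounds
            if minx < -1e-9 or miny < -1e-9 or maxx > self.width + 1e-9 or maxy > self.height + 1e-9:
                raise InvalidGeometryError("obstacle extends outside scene bounds")
            if sh.distance(self.liquid_start.shapely) < 1e-12 and sh.intersects(self.liquid_start.shapely):
                raise InvalidGeometryError("obstacle intersects the liquid start region")

    def solid_obstacles(self) -> List[Obstacle]:
        """Obstacles plus any receptacle geometry that particles collide with."""
        solids = list(self.obstacles)
        if isinstance(self.receptacle, Cup):
            solids.extend(self.receptacle.wall_polygons())
        return solids

    def total_obstacle_area(self) -> float:
        total = 0.0
        for ob in self.obstacles:
            if isinstance(ob, Circle):
                total += np.pi * ob.radius ** 2
            else:
                total += polygon_area(ob)
        return float(total)


@dataclass
class SceneSet:
    scenes: List[Scene]
    labels: List[str]

    def __post_init__(self) -> None:
        # empty sets are permitted only as the degenerate result of a
        # k = 0 selection; generators always produce non-empty sets
        if len(self.labels) != len(self.scenes):
            raise ValueError("labels must match scenes")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("SceneSet labels must be unique")

    def __len__(self) -> int:
        return len(self.scenes)

    def __iter__(self):
        return iter(zip(self.labels, self.scenes))

    @classmethod
    def from_scenes(cls, scenes: Sequence[Scene]) -> "SceneSet":
        labels = [s.label or f"scene_{i:04d}" for i, s in enumerate(scenes)]
        return cls(list(scenes), labels)


# ---------------------------------------------------------------------------
# JSON I/O


def _obstacle_to_dict(ob: Obstacle) -> dict:
    if isinstance(ob, Circle):
        return {"type": "circle", "center": [ob.center.x, ob.center.y], "radius": ob.radius}
    return {"type": "polygon", "vertices": ob.vertices.tolist()}


def _obstacle_from_dict(d: dict) -> Obstacle:
    if d["type"] == "circle":
        return Circle(Point2(*d["center"]), d["radius"])
    return Polygon(d["vertices"])


def scene_to_dict(scene: Scene) -> dict:
    if isinstance(scene.receptacle, Divider):
        rec = {"type": "divider", "x": scene.receptacle.x}
    else:
        c = scene.receptacle
        rec = {"type": "cup", "center_x": c.center_x, "width": c.width,
               "wall_height": c.wall_height, "wall_thickness": c.wall_thickness}
    return {
        "width": scene.width,
        "height": scene.height,
        "obstacles": [_obstacle_to_dict(o) for o in scene.obstacles],
        "liquid_start": {"center": [scene.liquid_start.center.x, scene.liquid_start.center.y],
                         "radius": scene.liquid_start.radius},
        "receptacle": rec,
        "seed": scene.seed,
        "provenance": scene.label,
    }


def scene_from_dict(d: dict) -> Scene:
    rec = d["receptacle"]
    if rec["type"] == "divider":
        receptacle: Receptacle = Divider(rec["x"])
    else:
        receptacle = Cup(rec["center_x"], rec["width"], rec.get("wall_height", CUP_WALL_HEIGHT),
                         rec.get("wall_thickness", CUP_WALL_THICKNESS))
    return Scene(
        width=d["width"],
        height=d["height"],
        obstacles=[_obstacle_from_dict(o) for o in d["obstacles"]],
        liquid_start=Circle(Point2(*d["liquid_start"]["center"]), d["liquid_start"]["radius"]),
        receptacle=receptacle,
        seed=d.get("seed"),
        label=d.get("provenance", ""),
    )


def save_scene(scene: Scene, path) -> None:
    Path(path).write_text(json.dumps(scene_to_dict(scene), indent=1, sort_keys=True))


def load_scene(path) -> Scene:
    return scene_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Voronoi scene generation


def _voronoi_cells(rng: np.random.Generator, n_sites: int) -> List[_ShPolygon]:
    """Clipped, inward-offset Voronoi cells inside the obstacle band."""
    sites = np.column_stack([
        rng.uniform(0.0, DEFAULT_WIDTH, n_sites),
        rng.uniform(BAND_Y_LO, BAND_Y_HI, n_sites),
    ])
    # reflect the sites across the four band edges so every interior cell is
    # finite and naturally clipped to the band
    mirrored = [sites]
    for axis, bound in ((0, 0.0), (0, DEFAULT_WIDTH), (1, BAND_Y_LO), (1, BAND_Y_HI)):
        m = sites.copy()
        m[:, axis] = 2.0 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    band = _sh_box(0.0, BAND_Y_LO, DEFAULT_WIDTH, BAND_Y_HI)
    cells: List[_ShPolygon] = []
    for i in range(n_sites):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue
        cell = _ShPolygon(vor.vertices[region]).intersection(band)
        cell = cell.buffer(-VORONOI_SHRINK, join_style=2)
        if cell.is_empty:
            continue
        if cell.geom_type == "MultiPolygon":
            cell = max(cell.geoms, key=lambda g: g.area)
        if cell.area >= MIN_CELL_AREA:
            cells.append(_sh_orient(cell, 1.0))
    return cells


def _pick_cells(rng: np.random.Generator, cells: List[_ShPolygon],
                target_area: float, tol: float) -> Optional[List[_ShPolygon]]:
    """Greedy random subset whose total area lands within tol of the target."""
    order = rng.permutation(len(cells))
    chosen: List[_ShPolygon] = []
    total = 0.0
    for idx in order:
        a = cells[idx].area
        if abs(total + a - target_area) < abs(total - target_area):
            chosen.append(cells[idx])
            total += a
    if abs(total - target_area) <= tol:
        return chosen
    return None


def generate_voronoi_scene(seed: int, n_sites: int = 25,
                           target_area: float = 0.12,
                           area_tol: float = 0.02,
                           max_retries: int = 20) -> Scene:
    """Experiment-1-style random obstacle course.

    Voronoi cells from ``n_sites`` uniform sites in the obstacle band are
    clipped to the band, shrunk inward by 0.01 m, and randomly accumulated
    until their total area is within ``area_tol`` of ``target_area``.
    Deterministic given ``seed``.
    """
    if n_sites < 4:
        raise ValueError("n_sites must be >= 4")
    if not (0.0 <= target_area < DEFAULT_WIDTH * DEFAULT_HEIGHT):
        raise ValueError("target_area out of range")
    if target_area == 0.0:
        return Scene(obstacles=[], receptacle=Divider(DEFAULT_WIDTH / 2),
                     seed=seed, label=f"voronoi_{seed}")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        cells = _voronoi_cells(rng, n_sites)
        for _ in range(10):
            chosen = _pick_cells(rng, cells, target_area, area_tol)
            if chosen is not None:
                obstacles = [Polygon(np.asarray(c.exterior.coords)[:-1]) for c in chosen]
                return Scene(obstacles=obstacles, receptacle=Divider(DEFAULT_WIDTH / 2),
                             seed=seed, label=f"voronoi_{seed}")
    raise SceneGenerationError(
        f"could not reach target_area={target_area} after {max_retries} retries")


# ---------------------------------------------------------------------------
# Shape (Experiment-2-style) scene generation

SHAPE_SIZE_RANGE = (0.12, 0.26)  # side length / diameter, meters
SHAPE_BAND_Y = (0.45, 1.10)
SHAPE_MARGIN = 0.02  # minimum clearance between obstacles


def cup_positions(width: float = DEFAULT_WIDTH, n: int = 5) -> np.ndarray:
    """The n evenly spaced cup center positions spanning valid placements.

    The cup is width/3 wide, so valid centers span [width/6, 5*width/6];
    with n = 5 this gives centers at k*width/6 for k = 1..5.
    """
    half = width / 6.0
    return np.linspace(half, width - half, n)


def _make_shape(kind: str, cx: float, cy: float, size: float) -> Obstacle:
    if kind == "circle":
        return Circle(Point2(cx, cy), size / 2)
    if kind == "square":
        s = size / 2
        return Polygon([(cx - s, cy - s), (cx + s, cy - s), (cx + s, cy + s), (cx - s, cy + s)])
    if kind == "triangle":  # equilateral, apex up
        r = size / np.sqrt(3.0)  # circumradius
        angles = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3])
        verts = np.column_stack([cx + r * np.cos(angles), cy + r * np.sin(angles)])
        return Polygon(verts)
    raise ValueError(f"unknown shape kind {kind!r}")


def generate_shape_scene(seed: int, max_retries: int = 500) -> Scene:
    """Experiment-2-style scene: 3 non-overlapping obstacles drawn from
    {equilateral triangle, square, circle} with a cup one third of the scene
    width at one of 5 evenly spaced positions.  Deterministic given seed."""
    rng = np.random.default_rng(seed)
    kinds = rng.choice(["triangle", "square", "circle"], size=3)
    cup_idx = int(rng.integers(5))
    cup = Cup(float(cup_positions()[cup_idx]), DEFAULT_WIDTH / 3.0)
    placed: List[Obstacle] = []
    for kind in kinds:
        ok = False
        for _ in range(max_retries):
            size = float(rng.uniform(*SHAPE_SIZE_RANGE))
            cx = float(rng.uniform(0.05 + size / 2, DEFAULT_WIDTH - 0.05 - size / 2))
            cy = float(rng.uniform(SHAPE_BAND_Y[0] + size / 2, SHAPE_BAND_Y[1] - size / 2))
            cand = _make_shape(kind, cx, cy, size)
            sh = cand.shapely
            if any(sh.distance(p.shapely) < SHAPE_MARGIN for p in placed):
                continue
            placed.append(cand)
            ok = True
            break
        if not ok:
            raise SceneGenerationError("could not place 3 non-overlapping obstacles")
    return Scene(obstacles=placed, receptacle=cup, seed=seed, label=f"shapes_{seed}")


def mirror_scene(scene: Scene) -> Scene:
    """Reflect the scene about its vertical midline (x = width/2), as used to
    build mirrored honey counterparts of water stimuli."""
    axis = scene.width / 2
    obstacles = [ob.mirrored_x(axis) for ob in scene.obstacles]
    if isinstance(scene.receptacle, Divider):
        rec: Receptacle = Divider(scene.width - scene.receptacle.x)
    else:
        c = scene.receptacle
        rec = Cup(scene.width - c.center_x, c.width, c.wall_height, c.wall_thickness)
    return Scene(width=scene.width, height=scene.height, obstacles=obstacles,
                 liquid_start=scene.liquid_start.mirrored_x(axis),
                 receptacle=rec, seed=scene.seed,
                 label=(scene.label + "_mirror") if scene.label else "mirror")


# ---------------------------------------------------------------------------
# Coarse-simulation filter


@dataclass(frozen=True)
class CoarseFilterParams:
    """Thresholds for the coarse-run scene filter.

    A coarse undamped simulation with few particles is run; the scene is
    rejected if too many particles end up trapped high in obstacle
    concavities, or too few ever interact with an obstacle.
    """

    n_particles: int = 15
    t_max: float = 4.0
    zeta: float = 5.0  # damped coarse run so trapped liquid settles to rest
    trap_frac: float = 0.2
    v_still: float = 0.01  # m/s: below this a particle counts as at rest
    basin_height: float = 0.2  # m: at rest above this height counts as trapped
    interact_frac: float = 0.5
    seed: int = 0


def coarse_filter(scene: Scene, filter_params: CoarseFilterParams | None = None) -> bool:
    """Accept (True) or reject (False) a scene based on a coarse simulation.

    Reject if (a) more than ``trap_frac`` of particles end at rest above the
    basin height (trapped in a concavity), or (b) fewer than
    ``interact_frac`` of particles ever contact an obstacle.
    """
    from .sph_engine import FluidParams, run_ife  # deferred: avoids import cycle

    fp = filter_params or CoarseFilterParams()
    if not scene.obstacles:
        return False  # nothing to interact with
    params = FluidParams(N=fp.n_particles, alpha=0.01, zeta=fp.zeta, sigma=0.0,
                         sticky=False, t_max=fp.t_max)
    result = run_ife(scene, params, seed=fp.seed)
    state = result.final_state
    speeds = np.hypot(state.velocities[:, 0], state.velocities[:, 1])
    trapped = (speeds < fp.v_still) & (state.positions[:, 1] > fp.basin_height)
    if trapped.mean() > fp.trap_frac:
        return False
    if result.contacts_seen.mean() < fp.interact_frac:
        return False
    return True


# ---------------------------------------------------------------------------
# Contrastive selection


def select_contrastive_scenes(candidates: SceneSet,
                              water_pred: Callable[[Scene], float],
                              honey_pred: Callable[[Scene], float],
                              k: int) -> SceneSet:
    """Pick the k scenes whose water and honey predictions differ most.

    The contrast score is |J_water - J_honey|; ties are broken by scene
    label order.  Selecting high-contrast scenes drives the water/honey
    prediction pair toward anti-correlation on the selected subset.
    """
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds candidate pool size {len(candidates)}")
    if k == 0:
        return SceneSet([], [])
    scored = []
    for label, scene in candidates:
        jw = float(water_pred(scene))
        jh = float(honey_pred(scene))
        scored.append((-abs(jw - jh), label, scene))
    scored.sort(key=lambda t: (t[0], t[1]))
    top = scored[:k]
    return SceneSet([s for _, _, s in top], [lab for _, lab, _ in top])
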