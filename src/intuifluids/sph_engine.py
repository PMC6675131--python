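"""The Intuitive Fluids Engine: weakly-compressible 2D SPH with damping,
optional stickiness and inelastic particle-obstacle collisions.

The engine models a splash prediction as a short particle simulation.  Each
particle carries position, velocity, density and pressure; densities are
kernel-weighted sums over neighbors, pressures follow a weakly-compressible
equation of state P = stiffness * (rho - rho0) (clamped at zero so free
surfaces do not generate tensile clumping), and the pair forces combine the
symmetric pressure-gradient term with Monaghan artificial viscosity scaled
by the particle-friction coefficient alpha.  Two deliberate departures from
production SPH codes reflect the cognitive-model character of the engine:

* a velocity damping term ``a = f - zeta * v`` slows the whole fluid down
  (the "mentally slowed splash" mechanism), and
* particle stickiness damps the normal and tangential velocity components
  of particles in contact with solids, producing honey-like clinging.

Particles never collide with each other here (SPH forces keep them apart);
obstacle collisions are perfectly inelastic.  Integration is naive
(semi-implicit Euler) at a fine time step, dt = 0.0002 s by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, NamedTuple, Optional

import numpy as np

from . import _core
from .geometry2d import Circle, Contact, Polygon
from .scenes import Scene

__all__ = [
    "FluidParams",
    "ParticleState",
    "SimResult",
    "NumericalInstabilityError",
    "kernel_w",
    "compute_density",
    "compute_forces",
    "apply_damping",
    "apply_stickiness",
    "resolve_obstacle_collision",
    "step",
    "run_ife",
    "initialize_particles",
    "compile_scene",
]

GRAVITY = _core.GRAVITY
V_CAP = 50.0  # m/s; beyond this the integration is declared unstable
STUCK_SPEED = 0.005  # m/s
STUCK_TIME = 0.1  # s of consecutive slow contact before a particle is "stuck"


class NumericalInstabilityError(RuntimeError):
    """A particle exceeded the speed cap; carries the simulation time."""

    def __init__(self, stage: str, time: float) -> None:
        super().__init__(f"numerical instability during {stage} at t={time:.4f} s")
        self.time = time


@dataclass(frozen=True)
class FluidParams:
    """Parameters of the fluids engine.

    N            particle count (>= 1)
    alpha        Monaghan artificial-viscosity coefficient ("particle friction")
    zeta         velocity damping rate, 1/s
    sigma        half-width of the damping-uncertainty window, 1/s
    sticky       whether contact stickiness is active (honey Model 1)
    kappa_n/t    per-step fractional damping of normal/tangential velocity
                 while in contact, in [0, 1]
    rest_density kg/m^2 (2D, per unit depth)
    stiffness    equation-of-state constant (= sound speed squared)
    dt           integration step, s
    t_max        simulated duration, s (4 s water-like, 10 s honey-like)
    mass, h, particle_radius: derived from the liquid start region when None
    """

    N: int = 50
    alpha: float = 0.01
    zeta: float = 5.0
    sigma: float = 4.0
    sticky: bool = False
    kappa_n: float = 0.9
    kappa_t: float = 0.5
    mass: Optional[float] = None
    rest_density: float = 1000.0
    h: Optional[float] = None
    stiffness: float = 400.0  # sound speed 20 m/s
    dt: float = 0.0002
    t_max: float = 4.0
    particle_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.alpha < 0 or self.zeta < 0 or self.sigma < 0:
            raise ValueError("alpha, zeta, sigma must be >= 0")
        if not (0 <= self.kappa_n <= 1 and 0 <= self.kappa_t <= 1):
            raise ValueError("stickiness coefficients must lie in [0, 1]")
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be > 0")
        if self.h is not None and self.h <= 0:
            raise ValueError("h must be > 0")

    @property
    def sound_speed(self) -> float:
        return float(np.sqrt(self.stiffness))


@dataclass
class ParticleState:
    positions: np.ndarray  # (N, 2)
    velocities: np.ndarray  # (N, 2)
    densities: np.ndarray  # (N,)
    pressures: np.ndarray  # (N,)
    stuck_flags: np.ndarray  # (N,) bool
    time: float = 0.0

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ParticleState":
        return ParticleState(self.positions.copy(), self.velocities.copy(),
                             self.densities.copy(), self.pressures.copy(),
                             self.stuck_flags.copy(), self.time)


@dataclass
class SimResult:
    final_state: ParticleState
    contacts_seen: np.ndarray  # (N,) bool: ever touched a real obstacle
    trajectory: Optional[np.ndarray] = None  # (frames, N, 2)
    trajectory_times: Optional[np.ndarray] = None
    params: Optional[FluidParams] = None
    seed: Optional[int] = None


class ResolvedGeometry(NamedTuple):
    spacing: float
    h: float
    mass: float
    particle_radius: float


class CompiledScene(NamedTuple):
    poly_verts: np.ndarray
    poly_off: np.ndarray
    poly_obst: np.ndarray
    circles: np.ndarray


# ---------------------------------------------------------------------------
# kernel and reference operations (thin wrappers over the compiled core)


def kernel_w(r, h: float):
    """Cubic-spline smoothing kernel W(r, h); zero at and beyond the cutoff h,
    normalized so the 2D disk integral is 1."""
    if h <= 0:
        raise ValueError("h must be > 0")
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.array([_core.kernel_w_scalar(float(ri), h) for ri in r_arr])
    return float(out[0]) if np.isscalar(r) or np.asarray(r).ndim == 0 else out


def compute_density(positions: np.ndarray, mass: float, h: float) -> np.ndarray:
    """rho_i = sum_j m W(r_ij, h), the sum including j = i."""
    if h <= 0 or mass <= 0:
        raise ValueError("h and mass must be > 0")
    pos = np.ascontiguousarray(positions, dtype=float)
    rho = np.empty(pos.shape[0])
    _core._density(pos, mass, h, rho)
    return rho


def _pressures(densities: np.ndarray, params: FluidParams) -> np.ndarray:
    p = params.stiffness * (densities - params.rest_density)
    return np.maximum(p, 0.0)


def compute_forces(state: ParticleState, params: FluidParams) -> np.ndarray:
    """Per-particle acceleration: gravity + pressure gradient + artificial
    viscosity.  Densities must be current for the positions."""
    n = state.n
    geo = resolve_geometry(params)
    fx = np.zeros(n)
    fy = np.zeros(n)
    _core._sph_forces(np.ascontiguousarray(state.positions),
                      np.ascontiguousarray(state.velocities),
                      state.densities, state.pressures,
                      geo.mass, geo.h, params.alpha, params.sound_speed, fx, fy)
    f = np.column_stack([fx, fy])
    if not np.all(np.isfinite(f)):
        raise NumericalInstabilityError("force computation", state.time)
    return f


def apply_damping(f: np.ndarray, v: np.ndarray, zeta: float) -> np.ndarray:
    """a = f - zeta * v: acceleration reduced by a fixed proportion of the
    current velocity, slowing the simulated liquid."""
    if zeta < 0:
        raise ValueError("zeta must be >= 0")
    return np.asarray(f, dtype=float) - zeta * np.asarray(v, dtype=float)


def apply_stickiness(v, contact: Contact, kappa_n: float, kappa_t: float) -> np.ndarray:
    """Damp the normal and tangential components of v with respect to the
    contact normal: v' = (1 - kappa_n) v_n + (1 - kappa_t) v_t."""
    n = np.asarray(contact.normal, dtype=float)
    if abs(np.hypot(*n) - 1.0) > 1e-9:
        raise ValueError("contact normal must be a unit vector")
    v = np.asarray(v, dtype=float)
    vn = float(v @ n) * n
    vt = v - vn
    return (1.0 - kappa_n) * vn + (1.0 - kappa_t) * vt


# ---------------------------------------------------------------------------
# scene compilation and particle initialization


def compile_scene(scene: Scene) -> CompiledScene:
    """Flatten scene solids into the array form consumed by the compiled core.

    Obstacles keep an 'is obstacle' flag (used for interaction bookkeeping);
    cup walls and the floor/side-wall boundary slabs are solid but unflagged.
    """
    polys: List[np.ndarray] = []
    flags: List[int] = []
    circles: List[List[float]] = []
    for ob in scene.obstacles:
        if isinstance(ob, Circle):
            circles.append([ob.center.x, ob.center.y, ob.radius])
        else:
            polys.append(ob.vertices)
            flags.append(1)
    from .scenes import Cup  # local import to avoid cycle at module load

    if isinstance(scene.receptacle, Cup):
        for wall in scene.receptacle.wall_polygons():
            polys.append(wall.vertices)
            flags.append(0)
    w, hgt = scene.width, scene.height
    pad = 0.5
    boundary = [
        np.array([(-pad, -pad), (w + pad, -pad), (w + pad, 0.0), (-pad, 0.0)]),  # floor
        np.array([(-pad, -pad), (0.0, -pad), (0.0, hgt + pad), (-pad, hgt + pad)]),  # left
        np.array([(w, -pad), (w + pad, -pad), (w + pad, hgt + pad), (w, hgt + pad)]),  # right
    ]
    for b in boundary:
        polys.append(b)
        flags.append(0)
    off = np.zeros(len(polys) + 1, dtype=np.int64)
    for i, p in enumerate(polys):
        off[i + 1] = off[i] + p.shape[0]
    verts = np.vstack(polys).astype(float) if polys else np.zeros((0, 2))
    circ = np.asarray(circles, dtype=float).reshape(-1, 3)
    return CompiledScene(np.ascontiguousarray(verts), off,
                         np.asarray(flags, dtype=np.int64), np.ascontiguousarray(circ))


def resolve_geometry(params: FluidParams,
                     liquid_radius: float = 0.074) -> ResolvedGeometry:
    """Derive lattice spacing, smoothing length, particle mass and radius.

    The spacing is chosen so N particles on a square lattice fill the liquid
    start disc; h = 1.3 * spacing; the mass is normalized so an interior
    lattice particle sits exactly at rest density (hence zero pressure at
    rest); the contact radius is spacing / 2.
    """
    R = liquid_radius
    s = np.sqrt(np.pi * R * R / params.N)
    while _lattice_count(R, s) < params.N:
        s *= 0.98
    h = params.h if params.h is not None else 1.3 * s
    if params.mass is not None:
        mass = params.mass
    else:
        ksum = 0.0
        for k in range(-3, 4):
            for l in range(-3, 4):
                ksum += _core.kernel_w_scalar(s * float(np.hypot(k, l)), h)
        mass = params.rest_density / ksum
    pr = params.particle_radius if params.particle_radius is not None else s / 2
    return ResolvedGeometry(float(s), float(h), float(mass), float(pr))


def _lattice_count(R: float, s: float) -> int:
    k = int(np.ceil(R / s))
    xs = np.arange(-k, k + 1) * s
    gx, gy = np.meshgrid(xs, xs)
    return int(np.count_nonzero(gx ** 2 + gy ** 2 <= R * R))


def initialize_particles(scene: Scene, params: FluidParams, seed: int) -> ParticleState:
    """Jittered square lattice filling the liquid start disc, at rest."""
    geo = resolve_geometry(params, scene.liquid_start.radius)
    R = scene.liquid_start.radius
    cx, cy = scene.liquid_start.center.x, scene.liquid_start.center.y
    s = geo.spacing
    k = int(np.ceil(R / s))
    xs = np.arange(-k, k + 1) * s
    gx, gy = np.meshgrid(xs, xs)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= R]
    order = np.argsort(np.hypot(pts[:, 0], pts[:, 1]), kind="stable")
    pts = pts[order[: params.N]]
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.05 * s, 0.05 * s, size=pts.shape)
    pos = pts + jitter + np.array([cx, cy])
    n = pos.shape[0]
    rho = compute_density(pos, geo.mass, geo.h)
    return ParticleState(
        positions=np.ascontiguousarray(pos),
        velocities=np.zeros((n, 2)),
        densities=rho,
        pressures=_pressures(rho, params),
        stuck_flags=np.zeros(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# stepping and full runs


def _run_compiled(state: ParticleState, scene: Scene, params: FluidParams,
                  n_steps: int, marble: bool,
                  contact_seen: np.ndarray, stuck_steps: np.ndarray,
                  traj: Optional[np.ndarray] = None,
                  record_every: int = -1) -> None:
    geo = resolve_geometry(params, scene.liquid_start.radius)
    comp = compile_scene(scene)
    rho = state.densities
    press = state.pressures
    traj_arr = traj if traj is not None else np.zeros((0, 1, 2))
    status = _core.run_engine(
        state.positions, state.velocities, n_steps, params.dt, marble,
        geo.mass, geo.h, params.rest_density, params.stiffness,
        params.alpha, params.zeta,
        params.sticky, params.kappa_n, params.kappa_t,
        geo.particle_radius, V_CAP,
        comp.poly_verts, comp.poly_off, comp.poly_obst, comp.circles,
        contact_seen, stuck_steps, rho, press,
        traj_arr, record_every)
    if status != 0:
        raise NumericalInstabilityError("integration", state.time + status * params.dt)
    state.time += n_steps * params.dt
    stuck_needed = int(round(STUCK_TIME / params.dt))
    state.stuck_flags = stuck_steps >= stuck_needed
    if not marble:
        state.pressures = _pressures(rho, params)


def step(state: ParticleState, scene: Scene, params: FluidParams) -> ParticleState:
    """One naive Euler step: density -> forces -> damping -> update ->
    collision resolution -> stickiness.  Deterministic; returns a new state."""
    new = state.copy()
    contact_seen = np.zeros(new.n, dtype=bool)
    stuck_steps = np.zeros(new.n, dtype=np.int64)
    _run_compiled(new, scene, params, 1, marble=False,
                  contact_seen=contact_seen, stuck_steps=stuck_steps)
    return new


def resolve_obstacle_collision(state: ParticleState, scene: Scene,
                               params: FluidParams) -> ParticleState:
    """Project penetrating particles to the contact surface and zero the
    inward normal velocity (perfectly inelastic); stickiness applied when
    the fluid is sticky."""
    new = state.copy()
    geo = resolve_geometry(params, scene.liquid_start.radius)
    comp = compile_scene(scene)
    contact_seen = np.zeros(new.n, dtype=bool)
    in_contact = np.zeros(new.n, dtype=bool)
    _core._resolve_obstacles(new.positions, new.velocities, geo.particle_radius,
                             params.sticky, params.kappa_n, params.kappa_t,
                             comp.poly_verts, comp.poly_off, comp.poly_obst,
                             comp.circles, contact_seen, in_contact)
    return new


def run_ife(scene: Scene, params: FluidParams, seed: int = 0,
            record_every: Optional[int] = None, marble: bool = False) -> SimResult:
    """Full Intuitive-Fluids-Engine run: jittered-lattice initialization
    (seeded), integration to t_max, contact bookkeeping.

    ``marble=True`` switches the pair interaction to rigid sphere-sphere
    collisions (used by the MarbleSim front end); everything else —
    initialization, gravity, damping, obstacle collisions, integrator —
    is shared.
    """
    state = initialize_particles(scene, params, seed)
    n_steps = int(round(params.t_max / params.dt))
    contact_seen = np.zeros(state.n, dtype=bool)
    stuck_steps = np.zeros(state.n, dtype=np.int64)
    traj = None
    times = None
    if record_every is not None:
        n_frames = n_steps // record_every
        traj = np.zeros((n_frames, state.n, 2))
        times = (np.arange(1, n_frames + 1) * record_every) * params.dt
    _run_compiled(state, scene, params, n_steps, marble,
                  contact_seen, stuck_steps, traj,
                  record_every if record_every is not None else -1)
    return SimResult(final_state=state, contacts_seen=contact_seen,
                     trajectory=traj, trajectory_times=times,
                     params=params, seed=seed)
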