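"""MarbleSim: the fluid as a handful of rigid marbles.

Identical to the fluids engine in initialization, gravity, damping,
integrator and particle-obstacle handling (the compiled code path is
literally shared), but SPH pair forces are replaced by perfectly inelastic
rigid sphere-sphere collisions: overlapping pairs are separated
symmetrically along the center line and the approaching relative normal
velocity is zeroed, conserving pair momentum.  Stickiness and the
viscosity coefficient alpha are meaningless here and ignored; sphere
friction is intentionally omitted (it has negligible effect at this scale).
"""

from __future__ import annotations

import numpy as np

from . import _core
from .scenes import Scene
from .sph_engine import FluidParams, ParticleState, SimResult, run_ife

__all__ = ["resolve_sphere_collisions", "run_marblesim", "marble_params"]


def marble_params(N: int = 25, zeta: float = 2.0, sigma: float = 4.0,
                  dt: float = 0.0002, t_max: float = 4.0,
                  particle_radius=None) -> FluidParams:
    """MarbleSim uses the restricted parameter set {N, zeta, sigma, dt,
    t_max, particle_radius}; SPH-only fields are pinned to inert values."""
    return FluidParams(N=N, alpha=0.0, zeta=zeta, sigma=sigma, sticky=False,
                       dt=dt, t_max=t_max, particle_radius=particle_radius)


def resolve_sphere_collisions(state: ParticleState,
                              particle_radius: float,
                              n_sweeps: int = 4) -> ParticleState:
    """Resolve every overlapping sphere pair inelastically (new state).

    Symmetric positional separation along the center line; the approaching
    relative normal velocity is zeroed by giving both particles the mean
    normal velocity (equal masses), leaving tangential components unchanged.
    """
    new = state.copy()
    _core._marble_pairs(new.positions, new.velocities, particle_radius, n_sweeps)
    return new


def run_marblesim(scene: Scene, params: FluidParams, seed: int = 0,
                  record_every=None) -> SimResult:
    """Full MarbleSim run; same contract as ``run_ife``."""
    return run_ife(scene, params, seed=seed, record_every=record_every, marble=True)
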