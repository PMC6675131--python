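"""Named parameter regimes for every engine (the standard model zoo).

Particle-engine presets (N, alpha, zeta, sigma, stickiness) and the
SimpleSim presets (g, m, sigma_m) follow the standard summary table; the
honey-viscosity coefficient is reported inconsistently across experiment
descriptions, so both values are exposed as distinct presets rather than
asserting one canonical assignment.  Honey-like liquids simulate 10 s,
water-like 4 s, matching the stimulus durations.
"""

from __future__ import annotations

from .marble_sim import marble_params
from .simple_sim import HeuristicParams
from .sph_engine import FluidParams

__all__ = ["FLUID_PRESETS", "SIMPLESIM_PRESETS", "fluid_preset", "simplesim_preset"]

_STICKY = dict(sticky=True, kappa_n=0.9, kappa_t=0.5)

FLUID_PRESETS = {
    # engine, params
    "water-ife": ("ife", FluidParams(N=50, alpha=0.01, zeta=5, sigma=4, t_max=4.0)),
    "honey1-ife": ("ife", FluidParams(N=50, alpha=1.25, zeta=5, sigma=4,
                                      t_max=10.0, **_STICKY)),
    "honey1-ife-exp2": ("ife", FluidParams(N=50, alpha=2.0, zeta=5, sigma=4,
                                           t_max=10.0, **_STICKY)),
    # Model 2 honey: the water fluid with high damping
    "honey2-ife": ("ife", FluidParams(N=50, alpha=0.01, zeta=11, sigma=4, t_max=10.0)),
    # table variant of Model 2 (honey viscosity, still non-sticky)
    "honey2-ife-table": ("ife", FluidParams(N=50, alpha=1.25, zeta=11, sigma=4,
                                            t_max=10.0)),
    "water-marble": ("marble", marble_params(N=25, zeta=2, sigma=4, t_max=4.0)),
    "honey-marble": ("marble", marble_params(N=75, zeta=6, sigma=4, t_max=10.0)),
    "ground-truth-water": ("ife", FluidParams(N=200, alpha=0.01, zeta=0, sigma=0,
                                              t_max=4.0)),
    "ground-truth-honey": ("ife", FluidParams(N=100, alpha=1.25, zeta=0, sigma=0,
                                              t_max=10.0, **_STICKY)),
}

SIMPLESIM_PRESETS = {
    "water-simplesim": HeuristicParams(g=0.1, m=0.1, sigma_m=0.04),
    "honey-simplesim": HeuristicParams(g=0.0, m=0.04, sigma_m=0.04),
    "gravity": HeuristicParams(g=0.0, m=0.0, sigma_m=0.0),
}


def fluid_preset(name: str):
    """(engine, FluidParams) for a named particle-engine preset."""
    try:
        return FLUID_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(FLUID_PRESETS)}")


def simplesim_preset(name: str) -> HeuristicParams:
    try:
        return SIMPLESIM_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(SIMPLESIM_PRESETS)}")
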