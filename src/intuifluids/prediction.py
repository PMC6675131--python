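"""Judgment extraction, damping-uncertainty averaging and parameter sweeps.

A model's prediction for a scene is a single judgment J in [0, 1]:
J = n_right / N for divider scenes, or the fraction of particles inside
the cup for cup scenes.  Probabilistic ("uncertain") engines average the
deterministic J over a window of damping values [zeta - sigma, zeta +
sigma] on the standard grid of spacing 1.0 (21 values from 0 to 20); the
SimpleSim analogue matches the relative window width via
sigma_m / (m_max - m_min) = sigma / (zeta_max - zeta_min).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Callable, Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .scenes import Cup, Divider, Scene, SceneSet
from .sph_engine import FluidParams, SimResult, run_ife
from .marble_sim import run_marblesim

__all__ = [
    "Judgment",
    "ParamGrid",
    "compute_judgment",
    "zeta_grid",
    "uncertain_predict",
    "sigma_m_from_sigma",
    "sweep",
    "deterministic_engine_J",
    "ZETA_MIN",
    "ZETA_MAX",
    "ZETA_SPACING",
]

ZETA_MIN, ZETA_MAX, ZETA_SPACING = 0.0, 20.0, 1.0


@dataclass(frozen=True)
class Judgment:
    J: float
    engine: str = ""
    params_digest: str = ""
    scene_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.J <= 1.0:
            raise ValueError("J must lie in [0, 1]")

    def __float__(self) -> float:
        return self.J


@dataclass(frozen=True)
class ParamGrid:
    """Cartesian grid of parameter values, one sorted axis per name."""

    axes: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, vals in self.axes.items():
            v = np.asarray(vals, dtype=float)
            if v.ndim != 1 or not np.all(np.diff(v) > 0):
                raise ValueError(f"axis {name!r} must be 1D with ascending values")

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self.axes.values()]))

    def points(self) -> Iterable[Dict[str, float]]:
        names = list(self.axes)
        for combo in product(*(self.axes[n] for n in names)):
            yield dict(zip(names, (float(c) for c in combo)))


def zeta_grid(zmin: float = ZETA_MIN, zmax: float = ZETA_MAX,
              spacing: float = ZETA_SPACING) -> np.ndarray:
    """Inclusive arithmetic damping grid; the standard 0..20 at spacing 1.0
    has 21 values."""
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if zmax < zmin:
        raise ValueError("zmax must be >= zmin")
    n = int(round((zmax - zmin) / spacing))
    return zmin + spacing * np.arange(n + 1)


def sigma_m_from_sigma(sigma: float, m_range: float = 0.2,
                       zeta_range: float = 20.0) -> float:
    """SimpleSim uncertainty half-width matched proportionally to the
    damping uncertainty: sigma_m / m_range = sigma / zeta_range."""
    if zeta_range <= 0:
        raise ValueError("zeta_range must be > 0")
    return sigma * m_range / zeta_range


def compute_judgment(result: SimResult, scene: Scene) -> Judgment:
    """J from a finished simulation: fraction of particles right of the
    divider, or inside the cup interior.  Particles stuck on obstacles are
    simply not in the counted region."""
    pos = result.final_state.positions
    n = pos.shape[0]
    rec = scene.receptacle
    if isinstance(rec, Divider):
        j = float(np.count_nonzero(pos[:, 0] > rec.x)) / n
    elif isinstance(rec, Cup):
        inside = [rec.contains(float(x), float(y)) for x, y in pos]
        j = float(np.count_nonzero(inside)) / n
    else:  # pragma: no cover
        raise TypeError(f"unknown receptacle {type(rec)!r}")
    return Judgment(J=j, engine="particle", scene_label=scene.label)


_ENGINES: Dict[str, Callable] = {"ife": run_ife, "marble": run_marblesim}


def deterministic_engine_J(engine: str, scene: Scene, params: FluidParams,
                           zeta: float, seed: int = 0) -> float:
    """One deterministic run of a particle engine at a given damping."""
    runner = _ENGINES[engine]
    result = runner(scene, replace(params, zeta=zeta, sigma=0.0), seed=seed)
    return compute_judgment(result, scene).J


def uncertain_predict(engine: str, scene: Scene, params: FluidParams,
                      zeta: float, sigma: float, seed: int = 0,
                      cache: Optional[Dict] = None) -> Judgment:
    """Mean of deterministic judgments over the zeta grid points in
    [zeta - sigma, zeta + sigma], clipped to the explored range [0, 20].

    sigma = 0 reduces exactly to the single deterministic run.  The same
    simulation seed is shared across the window, so nearby windows reuse
    cached runs (pass a dict as ``cache`` keyed by (scene label, zeta))."""
    lo = max(ZETA_MIN, zeta - sigma)
    hi = min(ZETA_MAX, zeta + sigma)
    if hi < lo:
        raise ValueError("empty damping window")
    zs = zeta_grid(lo, hi, ZETA_SPACING) if hi > lo else np.array([lo])
    js = []
    for z in zs:
        key = (scene.label, engine, float(z), seed)
        if cache is not None and key in cache:
            js.append(cache[key])
            continue
        j = deterministic_engine_J(engine, scene, params, float(z), seed)
        if cache is not None:
            cache[key] = j
        js.append(j)
    return Judgment(J=float(np.mean(js)), engine=engine, scene_label=scene.label,
                    params_digest=f"zeta={zeta},sigma={sigma},N={params.N}")


def sweep(engine: str, scene_set: SceneSet, grid: ParamGrid,
          params: Optional[FluidParams] = None, seed: int = 0,
          predictor: Optional[Callable] = None) -> pd.DataFrame:
    """One judgment per (scene, grid point), as a tidy DataFrame.

    For the particle engines the grid axes override FluidParams fields
    ("zeta", "N", "alpha"); a custom ``predictor(scene, point, seed)`` may
    be supplied instead (used for SimpleSim's 11 x 11 g/m grid).
    Individual cell failures are flagged in the ``ok`` column, not fatal.
    Deterministic per cell given the seed.
    """
    params = params or FluidParams()
    rows = []
    for label, scene in scene_set:
        for point in grid.points():
            row = {"scene_label": label, "engine": engine, "seed": seed, **point}
            try:
                if predictor is not None:
                    row["J"] = float(predictor(scene, point, seed))
                else:
                    p = params
                    for k, v in point.items():
                        if k == "N":
                            p = replace(p, N=int(v))
                        elif hasattr(p, k):
                            p = replace(p, **{k: v})
                    zeta = point.get("zeta", p.zeta)
                    row["J"] = deterministic_engine_J(engine, scene, p, zeta, seed)
                row["ok"] = True
            except Exception as exc:  # noqa: BLE001 — cell failures are data
                row["J"] = np.nan
                row["ok"] = False
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
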