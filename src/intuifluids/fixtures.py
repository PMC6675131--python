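"""Synthetic response data and hand-built deterministic test scenes.

No human judgment dataset ships with the package; ``synth_responses``
emulates the structure of such data — judgments in [0, 1] clustered
around a generating model's per-scene prediction with beta-distributed
noise, plus an optional uniform lapse.  The beta is parameterized by mean
and precision (a = mu*nu, b = (1-mu)*nu), the minimal family consistent
with the marginal-beta null model used in evaluation.

``toy_scene`` returns small scenes whose gravity-heuristic outcome is
known analytically; they anchor the geometric tracer and the filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ResponseSet
from .geometry2d import Circle, Point2, Polygon
from .scenes import Cup, Divider, Scene, cup_positions

__all__ = ["SynthConfig", "synth_responses", "toy_scene", "TOY_SCENE_NAMES"]

TOY_SCENE_NAMES = ("empty", "ramp_left", "ramp_right", "funnel_right", "ledge",
                   "pocket_trap", "wedge_center", "cup_center", "cup_offset")


@dataclass(frozen=True)
class SynthConfig:
    n_participants: int = 20
    concentration: float = 20.0  # beta precision nu = a + b
    lapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if self.n_participants < 1:
            raise ValueError("need >= 1 participant")


def synth_responses(generating_J, cfg: SynthConfig,
                    scene_labels=None) -> ResponseSet:
    """Responses ~ Beta(mu*nu, (1-mu)*nu) around the generating judgments
    (means clamped to [0.02, 0.98] so the beta stays proper), each replaced
    by Uniform(0, 1) with probability ``lapse_rate``.  Deterministic given
    the config seed."""
    j = np.asarray(generating_J, dtype=float)
    if np.any(j < 0) or np.any(j > 1):
        raise ValueError("generating judgments must lie in [0, 1]")
    mu = np.clip(j, 0.02, 0.98)
    nu = cfg.concentration
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_participants, len(j))
    resp = rng.beta(mu * nu, (1.0 - mu) * nu, size=shape)
    if cfg.lapse_rate > 0:
        lapse = rng.random(shape) < cfg.lapse_rate
        resp = np.where(lapse, rng.random(shape), resp)
    labels = list(scene_labels) if scene_labels is not None else [
        f"scene_{i:04d}" for i in range(len(j))]
    pids = [f"synth_{i:03d}" for i in range(cfg.n_participants)]
    return ResponseSet(resp, labels, pids)


def _plank(x0, y0, x1, y1, thickness=0.03) -> Polygon:
    """Quadrilateral plank whose top edge runs (x0, y0) -> (x1, y1)."""
    return Polygon([(x0, y0 - thickness), (x1, y1 - thickness), (x1, y1), (x0, y0)]
                   if x0 < x1 else
                   [(x1, y1 - thickness), (x0, y0 - thickness), (x0, y0), (x1, y1)])


def toy_scene(name: str) -> Scene:
    """Deterministic hand-built scenes with analytically known
    gravity-heuristic outcomes (liquid starts centered at x = 0.5):

    empty        no obstacles, divider at 0.5               -> J = 0.5
    ramp_left    plank tilted down-left under the liquid    -> J = 0.0
    ramp_right   plank tilted down-right under the liquid   -> J = 1.0
    funnel_right two planks funnelling all paths right      -> J = 1.0
    ledge        plank descending right, right edge x=0.6   -> J = 1.0
    pocket_trap  open-top box directly under the liquid (traps slow fluid)
    wedge_center triangle apex-up centered on the midline   -> J = 0.5
    cup_center   cup centered: all straight drops enter     -> J = 1.0
    cup_offset   cup at the far left: nothing enters        -> J = 0.0
    """
    if name == "empty":
        return Scene(obstacles=[], receptacle=Divider(0.5), label="toy_empty")
    if name == "ramp_left":
        return Scene(obstacles=[_plank(0.2, 0.9, 0.8, 1.05)],
                     receptacle=Divider(0.5), label="toy_ramp_left")
    if name == "ramp_right":
        return Scene(obstacles=[_plank(0.3, 1.05, 0.8, 0.9)],
                     receptacle=Divider(0.5), label="toy_ramp_right")
    if name == "funnel_right":
        return Scene(obstacles=[_plank(0.1, 1.1, 0.62, 0.85),
                                _plank(0.68, 0.9, 0.95, 1.05)],
                     receptacle=Divider(0.5), label="toy_funnel_right")
    if name == "ledge":
        return Scene(obstacles=[_plank(0.3, 1.0, 0.6, 0.9)],
                     receptacle=Divider(0.5), label="toy_ledge")
    if name == "pocket_trap":
        # open-top box spanning the liquid footprint: U-shaped solid
        outline = [(0.33, 0.60), (0.67, 0.60), (0.67, 0.95), (0.62, 0.95),
                   (0.62, 0.65), (0.38, 0.65), (0.38, 0.95), (0.33, 0.95)]
        return Scene(obstacles=[Polygon(outline)], receptacle=Divider(0.5),
                     label="toy_pocket_trap")
    if name == "wedge_center":
        return Scene(obstacles=[Polygon([(0.3, 0.7), (0.7, 0.7), (0.5, 0.95)])],
                     receptacle=Divider(0.5), label="toy_wedge_center")
    if name == "cup_center":
        return Scene(obstacles=[], receptacle=Cup(float(cup_positions()[2]), 1.0 / 3),
                     label="toy_cup_center")
    if name == "cup_offset":
        return Scene(obstacles=[], receptacle=Cup(float(cup_positions()[0]), 1.0 / 3),
                     label="toy_cup_offset")
    raise ValueError(f"unknown toy scene {name!r}; choose from {TOY_SCENE_NAMES}")
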