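# intuifluids

Approximate particle-based models of how people predict liquid flow through
2D obstacle courses.

People are remarkably good at glancing at a scene — a blob of water about to
fall through a jumble of solid obstacles — and predicting roughly where it
will end up.  One prominent account holds that the brain runs a coarse,
game-engine-style simulation.  `intuifluids` implements a full model zoo for
this judgment task, together with the scene generators and the statistics
needed to compare models against judgment data:

* **Intuitive Fluids Engine (IFE)** — weakly-compressible smoothed-particle
  hydrodynamics (SPH) in 2D: density ρᵢ = Σⱼ m·W(rᵢⱼ, h), pressure
  P = c²(ρ − ρ₀), Monaghan artificial viscosity α, plus two cognitively
  motivated mechanisms: velocity damping (a = f − ζ·v, a "mentally slowed"
  splash) and contact stickiness for honey-like liquids.
* **MarbleSim** — the same scene, gravity, damping and obstacle handling, but
  rigid inelastic sphere–sphere collisions instead of SPH forces.
* **SimpleSim** — a heuristic path tracer: particles fall straight down and
  follow obstacle surfaces downhill, with a wrong-direction noise probability
  g and a horizontal "momentum" carry-over m.
* **Gravity heuristic** — SimpleSim with g = 0, m = 0: pure geometry.

All models report a judgment J ∈ [0, 1]: the fraction of liquid ending right
of a divider, or inside a cup.  Probabilistic variants average deterministic
predictions over a damping window [ζ − σ, ζ + σ] (SimpleSim analogously over
m, with σₘ/(m_max − m_min) = σ/(ζ_max − ζ_min)).

The package also provides the two random stimulus generators (Voronoi
obstacle courses with a 0.12 m² solid-area target and a coarse-simulation
filter; three-shape scenes with a cup at one of five positions and
contrastive water/honey selection), synthetic response matrices, and the
evaluation statistics: Pearson correlations with bootstrap CIs, split-half
reliability, a beta-distribution null with a two-sample KS test, and the
damping-window prediction variance.

See `docs/methods.md` for the model details and every numerical choice.

## Worked example

```python
from intuifluids import (generate_voronoi_scene, FluidParams, run_ife,
                         compute_judgment, uncertain_predict,
                         gravity_heuristic, predict_simplesim, HeuristicParams)

scene = generate_voronoi_scene(seed=1)          # divider task, 4 obstacles
print(scene.total_obstacle_area())              # 0.117  (target 0.12 m^2)

params = FluidParams(N=50, alpha=0.01, zeta=5, sigma=4)   # water preset
res = run_ife(scene, params, seed=0)
print(compute_judgment(res, scene).J)           # 0.6  -> 60% of the water
                                                #         ends right of the divider

j = uncertain_predict("ife", scene, params, zeta=5, sigma=4, seed=0)
print(j.J)                                      # 0.6  (mean over zeta in 1..9)

print(gravity_heuristic(scene))                 # 1.0  straight-down geometry
print(predict_simplesim(scene,                  # 0.1778  heuristic water
      HeuristicParams(g=0.1, m=0.1, sigma_m=0.04, seed=0)))
```

The spread across models on the same scene (0.6 vs 1.0 vs 0.18) is exactly
what the contrastive scene selection exploits when separating model classes.

A thin CLI mirrors the library: `intuifluids gen-scenes`, `simulate`,
`predict`, `evaluate`, `fixtures` (see `--help` on each).

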