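# Methods

`intuifluids` implements a zoo of approximate models for a single psychophysical
judgment: a volume of liquid is released near the top of a 2D scene (1.0 m wide,
1.50 m tall), falls under gravity through rigid obstacles, and the model reports
J ∈ [0, 1] — the fraction of liquid ending right of a bottom divider, or inside a
cup.  This note records the models, their assumptions, and every numerical choice
that the underlying description of the modelling approach leaves open.

## The Intuitive Fluids Engine (SPH)

The fluid is N particles (default 50) with position, velocity, density and
pressure, integrated with a naive semi-implicit Euler scheme at dt = 0.0002 s for
t_max = 4 s (water-like) or 10 s (honey-like), matching the durations over which
the judged outcomes settle.

* **Kernel.** Cubic spline with compact support radius h (W = 0 for r ≥ h),
  normalized so the 2D disk integral is exactly 1.  Density is
  ρᵢ = Σⱼ m·W(rᵢⱼ, h), the sum including j = i.
* **Equation of state.** Weakly compressible, P = c²(ρ − ρ₀) with ρ₀ = 1000
  (per-unit-depth interpretation of water density) and sound speed c = 20 m/s,
  roughly ten times the flow speeds reached by the damped fluids in these scenes.
  Pressures are clamped at zero: without the clamp, free-surface particles sit
  below rest density and the resulting tensile forces produce unphysical
  clumping.  The clamp also makes a single particle force-free, which is what
  yields the exact N = 1 equivalence with MarbleSim.
* **Pair forces.** Symmetric pressure-gradient term m(Pᵢ/ρᵢ² + Pⱼ/ρⱼ²)∇W plus
  Monaghan artificial viscosity scaled by the particle-friction coefficient α,
  active only for approaching pairs, with the standard ε = 0.01 h² regularizer.
  Pair forces are antisymmetric, so total momentum is conserved up to gravity,
  damping and collisions.
* **Derived geometry.** The lattice spacing s is chosen so N particles fill the
  liquid start disc (diameter 0.148 m); h = 1.3 s; the particle contact radius
  is s/2.  Particle mass is normalized so an *interior lattice particle sits
  exactly at rest density* (m = ρ₀ / Σ W over lattice neighbors).  Mass only
  sets the scale of the fluid, and this choice makes a resting lattice an exact
  pressure equilibrium, which stabilizes initialization.
* **Damping.** a = f − ζ·v.  The verbal description of this mechanism is
  "acceleration decreased by a fixed proportion of the current velocity" and the
  resulting liquid "falls more slowly", which fixes the sign as subtraction even
  though the compact equation is sometimes printed with a plus.  Free fall then
  obeys dv/dt = −g − ζv with terminal speed g/ζ (the closed form used in tests).
* **Stickiness.** For sticky (Model-1 honey) fluids, a particle in contact with
  a solid has its normal and tangential velocity components damped per step:
  v′ = (1 − κₙ)vₙ + (1 − κₜ)vₜ, defaults κₙ = 0.9, κₜ = 0.5.  The magnitudes were
  never published (they were chosen by hand a priori); these defaults make
  contacting honey particles stop within a few milliseconds and produce the
  intended clinging layers on ledges.  Stickiness applies to every solid
  (obstacles, cup, floor): honey clings to all of them.
* **Collisions.** Particle-obstacle collisions are perfectly inelastic:
  penetrating particles are projected to the surface and the inward normal
  velocity is zeroed; tangential velocity is retained.  SPH particles never
  collide with each other.  A particle is flagged *stuck* after 0.1 s of
  consecutive obstacle contact at speed < 0.005 m/s.  Any speed above 50 m/s
  raises a numerical-instability error with the simulation time.
* **Initialization.** Jittered square lattice filling the start disc (jitter
  uniform within ±5% of the spacing, seeded); this is the only randomness in
  the particle engines.

The compiled inner loop (numba) is shared between the SPH engine and MarbleSim,
so the particle-obstacle code path is identical in both by construction.

## MarbleSim

Same initialization, gravity, damping, integrator and obstacle handling; SPH
pair forces are replaced by perfectly inelastic rigid sphere-sphere collisions
(symmetric positional separation, approaching relative normal velocity zeroed).
Collision resolution order is unspecified in the source description; we sweep
all pairs in index order 4 times per step, which gives stable stacking at this
scale.  Sphere friction is intentionally omitted (reported to have very little
effect), and stickiness makes no physical sense for marbles.

## SimpleSim and the gravity heuristic

A purely geometric tracer: 100 particles start equally spaced along the midline
of the liquid disc and fall straight down; on hitting an obstacle they follow
the surface along the local downhill gradient until they can fall again.  Two
parameters: g ∈ [0, 1], the probability of initially traveling *against*
gravity at the first collision with each obstacle; and m ∈ [0, 0.2] m, the
horizontal distance carried past an obstacle edge before dropping.  Open
details resolved here:

* Horizontal edges have no downhill direction: ties break toward the endpoint
  nearer the contact point; an exact midpoint goes right.
* The against-gravity branch traverses to the far silhouette: it ascends until
  the boundary turns downward, then descends by the ordinary hugging rule.
* A particle departs a vertex only if the next edge does not strictly descend;
  a descending edge (including vertical) is hugged.  This is exact for convex
  obstacles (all generated obstacles are convex); on hand-built non-convex
  solids the path may shortcut a concavity.
* The momentum run is clipped at the first obstacle boundary or scene wall.
* Noise decisions are made once per obstacle on first contact; cup walls do not
  consume noise decisions.
* A terminal point exactly on the divider counts as left.
* Uncertainty over m averages deterministic predictions over 9 evenly spaced
  m values in [m − σₘ, m + σₘ] clipped to [0, 0.2] (mirroring the 9-point
  damping window at spacing 1), with the same seed shared across the window.

The gravity heuristic is SimpleSim with g = 0 and m = 0 — deterministic and
identical for every liquid.

## Judgment and uncertainty

J = n_right/N for divider scenes (final x strictly greater than the divider);
for cup scenes, the fraction of particles inside the cup interior (between the
inner wall faces, below the wall tops).  Stuck particles count toward neither
region.  The probabilistic engines average deterministic J over the damping
window [ζ − σ, ζ + σ] on the grid of spacing 1.0, clipped to the explored range
[0, 20]; σ = 0 reduces exactly to one deterministic run.  The same simulation
seed is shared across a window so neighboring windows can reuse cached runs.

## Scene generation

* **Voronoi (divider) scenes.** 25 uniform sites in the obstacle band
  0.25 ≤ y ≤ 1.15 (keeping the top clear for the liquid and the bottom for the
  basins); sites are reflected across the band edges so all interior cells are
  finite and clipped to the band; each cell is shrunk inward by 0.01 m so
  channels exist between obstacles; slivers under 0.004 m² are discarded.  A
  random greedy subset accumulates cells while the running total moves closer
  to the 0.12 m² area target; subsets landing outside ±0.02 m² are re-drawn.
  Scene site count and band extent were never published; these defaults
  reproduce the "obstacle course" topology with passable gaps.
* **Coarse filter.** A coarse damped run (N = 15 — the stated floor below
  which the particle fluid stops being meaningful — ζ = 5, 4 s; damping makes
  trapped liquid settle to rest instead of sloshing forever) rejects scenes where
  more than 20% of particles end at rest (speed < 0.01 m/s) above the basin
  height 0.2 m (trapped in a concavity), or where fewer than half the particles
  ever touch an obstacle.
* **Shape (cup) scenes.** Exactly 3 obstacles from {equilateral triangle,
  square, circle}, sizes 0.12–0.26 m, centers in 0.45 ≤ y ≤ 1.10, pairwise
  clearance ≥ 0.02 m; shapes are upright and unrotated.  The cup is width/3
  wide at one of 5 evenly spaced centers k·width/6 (k = 1..5), built as a
  U of three rectangles (wall thickness 0.02 m, height 0.2 m, open top) — the
  minimal container consistent with the stimulus pictures.  A mirror transform
  reflects a scene about the vertical midline to build matched stimulus pairs.
* **Contrastive selection** scores each candidate by |J_water − J_honey| and
  keeps the top k (ties by label); no formula for "anti-correlated selection"
  was published, and this contrast score demonstrably drives the selected
  subset's water/honey correlation below the pool's.

## Evaluation statistics

Pearson r with a 95% percentile bootstrap CI over paired scene resamples
(default 10,000); split-half reliability averaged over 100 random participant
halvings (⌊P/2⌋/⌈P/2⌉ for odd P, no Spearman-Brown correction); a beta null fit
by method of moments to pooled responses clipped to (0.001, 0.999), compared to
real per-participant correlations by a two-sample Kolmogorov-Smirnov test; and
the damping-window prediction variance, computed as the *population* variance
of deterministic J over the window, averaged across scenes with a bootstrap CI.
Whether the original split-half used one or many splits, and whether the
variance was population or sample, is unstated; the choices here are fixed and
documented.  No multiple-testing correction is applied anywhere.

## Synthetic responses

No human dataset ships with the package.  `fixtures.synth_responses` emulates a
response matrix: participant responses are Beta(μν, (1−μ)ν) draws around a
generating model's per-scene judgment (mean clamped to [0.02, 0.98], precision
ν = 20 by default — individual judgments scatter ±≈10 percentage points around
the scene mean, a plausible slider noise level), with an optional uniform lapse.
This matches the marginal-beta family of the null model, so structure detection
and parameter-recovery tests are non-circular: the null captures the variance
but not the scene-specific signal.  Synthetic data lack everything else real
participants do — sequential effects, anchoring, individual biases — so passing
recovery tests shows the *pipeline* distinguishes the model classes, not that
people behave like any of them.

## Problem sizes and limitations

Headline checks use desk-scale sizes chosen for a laptop-class machine: 50
scenes for the area target; 15 filtered scenes × 9 damping values × 4 s
simulations for the damping-window variance (the damping-window variance
reproduces ≈0.003 at this scale); property suites use N ≤ 100 particles.
Known limitations: strictly 2D (the original stimuli were rendered with a
shallow depth dimension); no incompressible pressure solver, leap-frog
integrator or surface rendering; honey's α is reported inconsistently between
experiment descriptions (1.25 vs 2.0), so both ship as presets with no
canonical assignment; the headline human-model correlations are not
reproducible because the human data were never published.
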