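# Methods

## Model overview

The package treats intracellular subdiffusion as the composition of two
independent mechanisms:

* **Spatial crowding.** The molecule walks on a generalized Sierpinski
  carpet (GSC): the self-similar set obtained by iterating a ν×ν (or
  ν×ν×ν) generator mask that deletes at most half of its cells. Obstructed
  space slows the walk to `⟨r²⟩ ∝ t^α` with α < 1; for the standard 3×3
  carpet the simulations here measure α ≈ 0.94.
* **Temporal heterogeneity.** Before each step the molecule waits a random
  time drawn from the inverse-gamma density
  `ψ(t) = e^{−1/t}·t^{−(1+γ)}/Γ(γ)`, 0 < γ ≤ 1. The first moment is
  infinite, so the central limit theorem does not apply: the number of
  completed steps grows as `t^γ`, ensemble MSDs scale as `t^γ`, and
  ergodicity is broken on all time scales — time-averaged MSD amplitudes
  per track remain random no matter how long the measurement.

When both act, the exponents decouple: `γ̃ = α·γ`. The *limited* CTRW adds
two experimental constraints: a geometric displacement cap `r_max` (the
cell or nucleus size — proposed steps beyond the cap are rejected, so the
MSD plateaus at ≤ r_max²), and the single-molecule occupancy condition
N < 1 for the observation volume, enforced as a configuration error.

## Fractal supports

Supports are virtual: a site's accessibility is decided on demand by
stage-wise coarse-graining. A point belongs to stage k when its largest
coordinate lies in [ν^(k−1), ν^k); from that stage downward the coarse cell
`⌊x/ν^(k−1)⌋` must be allowed and the remainder `x mod ν^(k−1)` is carried
to the next stage. Coordinates are 0-based and the stage interval is
half-open, which makes the rule exact integer arithmetic. The number of
accessible sites in [0, ν^k)^dim equals (allowed cells)^k whenever the
origin cell is allowed (shipped masks guarantee this); the test suite
checks this count and the equivalent digit-by-digit oracle exhaustively at
small k. The bounding box blocks like a deleted cell (blind-ant
semantics); supports are never materialized beyond the test enumerations.

## Walkers

All walkers are blind ants on the unit lattice (ℓ₀ = 1): a uniformly
random neighbor is proposed each tick and rejected proposals consume the
tick (and, for CTRWs, the waiting time). Waiting times are sampled as
reciprocals of Gamma(γ, 1) draws; the waiting-time law is a pluggable
interface (a degenerate fixed-step law is included, recovering the plain
walk). The waiting-time scale defaults to one simulation time unit;
physical calibration is the caller's concern.

Two implementations exist: per-trajectory loops (the reference) and
lock-step vectorized ensembles used for exponent estimation; a test
compares their statistics. Ensemble walkers can start from uniformly
random accessible sites (rejection sampling), which is the natural
translation-averaged ensemble for measuring exponents on a fractal — a
corner start sits on the carpet's unobstructed outer edge and biases α
upward.

## MSD estimation and study conditions

Trajectories are right-continuous step functions (the molecule sits on the
last visited site between events). The time-averaged MSD at lag Δ averages
`|r(t+Δ)−r(t)|²` over evenly spaced origins in [0, T−Δ]; the ensemble MSD
averages `|r(t)−r(0)|²` over tracks. Scaling exponents are ordinary least
squares of log MSD on log t; the default fit window discards the first and
last half-decade of abscissa, where transients and poor statistics bias
the slope. The step-count decomposition `⟨r²(t)⟩ = Σ_n r̄²_n·χ̂_n(t)` uses
the empirical fraction χ̂_n(t) of tracks with exactly n completed steps by
time t (an analytic Laplace inversion of χ_n is out of scope).

Simulation sizes used by the tests and chosen once as the study
conditions: 500 walkers; 10⁴ ticks for constant-time walks fitted on
[10, 10⁴]; 3000 steps for CTRWs, whose event times then span ≳ 10⁶ time
units, fitted on [10², 10⁶] where the asymptotic power law dominates
(short-time CTRW corrections bias the slope upward by ≈ +0.05 in a
[10, 10⁴] window). Exponent standard errors come from refitting ten
disjoint track groups. Under these conditions: α = 0.94 ± 0.01 on the
stage-6 carpet (CI excludes 1), γ̂ = 0.51 ± 0.01 for γ = 0.5 on the free
lattice, and the carpet CTRW exponent agrees with α·γ within combined
errors — the decoupling check.

## Sub-population averaging

Ideal single-molecule MSD tracks are power laws `f_ℓ(t) = A(γ̃_ℓ)·t^{γ̃_ℓ}`
with equispaced exponents `γ̃_ℓ = γ̃_min + Δγ̃·ℓ`,
`Δγ̃ = (γ̃_max − γ̃_min)/ℓ_max`. The sub-population exponent γ̃_sub and
log-prefactor c_sub minimize the squared log-residuals of the *mean* curve
against `γ̃_sub·log t + c_sub` — closed-form OLS, cross-checked against an
exhaustive 2-D grid search. (The regressor is log t: that is the only
reading under which power-law tracks become linear; the fit is scale
invariant, so only the grid's decade span and point placement matter.)
Scanning ℓ_max yields the variation curve |γ̃ − γ̃_sub|(ℓ_max) whose global
minimum, under the band constraint γ̃_min ≤ γ̃_sub ≤ γ̃_max, selects a small
finite number of tracks; ties break toward the smallest ℓ_max.

**Grid calibration.** The measurement grid and prefactor rule are free
analysis choices. The module default — unit prefactors, 51 log-spaced
points spanning [1, 10⁸] — was calibrated once so that the reference case
γ̃ = 0.689 with bounds [0.243, 0.799] attains its global minimum at
ℓ_max* = 32, with the variation rising to a stable plateau (≈ 7·10⁻³) at
large ℓ_max; both features, and the value 32, are asserted in the tests.
Narrower grids (e.g. [1, 10⁴] at 25 points/decade) move the minimum to
single-digit ℓ_max, and gamma-function prefactors `A = Γ(γ̃_ℓ)` shift it as
well; both remain available through the `grid` and `prefactor_rule`
arguments. The bound optimizer grid-searches candidate (γ̃_min, γ̃_max)
pairs at a configurable resolution (default 0.005; finer resolutions are a
quadratically larger scan), admitting degenerate bands, and enforces the
γ̃_sub containment constraint.

## FCS, counting and exposure calculators

The correlation model, amplitude law G(0) − 1 = 1/N, and the reductions
(γ̃ = 1 → classical one-component FCS; dim = 2 → no axial factor) are
closed-form. The diffusion time is implemented as
`τ_D = [ω_xy²·2·dim/(4·m·Γ_γ̃ℓ)]^{1/γ̃}` and asserted to be the fixed point
of `τ = ω_xy²/(4·m·D_app(τ))`, which makes the compact definition
testable. Curve fitting is nonlinear least squares with N and τ_D in log
space (positivity) and γ̃ box-bounded to [0.05, 1.5] so boundary solutions
are detectable; noiseless round trips recover parameters to < 0.1%.

Counting uses the exact 2019 SI Avogadro constant. For ΔV = 0.14 fL the
C = 1 cutoff evaluates to 11.86 nM; the commonly quoted "about 11 nM" is
this figure rounded down. C ≥ 1 is a warning in the calculators (the
formulas remain meaningful) but a hard error when configuring an LCTRW
simulation, where N < 1 is the premise.

Exposure moments are taken over the power-law density
`f(r) = q·r^{q−1}/r_max^q` on [0, r_max] — the small-r Maclaurin limit of
the Weibull law, for which `r̄ = q/(q+1)·r_max` and
`σ_r² = q/[(q+2)(q+1)²]·r_max²` are exact (verified against quadrature).
For r_max = 22.8 µm, q = 2: r̄ = 15.2 µm, σ_r² = 28.88 µm² =
2.888·10⁻¹¹ m². (A sometimes-quoted ±2.92·10⁻¹¹ m² is inconsistent with
28.88 µm²; the package reports the derived value.) The LCTRW cap radius
defaults to r̄, so the simulated MSD plateaus at the geometric limit
r̄² ≈ 2.31·10⁻¹⁰ m²; r_max itself can be passed instead.

## What the synthetic data does and does not show

The generators emulate: obstructed lattice geometry with holes on every
scale, heavy-tailed trapping, a hard geometric confinement, and ideal
power-law single-track MSDs. They do not emulate photophysics (blinking,
bleaching, detector noise), active transport (γ̃ > 1), continuum
off-lattice motion, spatially correlated disorder, or measurement noise on
trajectories. Passing tests therefore validate the algorithms and the
internal consistency of the theory at its own operating points, not the
biological fidelity of any particular experiment.

## Numerical choices and limitations

* Reproducibility: every stochastic routine takes a seed; identical seeds
  give bitwise-identical event sequences.
* Lag/time grids are logarithmic (default 25 points/decade) since all fits
  span decades.
* The enumeration oracle refuses lattices above 10⁷ sites; the bound
  optimizer at its published 7.8·10⁻⁴ resolution is an O(10⁶)-candidate
  scan and is left to explicit configuration.
* Blocked proposals consume waiting times (blind ant), so on strongly
  obstructed supports event counts overestimate displacements; this is the
  intended physics, not a bias.
* The time-averaged MSD discretizes the origin average (512 origins by
  default); for step-function trajectories this converges quickly but is
  not an exact integral.
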