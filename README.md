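# lctrw

Simulation and analysis toolkit for **anomalous subdiffusion of single
molecules in crowded cellular environments**, built around *limited
continuous-time random walks (LCTRW) on fractal supports*.

Intracellular diffusion is often subdiffusive, `⟨r²(t)⟩ ∝ t^γ̃` with
`γ̃ < 1`, for two physically distinct reasons: molecular **crowding**
(obstructed space, exponent α) and **temporal heterogeneity** (heavy-tailed
trapping by binding interactions, exponent γ). When both act, the exponents
decouple multiplicatively, `γ̃ = α·γ`. Heavy-tailed waiting times break
ergodicity — time averages along one trajectory and ensemble averages over
many trajectories disagree — yet averaging a *small, well-chosen
sub-population* of single-molecule tracks produces a mean scaling exponent
indistinguishable from an ergodic measurement. This package simulates that
physics and implements the diagnostics and calculators an experimenter in
fluorescence correlation spectroscopy (FCS) needs around it.

## What's inside

| module | contents |
| --- | --- |
| `lctrw.fractal` | generalized Sierpinski carpet supports from a 0/1 generator mask; on-demand, stage-wise (renormalization) accessibility |
| `lctrw.walks` | Brownian tracks, blind-ant walks on fractals (RWF), CTRWs with inverse-gamma waiting times `ψ(t) = e^{−1/t} t^{−(1+γ)}/Γ(γ)`, and LCTRWs with a geometric displacement cap `r_max` and the single-molecule occupancy condition N < 1 |
| `lctrw.msd` | time-averaged / ensemble / step-count MSD estimators, log-log scaling fits |
| `lctrw.subpop` | sub-population averaging: fit one exponent γ̃_sub to the mean of ℓ_max power-law tracks, scan ℓ_max for the global minimum of |γ̃ − γ̃_sub|, optimize the exponent bounds |
| `lctrw.fcs` | anomalous-diffusion FCS correlation model `G(τ) = (1/N)[1+(τ/τ_D)^γ̃]^{−1}[1+(τ/τ_D)^γ̃/s²]^{−(dim−2)/2} + 1`, apparent/instantaneous diffusion coefficients, diffusion time, curve fitting |
| `lctrw.counting` | Poisson occupancy `C = c_m·N_A·ΔV`, single-molecule probability `N = C·e^{−C}`, concentration cutoff, meaningful time `T_m = (τ_D/C)e^{−C}`, track budget `N_ℓmax = T/T_m` |
| `lctrw.exposure` | Weibull model of exposure to interaction sites, power-law limit, moments, the geometric MSD cap `r̄²` |
| `lctrw.io` / `lctrw.cli` | CSV/JSON/YAML formats, seeded fixtures, `lctrw` command-line tool |

## Worked example

How long must one measure to record a sub-population of distinct single
molecules at 5 nM in a 0.14 fL two-photon observation volume, and what does
the cell geometry do to the walk?

```bash
$ lctrw counting --cm 5e-9 --dV 0.14e-15 --tauD 1e-3 --T 0.1
{"C": 0.4215, "N": 0.2765, "cutoff_M": 1.186e-08, "T_m": 0.001556,
 "N_lmax": 64.26, "N_lmax_floor": 64}
```

The mean occupancy is C ≈ 0.42 molecules (below the single-molecule cutoff
of ≈ 11.9 nM, so N < 1 holds); one and the same molecule is observable for
T_m ≈ 1.56 ms, and a 100 ms measurement records 64 distinct molecules.

```bash
$ lctrw exposure --rmax 22.8e-6 --q 2
{"r_bar": 1.52e-05, "sigma_r2": 2.888e-11, "msd_cap": 2.3104e-10}
```

For a nucleus of linear size r_max = 22.8 µm with quadratic exposure shape
(q = 2), the mean interaction size is r̄ = 15.2 µm with variance
σ_r² = 28.88 µm²; the walk's MSD can never exceed r̄² ≈ 2.31·10⁻¹⁰ m² —
the geometric limit that the LCTRW enforces.

```bash
$ lctrw subpop scan --gamma 0.689 --gmin 0.243 --gmax 0.799 --out scan.csv
global minimizer l_max* = 32 (variation 4.490e-05); wrote scan.csv
```

Averaging exactly 32 tracks drawn from the exponent band [0.243, 0.799]
reproduces the target exponent γ̃ = 0.689 to within 4.5·10⁻⁵ — at that
point a non-ergodic ensemble is no longer distinguishable from an ergodic
one. Simulation from Python:

```python
import lctrw

carpet = lctrw.FractalSupport(lctrw.standard_carpet_mask(), k_max=6)
tracks = lctrw.walks.rwf_ensemble(carpet, n_steps=10_000, n_walkers=500, seed=42)
curve = lctrw.ensemble_msd(tracks, lctrw.msd.log_grid(1, 1e4))
print(lctrw.fit_scaling(curve, window=(10, 1e4)).exponent)  # ≈ 0.94 (α < 1)
```

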