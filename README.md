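# beamopt

Spatial optimization of external-beam radiotherapy (XRT) profiles for
radially symmetric tumour cell densities.

Clinical radiotherapy usually irradiates the visible tumour with a uniform
beam. When the tumour cell density n(r) is non-uniform — as it invariably is
for infiltrative tumours such as glioblastoma — a spatially shaped beam with
the *same total dose* kills more cells. `beamopt` computes such optimal beam
shapes for tumours whose growth is described by the standard
reaction–diffusion model

    ∂n/∂t = D_n ∇²n + ρ n (1 − a·n/n_max),

specialised to radially symmetric profiles in two dimensions (a = 0:
exponential growth, Gaussian profiles; a = 1: Fisher–KPP logistic growth,
flat-topped profiles well approximated by the Fermi function
a₁/(1 + b₁·e^{c₁r²})). During a fraction of duration Δt the density obeys

    ∂n/∂t = −γ f(r) n (1 − b·n/n_max),      γ = α·Ḋ,

where f(r) is the cytotoxic (beam) profile, α the linear radiosensitivity,
Ḋ the dose rate, and b selects exponential (b = 0) or saturable "logistic"
kill (b = 1, capturing the radio-resistance of dense, slowly proliferating
regions). The optimisation minimises the surviving cell number
N = 2π ∫ r n(r) dr — equivalently maximises the tumour control probability
TCP = e^{−N} — subject to the flux budget F′ = Σ fᵢ(rᵢ² − rᵢ₋₁²) and the
pointwise cap 0 ≤ f ≤ C.

What it computes:

* **Continuous optima** (Lagrange multipliers): f = ln(n/λ) truncated at
  zero for exponential kill — a parabolic, "semi-circular" beam for a
  Gaussian tumour, leaving a flat-topped residual density — and the
  corresponding stationarity solution for saturable kill.
* **One-step beams**: the optimal uniform disc (radius r₁, strength
  f₁ = F′/r₁²) from the closed-form stationarity condition, with the cap
  boundary handled explicitly.
* **Two-step beams and two-fraction plans**: constrained Monte-Carlo search
  over the feasible parameter slice (the outermost strength solved from the
  budget) with deterministic Nelder–Mead refinement, for per-fraction or
  joint dose constraints and for both kill models.

## Worked example

```python
from beamopt import DiscreteProblem, mc_optimize, onestep_optimal
from beamopt.tables import reference_gaussian

density = reference_gaussian(3.0)          # sigma = 3 mm, ~1e7 cells
print(f"initial cells: {density.total_cells():.3e}")

res1 = onestep_optimal(DiscreteProblem(density=density, n_steps=1))
(r1, f1), = res1.profiles[0].breaks
print(f"one-step optimum: r1 = {r1:.3f} mm, f1 = {f1:.3f}, N = {res1.N_final:.3e}")

res2 = mc_optimize(DiscreteProblem(density=density, n_steps=2),
                   n_samples=1_000_000, seed=0)
(r1, f1), (r2, f2) = res2.profiles[0].breaks
print(f"two-step optimum: r = ({r1:.2f}, {r2:.2f}) mm, "
      f"f = ({f1:.2f}, {f2:.2f}), N = {res2.N_final:.3e}")
```

prints

```
initial cells: 1.003e+07
one-step optimum: r1 = 3.708 mm, f1 = 1.818, N = 7.155e+06
two-step optimum: r = (2.82, 3.98) mm, f = (2.10, 1.05), N = 7.100e+06
```

Reading: for a σ = 3 mm Gaussian tumour with ~10⁷ cells, the best single
uniform disc of radiation (flux budget F′ = 25 mm², strength cap 2.5) has
radius 3.71 mm and leaves 7.16·10⁶ cells; adding a second, weaker outer
ring (a crude approximation to the parabolic continuous optimum) lowers
that to 7.10·10⁶. A uniform beam over r ≤ 5 mm with the same flux leaves
7.44·10⁶ cells — spatial shaping kills ~3·10⁵ more cells at no extra dose.

## Command line

```
beamopt simulate-growth  --config run.yaml --out out/   # evolve the PDE, fit a Fermi profile
beamopt optimize         --config run.yaml --out out/   # continuous or discrete optimisation
beamopt evaluate-profile --config run.yaml --profile beam.csv --out out/
beamopt reproduce-tables --config run.yaml --out out/   # full reference case grid as CSVs
```

See `beamopt.config` for the YAML schema; all model constants (D_n = 0.32
mm²/day, ρ = 0.35/day, γ = 60/day, Δt = 0.007 day, C = 2.5, F′ = 25 mm²,
R = 10 mm) are defaults and can be overridden per run.

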