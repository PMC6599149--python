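# Methods

## Model

Tumour growth follows the reaction–diffusion equation
∂n/∂t = D_n∇²n + ρn(1 − a·n/n_max) on a disc of radius R, restricted to
radially symmetric densities n(r) in two dimensions (densities in
cells/mm², radii in mm, time in days). Exponential growth (a = 0) from a
point seed yields the Gaussian n(r) = n₀e^{−r²/2σ²} with σ² = 2D_n t and
exponentially growing mass; logistic growth (a = 1) yields flat-topped
profiles that are well approximated by the Fermi function
n(r) = a₁/(1 + b₁e^{c₁r²}).

During a radiation fraction (Δt ≈ 10 min = 0.007 day) growth and diffusion
are negligible, so the fraction reduces to an ODE in time with exact
survival maps:

* exponential kill (b = 0): n ↦ n·e^{−x}, x = γ f(r) Δt;
* logistic (saturable) kill (b = 1):
  n ↦ n_max·n·e^{−x}/(n_max − n(1 − e^{−x})),
  which has n = n_max as a fixed point (saturated regions are
  radio-resistant) and reduces to the exponential map as n_max → ∞.

Between fractions separated by a gap τ the density is scaled by e^{ρτ};
this shape-preserving approximation is valid when D_n·τ ≪ σ², and a warning
is emitted when D_n·τ > 0.1·σ_ref².

Dose is accounted in reduced flux units F′ = F/(πγΔt): a step beam with
outer radii rᵢ and strengths fᵢ has flux Σ fᵢ(rᵢ² − rᵢ₋₁²). The objective
is the surviving cell number N = 2π∫ r n(r) dr (TCP = e^{−N} is reported
alongside); constraints are the per-fraction or total flux budget and the
pointwise cap 0 ≤ f ≤ C. The quadratic term of the linear-quadratic
dose-response model is deliberately omitted: it only rescales γ and does
not change the shape question the package answers.

## Reference study conditions

Defaults mirror the reference parameterisation for glioblastoma:
D_n = 0.32 mm²/day, ρ = 0.35/day, γ = α·Ḋ = 0.08 × 5/0.007 ≈ 60/day,
Δt = 0.007 day, C = 2.5, F′ = 25 mm², R = 10 mm. The five reference
Gaussian tumours (σ = 1…5 mm) are normalised to ≈10⁷ total cells via
n₀ = N/(2πσ²(1 − e^{−R²/2σ²})); the canonical n₀ values are quoted to three
significant figures (1.59e6, 3.98e5, 1.78e5, 1.04e5, 7.36e4), and those
quoted values — not the exact normalisation — are used when reproducing the
reference tables, since the tabulated cell numbers derive from them. The
three reference Fermi densities are taken as printed coefficient records;
the run that generated them (initial condition, evolution time, n_max) is
not specified, so regenerating the coefficients is out of scope and
`fit_fermi` is validated by round-trips instead.

## Continuous optima

With exponential kill, extremising N under the flux constraint gives
f = ln(n/λ) truncated at 0 and clipped at C; λ is solved from the budget by
Brent root finding on the (monotone) flux residual, with truncation and
clipping inside the λ iteration so the budget is saturated exactly
(residual tolerance ~1e−10 relative; flux integrals by Simpson on 16385
nodes). Inside the beam support the post-treatment density is exactly λ —
the flat-top property. For a Gaussian tumour this is the truncated parabola
with support r_m = [d(d+2)/S_d]^{1/(d+2)}F^{1/(d+2)}σ^{2/(d+2)} and peak
f_m = r_m²/2σ²; `semicircle_beam` keeps general d ∈ {2, 3} analytically.

With logistic kill, the pointwise stationarity condition is a quadratic in
the survival fraction w = e^{−f}. The admissible root, evaluated in the
numerically stable conjugate form w = 2λ(n_max − n)/(n·(n_max − 2λ +
√(n_max(n_max − 4λ)))), recovers w = λ/n as n_max → ∞. For n > n_max/2 the
pointwise problem is non-convex (the marginal kill per unit dose first
rises, then falls), so the profile takes the global minimiser of the
pointwise Lagrangian among {0, interior root, cap}. A consequence is that
regions at or near carrying capacity receive *zero* dose — killing there is
inefficient, and the budget is better spent elsewhere — which is what
produces ring-shaped discrete optima for flat-topped densities.

## Discrete optima

**One step.** With f₁ = F′/r₁² eliminated by the budget, the objective has
a closed form for Gaussian densities and its stationarity condition
dN/dr₁ = 0 is solved by sign-change scanning (513 nodes) plus Brent root
finding on [√(F′/C), R]; interior roots are compared against the
cap-saturating boundary r₁ = √(F′/C) and the domain edge. For σ = 1, 2 mm
the cap binds and the boundary solution wins. (A tabulated presentation of
these optima elsewhere prints the bound as r₁² ≥ F′/C; the package uses
r₁ = √10 ≈ 3.16 mm, which reproduces the tabulated cell numbers.)

**Two steps / two fractions.** Candidates are drawn uniformly over the
feasible slice: radii uniform then sorted, inner strengths uniform in
[0, C], and the outermost strength solved from the active budget, rejecting
out-of-range solutions. The exact objective — piecewise ring masses through
each density's closed-form cumulative mass — is evaluated vectorised in
batches of 2¹⁷, and the incumbent is then polished by a deterministic
Nelder–Mead refinement in the reduced parameter space (the solved strength
stays eliminated). The default budget of 10⁶ samples plus refinement
recovers the three-significant-figure reference optima in ~0.2 s; the
refined optimum is insensitive to the seed. Diagnostics record the top-10
candidates and the feasible-sample count, since near-optimal plateaus are
common (e.g. when the cap binds, many profiles achieve the same N).

Two fractions, separately constrained: fraction 1 is optimised on the
initial density; its kill and the inter-fraction growth factor e^{ρτ} are
applied; fraction 2 is optimised on the result (an exact piecewise-scaled
density). With negligible diffusion the final density depends only on the
summed dose, so fraction order does not matter — asserted to 1e−10 in
tests. Jointly constrained (budget 2F′): an 8-parameter search; the
separately constrained solution is a feasible joint point and seeds the
search, which guarantees the joint optimum is never worse, as the nesting
of the feasible sets requires. τ defaults to 0 (the reference two-fraction
results are consistent with negligible inter-fraction growth); it is
configurable per plan, and with D_n = 0 a nonzero τ only scales N by
e^{ρτ}.

**Logistic kill.** The same sampler with the saturable-kill objective. For
(scaled) Fermi densities the killed ring mass has the exact antiderivative
(s − ln|α + βe^{c₁s}|/c₁)/α with s = r², α = n_max − a₁(1 − e^{−x}),
β = n_max·b₁, used as a fast vectorised path; other densities fall back to
fixed-order Gauss–Legendre quadrature (96 nodes per segment; the two routes
agree to 1e−10 in tests). The carrying capacity for these runs is a
required input; qualitative checks use n_max = 1.5e6 cells/mm², slightly
above the σ = 1 Fermi peak of 1.454e6, and reproduce the characteristic
ring optimum (inner strength ≈ 0).

Every `OptimizationResult.N_final` is re-evaluated through the plan
simulator (`run_plan`) after the search, so the reported optimum cannot
drift from what the returned profiles actually achieve.

## PDE solver

`evolve_pde` uses a conservative mass-lumped linear-finite-element
discretisation of the radial Laplacian (1/r)∂_r(r∂_r n) on a uniform grid
with zero-flux boundaries; the r = 0 coordinate singularity is handled by
the finite control volume h²/6 of the first node. Because the discrete
mass functional equals the exact integral of the piecewise-linear
interpolant and the diffusion stencil telescopes, mass is conserved to
time-integrator precision when ρ = 0 (machine precision in practice, since
Runge–Kutta schemes preserve linear invariants). Time stepping is classical
RK4 with a diffusion-stable default step 0.2h²/D_n; instability (negative
or exploding values) raises an error advising a smaller step. The scheme
was validated against three independent limits: the logistic ODE closed
form at D_n = 0 (machine precision at the nodes), heat-kernel spreading
σ²(t) = σ₀² + 2D_n t with mass factor e^{ρt} for the linear PDE (1e−5
relative by moment fitting at grid 512), and the n ≤ n_max bound for
logistic growth.

`fit_fermi` fits a₁/(1 + b₁e^{c₁r²}) by Levenberg–Marquardt least squares,
multi-starting over both sign patterns of (b₁, c₁) — both occur among the
reference coefficient sets — with magnitudes seeded from the log-slope of
a₁/n − 1 against r². Constant inputs are rejected as degenerate (c₁
unidentifiable) rather than silently returned.

## Synthetic inputs and what the tests show

All inputs are parameter records: no external data is read. The reference
Gaussian and Fermi densities are idealised, noise-free, radially symmetric,
and two-dimensional; the test suite therefore demonstrates correctness of
the optimisation machinery under the stated model, not robustness to
imaging noise, anisotropy, 3-D geometry, or tissue heterogeneity beyond
the saturable-kill phenomenology. Test and acceptance Monte-Carlo runs use
10⁵–10⁶ samples with deterministic refinement; these sizes were chosen as
the point where the refined optima stabilise to well within the
three-significant-figure resolution of the reference values.

## Known limitations

* No normal-tissue term (NTCP), organ-at-risk dose, or scheduling
  optimisation; no beam physics (scatter, depth dose).
* The two-fraction flux split between fractions in joint-budget mode is a
  nearly flat direction of the objective when D_n = 0; the optimizer
  reports the incumbent and does not attempt to resolve the tie.
* Second-fraction optimisation under logistic kill is not implemented
  (the saturable objective after a first fraction loses its closed form).
* The σ = 3, 5 reference Fermi densities do not decay as r → ∞ and are
  treated as valid on [0, R] only.
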