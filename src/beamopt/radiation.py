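"""Intra-fraction radiation kill, beam profiles, dose accounting, and outcomes.

During a fraction of duration ``delta_t`` (days), growth and diffusion are
negligible and the density obeys dn/dt = -gamma * f(r) * n * (1 - b*n/n_max).
With exponential death (b = 0) the survival map is n -> n * exp(-x), and with
logistic death (b = 1) the exact ODE solution is

    n -> n_max * n * exp(-x) / (n_max - n * (1 - exp(-x))),   x = gamma*f*dt,

which leaves the carrying capacity n_max as a fixed point (saturated regions
are radio-resistant) and reduces to the exponential map as n_max -> inf.

Dose is accounted in reduced flux units F' = F / (pi * gamma * dt) =
sum_i f_i * (r_i^2 - r_{i-1}^2) for a piecewise-constant (step) beam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import Domain, FermiDensity, GriddedDensity, RadialDensity, ScaledDensity, grow_between_fractions

__all__ = [
    "RadiationParams",
    "StepProfile",
    "FractionPlan",
    "SurvivalScaledDensity",
    "LogisticKilledDensity",
    "BudgetError",
    "profile_strength",
    "profile_flux",
    "flux_to_F",
    "apply_kill_exponential",
    "apply_kill_logistic",
    "tcp",
    "run_plan",
]


@dataclass(frozen=True)
class RadiationParams:
    """Radiation model constants.

    gamma = alpha * dose-rate (1/day) is the linear radiosensitivity times the
    dose rate; ``cap_C`` bounds the beam strength pointwise (0 <= f <= C);
    ``budget_Fprime`` is the per-fraction flux budget in reduced units
    (mm^2 x strength).
    """

    gamma: float = 60.0
    delta_t: float = 0.007
    cap_C: float = 2.5
    budget_Fprime: float = 25.0
    death_mode_b: int = 0

    def __post_init__(self) -> None:
        for name in ("gamma", "delta_t", "cap_C", "budget_Fprime"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.death_mode_b not in (0, 1):
            raise ValueError(f"death_mode_b must be 0 or 1, got {self.death_mode_b}")


@dataclass(frozen=True)
class StepProfile:
    """Piecewise-constant radial beam: ordered (outer_radius, strength) pairs.

    Pieces are half-open [r_{i-1}, r_i); strength is 0 beyond the last radius.
    """

    breaks: tuple[tuple[float, float], ...]

    def __init__(self, breaks):
        object.__setattr__(self, "breaks", tuple((float(r), float(f)) for r, f in breaks))
        radii = [r for r, _ in self.breaks]
        if any(np.diff(radii) <= 0) or (radii and radii[0] <= 0):
            raise ValueError(f"step radii must be strictly increasing and > 0: {radii}")
        if any(f < 0 for _, f in self.breaks):
            raise ValueError("step strengths must be >= 0")

    @property
    def radii(self) -> np.ndarray:
        return np.array([r for r, _ in self.breaks])

    @property
    def strengths(self) -> np.ndarray:
        return np.array([f for _, f in self.breaks])

    def strength_at(self, r):
        """Beam strength at radius r (vectorised); half-open piece convention."""
        r_arr = np.asarray(r, dtype=float)
        if np.any(r_arr < 0):
            raise ValueError("radius must be >= 0")
        out = np.zeros_like(r_arr, dtype=float)
        edges = np.concatenate([[0.0], self.radii])
        for i, (_, f) in enumerate(self.breaks):
            out = np.where((r_arr >= edges[i]) & (r_arr < edges[i + 1]), f, out)
        return out if out.ndim else float(out)

    def flux(self) -> float:
        """Reduced flux F' = sum_i f_i * (r_i^2 - r_{i-1}^2)."""
        prev = 0.0
        total = 0.0
        for r, f in self.breaks:
            total += f * (r**2 - prev**2)
            prev = r
        return total


def profile_strength(profile: StepProfile, r) -> float:
    return profile.strength_at(r)


def profile_flux(profile: StepProfile) -> float:
    return profile.flux()


def flux_to_F(Fprime: float, params: RadiationParams) -> float:
    """Convert reduced flux F' to the physical dose integral F = pi*gamma*dt*F'."""
    return np.pi * params.gamma * params.delta_t * Fprime


@dataclass(frozen=True)
class FractionPlan:
    """A sequence of fractions: (StepProfile, delta_t, tau_after) triples.

    ``tau_after`` is the growth gap (days) following each fraction.
    ``constraint_mode`` is 'per_fraction' (each fraction's flux <= F') or
    'total' (summed flux <= n_fractions * F').
    """

    fractions: tuple
    constraint_mode: str = "per_fraction"

    def __init__(self, fractions, constraint_mode="per_fraction"):
        fr = tuple((p, float(dt), float(tau)) for p, dt, tau in fractions)
        if any(tau < 0 for _, _, tau in fr):
            raise ValueError("inter-fraction gaps tau must be >= 0")
        if constraint_mode not in ("per_fraction", "total"):
            raise ValueError(f"unknown constraint_mode {constraint_mode!r}")
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "constraint_mode", constraint_mode)


class BudgetError(ValueError):
    """A fraction plan violates its flux budget."""


class SurvivalScaledDensity(RadialDensity):
    """Density multiplied by a piecewise-constant survival factor (exponential kill).

    Ring masses remain exact: each base-density ring integral is scaled by
    the survival factor of the (sub-)annulus it lies in.
    """

    def __init__(self, base: RadialDensity, edges, factors):
        super().__init__(base.domain)
        self.base = base
        self.edges = np.asarray(edges, dtype=float)  # interior break radii
        self.factors = np.asarray(factors, dtype=float)  # len = len(edges)+1
        if len(self.factors) != len(self.edges) + 1:
            raise ValueError("need one factor per piece (len(edges)+1)")
        self.kind = base.kind

    def _factor_at(self, r):
        idx = np.searchsorted(self.edges, r, side="right")
        return self.factors[idx]

    def _evaluate(self, r):
        return self.base._evaluate(r) * self._factor_at(np.asarray(r))

    def ring_mass(self, p: float, q: float) -> float:
        if q <= p:
            return 0.0
        cuts = np.concatenate([[p], self.edges[(self.edges > p) & (self.edges < q)], [q]])
        total = 0.0
        for a, b in zip(cuts[:-1], cuts[1:]):
            total += self._factor_at(0.5 * (a + b)) * self.base.ring_mass(a, b)
        return float(total)

    def cumulative_mass(self, r):
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        pts = np.concatenate([[0.0], self.edges])
        cum_at_edges = np.asarray(self.base.cumulative_mass(pts))
        if len(self.edges):
            scaled_edges = np.concatenate(
                [[0.0], np.cumsum(self.factors[:-1] * np.diff(cum_at_edges))]
            )
        else:
            scaled_edges = np.array([0.0])
        idx = np.searchsorted(self.edges, r_arr, side="right")
        within = np.asarray(self.base.cumulative_mass(r_arr)) - cum_at_edges[idx]
        return scaled_edges[idx] + self.factors[idx] * within

    def max_density(self):
        r = np.linspace(0.0, self.domain.R, 4097)
        return float(np.max(self._evaluate(r)))


class LogisticKilledDensity(RadialDensity):
    """Result of applying logistic (saturable) kill to a base density.

    Pointwise: n -> n_max*n*exp(-x)/(n_max - n*(1-exp(-x))) with
    x = gamma*f(r)*dt.  Ring masses use an exact antiderivative when the base
    is a Fermi profile (possibly globally scaled) and fixed-order
    Gauss-Legendre quadrature otherwise.
    """

    _GL_N = 96

    def __init__(self, base: RadialDensity, profile: StepProfile, params: RadiationParams, n_max: float):
        super().__init__(base.domain)
        self.base = base
        self.profile = profile
        self.params = params
        self.n_max = float(n_max)
        self.kind = base.kind

    def _survive(self, n, x):
        ex = np.exp(-x)
        return self.n_max * n * ex / (self.n_max - n * (1.0 - ex))

    def _evaluate(self, r):
        r_arr = np.asarray(r, dtype=float)
        n = self.base._evaluate(r_arr)
        x = self.params.gamma * self.params.delta_t * np.asarray(self.profile.strength_at(r_arr))
        return self._survive(n, x)

    def _fermi_base(self):
        """Return (a1, b1, c1) if the base is a (scaled) Fermi density."""
        b = self.base
        scale = 1.0
        while isinstance(b, ScaledDensity):
            scale *= b.factor
            b = b.base
        if isinstance(b, FermiDensity):
            p = b.params
            return p.a1 * scale, p.b1, p.c1
        return None

    def _segment_mass(self, p: float, q: float, f: float) -> float:
        """Cells in [p, q] after a uniform dose of strength f."""
        if q <= p:
            return 0.0
        x = self.params.gamma * self.params.delta_t * f
        if x == 0.0:
            return self.base.ring_mass(p, q)
        fermi = self._fermi_base()
        m = self.n_max
        ex = np.exp(-x)
        if fermi is not None:
            a1, b1, c1 = fermi
            # n(r) = a1/(1+b1 e^{c s}), s = r^2; killed-density ring integral:
            # pi*m*a1*ex * int ds / (alpha + beta e^{c s}),
            # alpha = m - a1(1-ex), beta = m*b1
            alpha = m - a1 * (1.0 - ex)
            beta = m * b1
            sp, sq = p**2, q**2
            if abs(c1) < 1e-14 or beta == 0.0:
                integral = (sq - sp) / (alpha + beta)
            elif abs(alpha) < 1e-9 * m:
                integral = (np.exp(-c1 * sp) - np.exp(-c1 * sq)) / (beta * c1)
            else:
                def anti(s):
                    return (s - np.log(np.abs(alpha + beta * np.exp(c1 * s))) / c1) / alpha
                integral = anti(sq) - anti(sp)
            return float(np.pi * m * a1 * ex * integral)
        # generic quadrature
        nodes, wts = np.polynomial.legendre.leggauss(self._GL_N)
        r = 0.5 * (q - p) * nodes + 0.5 * (q + p)
        n = self.base._evaluate(r)
        vals = self._survive(n, x)
        return float(0.5 * (q - p) * np.sum(wts * 2.0 * np.pi * r * vals))

    def ring_mass(self, p: float, q: float) -> float:
        if q <= p:
            return 0.0
        edges = self.profile.radii
        cuts = np.concatenate([[p], edges[(edges > p) & (edges < q)], [q]])
        total = 0.0
        for a, b in zip(cuts[:-1], cuts[1:]):
            f = float(self.profile.strength_at(0.5 * (a + b)))
            total += self._segment_mass(a, b, f)
        return total


def apply_kill_exponential(
    density: RadialDensity, profile: StepProfile, params: RadiationParams
) -> RadialDensity:
    """Apply one fraction of exponential kill: n -> n * exp(-gamma*f(r)*dt)."""
    if params.death_mode_b != 0:
        raise ValueError("exponential kill requires death_mode_b=0")
    x = params.gamma * params.delta_t
    factors = np.concatenate([np.exp(-x * profile.strengths), [1.0]])
    if isinstance(density, GriddedDensity):
        vals = density.values * np.asarray(
            np.exp(-x * np.asarray(profile.strength_at(density.radii)))
        )
        return GriddedDensity(density.radii, vals, density.domain)
    return SurvivalScaledDensity(density, profile.radii, factors)


def apply_kill_logistic(
    density: RadialDensity, profile: StepProfile, params: RadiationParams, n_max: float
) -> RadialDensity:
    """Apply one fraction of logistic (saturable) kill.

    Density at the carrying capacity is a fixed point; densities above n_max
    are inadmissible and raise.
    """
    peak = density.max_density()
    if peak > n_max * (1 + 1e-12):
        raise ValueError(
            f"density ({peak:g}) exceeds carrying capacity n_max ({n_max:g})"
        )
    return LogisticKilledDensity(density, profile, params, n_max)


def tcp(N: float) -> float:
    """Tumour control probability e^{-N}: chance that no tumour cell survives."""
    if N < 0:
        raise ValueError("cell number must be >= 0")
    with np.errstate(under="ignore"):
        return float(np.exp(-N))


def run_plan(
    density: RadialDensity,
    plan: FractionPlan,
    params: RadiationParams,
    growth,
    sigma_ref: float | None = None,
):
    """Execute a fraction plan: alternate kill and inter-fraction growth.

    Returns a list of (time_days, density, N) tuples recorded after every
    event (each fraction and each growth gap).  Budgets are validated before
    any kill is applied.
    """
    fluxes = [p.flux() for p, _, _ in plan.fractions]
    if plan.constraint_mode == "per_fraction":
        for i, fl in enumerate(fluxes):
            if fl > params.budget_Fprime * (1 + 1e-9):
                raise BudgetError(
                    f"fraction {i + 1} flux {fl:g} exceeds per-fraction budget "
                    f"{params.budget_Fprime:g}"
                )
    else:
        total_budget = params.budget_Fprime * len(fluxes)
        if sum(fluxes) > total_budget * (1 + 1e-9):
            raise BudgetError(
                f"total flux {sum(fluxes):g} exceeds joint budget {total_budget:g}"
            )
    for i, (p, _, _) in enumerate(plan.fractions):
        if np.any(p.strengths > params.cap_C * (1 + 1e-9)):
            raise BudgetError(f"fraction {i + 1} exceeds the strength cap C")

    events = []
    t = 0.0
    current = density
    for profile, dt_frac, tau in plan.fractions:
        frac_params = RadiationParams(
            gamma=params.gamma,
            delta_t=dt_frac,
            cap_C=params.cap_C,
            budget_Fprime=params.budget_Fprime,
            death_mode_b=params.death_mode_b,
        )
        if params.death_mode_b == 1:
            current = apply_kill_logistic(current, profile, frac_params, growth.n_max)
        else:
            current = apply_kill_exponential(current, profile, frac_params)
        t += dt_frac
        events.append((t, current, current.total_cells()))
        if tau > 0:
            current = grow_between_fractions(
                current, growth.rho, tau, sigma_ref=sigma_ref, D_n=growth.D_n
            )
            t += tau
            events.append((t, current, current.total_cells()))
    return events
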