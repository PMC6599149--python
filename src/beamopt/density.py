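"""Radial tumour cell-density profiles.

Tumour growth is modelled by the reaction-diffusion (Fisher-KPP) equation

    dn/dt = D_n * lap(n) + rho * n * (1 - a * n / n_max),

specialised to radially symmetric profiles in two dimensions, so every
density is a function n(r) on a disc of radius ``R`` (cells/mm^2).  Three
representations are supported:

* :class:`GaussianDensity` -- n(r) = n0 * exp(-r^2 / 2 sigma^2), the exact
  profile reached by exponential growth plus diffusion from a point seed;
* :class:`FermiDensity` -- n(r) = a1 / (1 + b1 * exp(c1 * r^2)), the
  flat-topped analytic approximant to logistic-growth profiles;
* :class:`GriddedDensity` -- tabulated values with monotone piecewise-linear
  interpolation, produced e.g. by :func:`evolve_pde`.

All densities expose pointwise evaluation, exact (or quadrature) ring
masses ``2*pi * int_p^q r n(r) dr``, and the total cell number on the disc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "Domain",
    "GaussianParams",
    "FermiParams",
    "GrowthParams",
    "RadialDensity",
    "GaussianDensity",
    "FermiDensity",
    "GriddedDensity",
    "ScaledDensity",
    "FermiFitError",
    "gaussian_density",
    "fermi_density",
    "gridded_density",
    "n0_for_total",
    "total_cells",
    "evolve_pde",
    "fit_fermi",
    "grow_between_fractions",
]


@dataclass(frozen=True)
class Domain:
    """Radial computational domain: disc of radius ``R`` (mm)."""

    R: float = 10.0
    grid_n: int = 256

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"domain radius R must be positive, got {self.R}")
        if self.grid_n < 16:
            raise ValueError(f"grid_n must be >= 16, got {self.grid_n}")


@dataclass(frozen=True)
class GaussianParams:
    """Gaussian profile parameters: central density n0 and spread sigma (mm)."""

    n0: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.n0 > 0:
            raise ValueError(f"n0 must be positive, got {self.n0}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class FermiParams:
    """Fermi-function coefficients: n(r) = a1 / (1 + b1 * exp(c1 * r^2))."""

    a1: float
    b1: float
    c1: float


@dataclass(frozen=True)
class GrowthParams:
    """Growth-law parameters.

    Parameters
    ----------
    D_n : float
        Cell diffusivity (mm^2/day).
    rho : float
        Proliferation rate (1/day).
    n_max : float or None
        Carrying capacity (cells/mm^2); required when ``mode_a == 1``.
    mode_a : int
        0 for exponential growth, 1 for logistic growth.
    """

    D_n: float = 0.32
    rho: float = 0.35
    n_max: float | None = None
    mode_a: int = 0

    def __post_init__(self) -> None:
        if self.D_n < 0:
            raise ValueError(f"D_n must be >= 0, got {self.D_n}")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.mode_a not in (0, 1):
            raise ValueError(f"mode_a must be 0 or 1, got {self.mode_a}")
        if self.mode_a == 1 and (self.n_max is None or self.n_max <= 0):
            raise ValueError("logistic growth (mode_a=1) requires n_max > 0")


class RadialDensity:
    """Base class for radial cell-density profiles on a disc."""

    kind: str = "abstract"

    def __init__(self, domain: Domain):
        self.domain = domain

    # -- pointwise evaluation ------------------------------------------------

    def _evaluate(self, r: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def density_at(self, r):
        """Density (cells/mm^2) at radius ``r`` (mm); raises outside [0, R]."""
        r_arr = np.asarray(r, dtype=float)
        if np.any(r_arr < 0) or np.any(r_arr > self.domain.R * (1 + 1e-12)):
            raise ValueError(
                f"radius outside domain [0, {self.domain.R}]: {r!r}"
            )
        out = self._evaluate(np.clip(r_arr, 0.0, self.domain.R))
        return out if out.ndim else float(out)

    def __call__(self, r):
        return self.density_at(r)

    # -- integrals -----------------------------------------------------------

    def ring_mass(self, p: float, q: float) -> float:
        """Cells in the annulus p <= r <= q: 2*pi * int_p^q r n(r) dr.

        Subclasses override with closed forms where available; the default
        is adaptive quadrature (relative tolerance 1e-10).
        """
        if q <= p:
            return 0.0
        val, _ = integrate.quad(
            lambda r: 2.0 * np.pi * r * float(self._evaluate(np.asarray(r))),
            p,
            q,
            epsrel=1e-10,
            epsabs=0.0,
            limit=200,
        )
        return val

    def cumulative_mass(self, r):
        """Vectorised M(r) = cells within radius r.  Exact for analytic kinds."""
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        return np.array([self.ring_mass(0.0, float(ri)) for ri in r_arr])

    def total_cells(self) -> float:
        """Total cell number N = 2*pi * int_0^R r n(r) dr."""
        n = self.ring_mass(0.0, self.domain.R)
        if not np.isfinite(n):
            raise ValueError("density integral is not finite")
        return n

    def max_density(self) -> float:
        """Maximum density on the domain (sampled on a fine grid by default)."""
        r = np.linspace(0.0, self.domain.R, 4097)
        return float(np.max(self._evaluate(r)))


class GaussianDensity(RadialDensity):
    """n(r) = n0 * exp(-r^2 / 2 sigma^2) on a disc of radius R."""

    kind = "gaussian"

    def __init__(self, params: GaussianParams, domain: Domain = Domain()):
        super().__init__(domain)
        self.params = params

    def _evaluate(self, r):
        p = self.params
        return p.n0 * np.exp(-(r**2) / (2.0 * p.sigma**2))

    def ring_mass(self, p: float, q: float) -> float:
        # closed form: 2*pi*n0*sigma^2 * (exp(-p^2/2s^2) - exp(-q^2/2s^2))
        if q <= p:
            return 0.0
        g = self.params
        s2 = g.sigma**2
        return float(
            2.0 * np.pi * g.n0 * s2
            * (np.exp(-(p**2) / (2 * s2)) - np.exp(-(q**2) / (2 * s2)))
        )

    def cumulative_mass(self, r):
        g = self.params
        s2 = g.sigma**2
        r_arr = np.asarray(r, dtype=float)
        return 2.0 * np.pi * g.n0 * s2 * (1.0 - np.exp(-(r_arr**2) / (2 * s2)))

    def max_density(self) -> float:
        return self.params.n0


class FermiDensity(RadialDensity):
    """Flat-topped profile n(r) = a1 / (1 + b1 * exp(c1 * r^2)).

    Used as the analytic approximant to densities evolved under logistic
    growth.  The fitted coefficient pairs in the source tables come in both
    sign patterns (b1, c1 > 0 decaying; b1, c1 < 0 also decaying); validity
    (positive finite density) is checked on [0, R] at construction.
    """

    kind = "fermi"

    def __init__(self, params: FermiParams, domain: Domain = Domain()):
        super().__init__(domain)
        self.params = params
        r = np.linspace(0.0, domain.R, 1025)
        denom = 1.0 + params.b1 * np.exp(params.c1 * r**2)
        if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
            raise ValueError(
                "Fermi parameters give a non-positive or singular density "
                f"on [0, {domain.R}]: {params}"
            )
        if params.a1 <= 0:
            raise ValueError(f"a1 must be positive, got {params.a1}")

    def _evaluate(self, r):
        p = self.params
        return p.a1 / (1.0 + p.b1 * np.exp(p.c1 * r**2))

    def ring_mass(self, p: float, q: float) -> float:
        if q <= p:
            return 0.0
        m = self.cumulative_mass(np.array([p, q]))
        return float(m[1] - m[0])

    def cumulative_mass(self, r):
        # substitute s = r^2:  pi*a1 * int_0^{r^2} ds / (1 + b1 e^{c1 s})
        # antiderivative: s - ln(1 + b1 e^{c1 s}) / c1
        f = self.params
        r_arr = np.asarray(r, dtype=float)
        s = r_arr**2
        if abs(f.c1) < 1e-14:
            return np.pi * f.a1 * s / (1.0 + f.b1)
        anti = s - np.log1p(f.b1 * np.exp(f.c1 * s)) / f.c1
        anti0 = -np.log1p(f.b1) / f.c1
        return np.pi * f.a1 * (anti - anti0)


class GriddedDensity(RadialDensity):
    """Tabulated density with monotone piecewise-linear interpolation in r."""

    kind = "gridded"

    def __init__(self, radii, values, domain: Domain | None = None):
        radii = np.asarray(radii, dtype=float)
        values = np.asarray(values, dtype=float)
        if radii.ndim != 1 or radii.shape != values.shape:
            raise ValueError("radii and values must be 1-D arrays of equal length")
        if radii[0] != 0.0 or np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be strictly increasing from 0")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("density values must be finite and non-negative")
        if domain is None:
            domain = Domain(R=float(radii[-1]))
        elif abs(radii[-1] - domain.R) > 1e-9 * domain.R:
            raise ValueError("grid must extend to the domain radius R")
        super().__init__(domain)
        self.radii = radii
        self.values = values
        # exact integral of r*n(r) for linear n on each segment, cumulative
        a, b = radii[:-1], radii[1:]
        na, nb = values[:-1], values[1:]
        seg = (b - a) * (na * (2 * a + b) + nb * (a + 2 * b)) / 6.0
        self._cum = 2.0 * np.pi * np.concatenate([[0.0], np.cumsum(seg)])

    def _evaluate(self, r):
        return np.interp(r, self.radii, self.values)

    def ring_mass(self, p: float, q: float) -> float:
        if q <= p:
            return 0.0
        m = self.cumulative_mass(np.array([p, q]))
        return float(m[1] - m[0])

    def cumulative_mass(self, r):
        # exact integral of the piecewise-linear interpolant up to r
        r_arr = np.asarray(r, dtype=float)
        idx = np.clip(np.searchsorted(self.radii, r_arr, side="right") - 1,
                      0, len(self.radii) - 2)
        a = self.radii[idx]
        b = self.radii[idx + 1]
        na = self.values[idx]
        nb = self.values[idx + 1]
        x = np.clip(r_arr, a, b) - a
        slope = (nb - na) / (b - a)
        partial = 2 * np.pi * (na * (a * x + x**2 / 2)
                               + slope * (a * x**2 / 2 + x**3 / 3))
        return self._cum[idx] + partial

    def max_density(self) -> float:
        return float(np.max(self.values))


class ScaledDensity(RadialDensity):
    """A density multiplied by a global scalar factor (e.g. growth e^{rho*tau})."""

    def __init__(self, base: RadialDensity, factor: float):
        super().__init__(base.domain)
        self.base = base
        self.factor = float(factor)
        self.kind = base.kind

    def _evaluate(self, r):
        return self.factor * self.base._evaluate(r)

    def ring_mass(self, p, q):
        return self.factor * self.base.ring_mass(p, q)

    def cumulative_mass(self, r):
        return self.factor * self.base.cumulative_mass(r)

    def max_density(self):
        return self.factor * self.base.max_density()


# -- constructors ------------------------------------------------------------


def gaussian_density(n0: float, sigma: float, domain: Domain = Domain()) -> GaussianDensity:
    return GaussianDensity(GaussianParams(n0=n0, sigma=sigma), domain)


def fermi_density(a1: float, b1: float, c1: float, domain: Domain = Domain()) -> FermiDensity:
    return FermiDensity(FermiParams(a1=a1, b1=b1, c1=c1), domain)


def gridded_density(radii, values, domain: Domain | None = None) -> GriddedDensity:
    return GriddedDensity(radii, values, domain)


def total_cells(density: RadialDensity) -> float:
    """Total cell number on the disc (convenience wrapper)."""
    return density.total_cells()


def n0_for_total(N_total: float, sigma: float, R: float) -> float:
    """Central density n0 of a Gaussian with given total cell number.

    Inverts the closed form N = 2*pi*n0*sigma^2*(1 - exp(-R^2/2 sigma^2)).
    """
    if not N_total > 0:
        raise ValueError(f"N_total must be positive, got {N_total}")
    s2 = sigma**2
    return N_total / (2.0 * np.pi * s2 * (1.0 - np.exp(-(R**2) / (2 * s2))))


# -- PDE evolution -----------------------------------------------------------


class PDEInstabilityError(RuntimeError):
    """Raised when the explicit time stepper produces negative/exploding values."""


def evolve_pde(
    density: RadialDensity,
    growth: GrowthParams,
    t: float,
    dt: float | None = None,
    grid_n: int | None = None,
) -> GriddedDensity:
    """Evolve a radial density under diffusion + (exponential|logistic) growth.

    Solves dn/dt = D_n*(1/r) d/dr(r dn/dr) + rho*n*(1 - a*n/n_max) on [0, R]
    with zero-flux boundaries, using a conservative mass-lumped linear-element
    discretisation (the r=0 coordinate singularity is handled by the finite
    control volume of the first node) and classical RK4 time stepping.  The
    spatial operator conserves the piecewise-linear mass functional exactly
    when rho = 0.

    Parameters
    ----------
    t : float
        Evolution time (days).
    dt : float, optional
        Time step (days); defaults to a diffusion-stable value
        0.2*h^2/D_n (capped by the reaction time scale).

    Returns
    -------
    GriddedDensity on a uniform radial grid.
    """
    if t < 0:
        raise ValueError("evolution time must be >= 0")
    M = grid_n or density.domain.grid_n
    R = density.domain.R
    r = np.linspace(0.0, R, M)
    h = r[1] - r[0]
    n = density.density_at(r).astype(float).copy()
    if t == 0:
        return GriddedDensity(r, n, density.domain)

    # control volumes v_i = int r * phi_i(r) dr  (exact for hat functions)
    v = np.empty(M)
    v[1:-1] = h * r[1:-1]
    v[0] = h**2 / 6.0
    v[-1] = R * h / 2.0 - h**2 / 6.0
    r_half = 0.5 * (r[:-1] + r[1:])

    def rhs(u):
        flux = growth.D_n * r_half * np.diff(u) / h  # zero flux beyond ends
        du = np.empty_like(u)
        du[0] = flux[0] / v[0]
        du[1:-1] = np.diff(flux) / v[1:-1]
        du[-1] = -flux[-1] / v[-1]
        if growth.rho:
            if growth.mode_a == 1:
                du += growth.rho * u * (1.0 - u / growth.n_max)
            else:
                du += growth.rho * u
        return du

    if dt is None:
        dt_diff = 0.2 * h**2 / growth.D_n if growth.D_n > 0 else np.inf
        dt_reac = 0.1 / growth.rho if growth.rho > 0 else np.inf
        dt = min(dt_diff, dt_reac, t)
    n_steps = max(1, int(np.ceil(t / dt)))
    step = t / n_steps

    cap = density.max_density() * np.exp(growth.rho * t) * 10.0 + 1e3
    if growth.mode_a == 1:
        cap = max(cap, growth.n_max * 2.0)
    for _ in range(n_steps):
        k1 = rhs(n)
        k2 = rhs(n + 0.5 * step * k1)
        k3 = rhs(n + 0.5 * step * k2)
        k4 = rhs(n + step * k3)
        n = n + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(n)) or np.max(n) > cap or np.min(n) < -1e-6 * np.max(np.abs(n)):
            raise PDEInstabilityError(
                "PDE time stepping unstable (negative or exploding density); "
                f"retry with a smaller dt than {step:g}"
            )
    return GriddedDensity(r, np.maximum(n, 0.0), density.domain)


# -- Fermi fitting -----------------------------------------------------------


class FermiFitError(RuntimeError):
    """Raised when a Fermi-function fit does not converge or is degenerate."""


def fit_fermi(density: GriddedDensity) -> tuple[FermiParams, float]:
    """Least-squares Fermi-function fit to a gridded density.

    Fits n(r) = a1/(1 + b1*exp(c1*r^2)) over the grid by minimising the sum
    of squared residuals, multi-starting over both sign patterns of (b1, c1)
    since flat-topped profiles admit both parameterisations.

    Returns
    -------
    (FermiParams, residual_norm)

    Raises
    ------
    FermiFitError
        On non-convergence or an (unidentifiable) flat input.
    """
    r = np.asarray(density.radii, dtype=float)
    y = np.asarray(density.values, dtype=float)
    if len(r) < 10:
        raise FermiFitError("need at least 10 grid points to fit")
    if np.any(y <= 0):
        raise FermiFitError("Fermi fit requires strictly positive densities")
    span = (y.max() - y.min()) / y.max()
    if span < 1e-8:
        raise FermiFitError(
            "density is constant to within 1e-8: c1 is unidentifiable"
        )
    s = r**2

    def model(theta, sq):
        a1, b1, c1 = theta
        return a1 / (1.0 + b1 * np.exp(np.clip(c1 * sq, -700, 700)))

    def resid(theta):
        return model(theta, s) - y

    # seed c1 magnitude from the log-slope of a1/y - 1 over the decaying tail
    starts = []
    a0 = y.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        g = a0 * 1.0000001 / y - 1.0
        ok = g > 1e-9
        if ok.sum() >= 3:
            slope, intercept = np.polyfit(s[ok], np.log(g[ok]), 1)
            starts.append((a0, np.exp(intercept), slope))
    # generic sign multi-start
    c_mag = 2.0 / max(s[-1], 1e-12)
    starts.append((a0, 0.5, c_mag))
    starts.append((a0 * (1 + 1e-3), -0.5, -c_mag))

    best = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(
                resid, theta0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=20000
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e-6 * np.sum(y**2):
        raise FermiFitError("Fermi fit failed to converge from all starts")
    a1, b1, c1 = best.x
    params = FermiParams(a1=float(a1), b1=float(b1), c1=float(c1))
    return params, float(np.sqrt(2.0 * best.cost))


def grow_between_fractions(
    density: RadialDensity,
    rho: float,
    tau: float,
    sigma_ref: float | None = None,
    D_n: float = 0.0,
) -> RadialDensity:
    """Inter-fraction growth: scale the density by e^{rho*tau}.

    Valid when diffusion is negligible over the gap, i.e. D_n*tau << sigma^2;
    a warning is emitted when D_n*tau > 0.1*sigma_ref^2.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        return density
    if sigma_ref is not None and D_n * tau > 0.1 * sigma_ref**2:
        warnings.warn(
            f"shape-preserving growth assumption dubious: D_n*tau = {D_n * tau:g} "
            f"exceeds 0.1*sigma_ref^2 = {0.1 * sigma_ref**2:g}",
            stacklevel=2,
        )
    factor = float(np.exp(rho * tau))
    if isinstance(density, GaussianDensity):
        return GaussianDensity(
            GaussianParams(n0=density.params.n0 * factor, sigma=density.params.sigma),
            density.domain,
        )
    if isinstance(density, GriddedDensity):
        return GriddedDensity(density.radii, density.values * factor, density.domain)
    return ScaledDensity(density, factor)
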