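"""Analytic optimal continuous beam profiles for one fraction.

The objective is the total number of cells surviving the fraction,
minimised over the cytotoxic profile f(r) >= 0 under the total-flux
constraint int f d^2x = F (and optionally the pointwise cap f <= C).
Throughout this module strengths are expressed in kill units, i.e.
gamma * delta_t = 1, so the exponential survival map is n -> n e^{-f}.

With exponential death the Euler-Lagrange condition gives
f = ln(n / lambda) truncated at 0 (and clipped at C when capped): dose is
spent where density is high, and the post-treatment density is flat at the
multiplier value lambda inside the beam support.  For a Gaussian tumour the
uncapped optimum is the parabolic ("semi-circular") beam of
:func:`semicircle_beam`.

With logistic (saturable) death the pointwise stationarity condition is a
quadratic in the survival factor w = e^{-f}; the admissible root

    w = (n_max - n) * [(n_max - 2*lambda) - sqrt(n_max*(n_max - 4*lambda))]
        / (2 * lambda * n)

recovers w = lambda/n (i.e. f = ln(n/lambda)) as n_max -> inf.  For
n > n_max/2 the pointwise problem is non-convex, so the profile picks the
global minimiser of the pointwise Lagrangian among {0, interior root, cap}:
near-saturated regions receive no dose because killing there is inefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .density import RadialDensity

__all__ = [
    "ContinuousSolution",
    "SemicircleBeam",
    "InfeasibleFluxError",
    "optimal_continuous_exponential",
    "optimal_continuous_logistic",
    "semicircle_beam",
]

_GRID_N = 16385  # Simpson grid for flux integrals


class InfeasibleFluxError(ValueError):
    """The flux budget cannot be met under the strength cap."""


@dataclass
class ContinuousSolution:
    """An optimal continuous profile f(r) with its Lagrange multiplier."""

    lambda_mult: float
    profile: callable
    support_radius: float
    capped: bool
    flux: float

    def __call__(self, r):
        return self.profile(np.asarray(r, dtype=float))


def _flux_of(profile, R: float) -> float:
    r = np.linspace(0.0, R, _GRID_N)
    from scipy.integrate import simpson

    return float(simpson(2.0 * np.pi * r * profile(r), x=r))


def _support_radius(profile, R: float) -> float:
    r = np.linspace(0.0, R, _GRID_N)
    f = np.asarray(profile(r))
    nz = np.nonzero(f > 0)[0]
    return float(r[nz[-1]]) if len(nz) else 0.0


def optimal_continuous_exponential(
    density: RadialDensity, F: float, C: float | None = None
) -> ContinuousSolution:
    """Optimal continuous profile under exponential death.

    f(r) = clip(ln(n(r)/lambda), 0, C), with lambda solved by bracketed
    root finding so that the flux constraint 2*pi*int r f dr = F is
    saturated.  Works for any positive density; for a Gaussian the result
    is the truncated parabola of :func:`semicircle_beam`.
    """
    if not F > 0:
        raise ValueError("flux budget F must be positive")
    R = density.domain.R
    r_grid = np.linspace(0.0, R, _GRID_N)
    n_grid = np.asarray(density.density_at(r_grid), dtype=float)
    n_peak = float(np.max(n_grid))
    if n_peak <= 0:
        raise ValueError("density must be positive somewhere")
    if C is not None and F > C * np.pi * R**2 * (1 + 1e-12):
        raise InfeasibleFluxError(
            f"budget F={F:g} exceeds the maximum deliverable flux "
            f"C*pi*R^2={C * np.pi * R**2:g}"
        )

    def make_profile(lam):
        def profile(r):
            n = np.asarray(density.density_at(r), dtype=float)
            with np.errstate(divide="ignore"):
                f = np.where(n > 0, np.log(np.maximum(n, 1e-300) / lam), -np.inf)
            f = np.maximum(f, 0.0)
            if C is not None:
                f = np.minimum(f, C)
            return f

        return profile

    def residual(log_lam):
        return _flux_of(make_profile(np.exp(log_lam)), R) - F

    # flux is monotone decreasing in lambda: bracket between n_peak (flux 0)
    # and a lambda small enough to overshoot the budget
    hi = np.log(n_peak)
    lo = hi - 1.0
    while residual(lo) < 0:
        lo -= 2.0
        if hi - lo > 800:
            raise InfeasibleFluxError("flux budget unreachable on this domain")
    log_lam = optimize.brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16)
    lam = float(np.exp(log_lam))
    profile = make_profile(lam)
    capped = C is not None and bool(np.any(np.asarray(profile(r_grid)) >= C * (1 - 1e-9)))
    return ContinuousSolution(
        lambda_mult=lam,
        profile=profile,
        support_radius=_support_radius(profile, R),
        capped=capped,
        flux=_flux_of(profile, R),
    )


@dataclass(frozen=True)
class SemicircleBeam:
    """Truncated-parabola beam f(r) = f_m * (1 - r^2/r_m^2) for r <= r_m."""

    f_m: float
    r_m: float
    d: int

    def __call__(self, r):
        r_arr = np.asarray(r, dtype=float)
        out = self.f_m * (1.0 - r_arr**2 / self.r_m**2)
        return np.maximum(out, 0.0)


def semicircle_beam(F: float, sigma: float, d: int = 2) -> SemicircleBeam:
    """Closed-form optimal beam for a Gaussian tumour (uncapped).

    r_m = [d(d+2)/S_d]^{1/(d+2)} * F^{1/(d+2)} * sigma^{2/(d+2)}, with solid
    angles S_2 = 2*pi, S_3 = 4*pi, and peak strength f_m = r_m^2/(2 sigma^2).
    The support radius grows sub-linearly with tumour size (r_m ~ sigma^{1/2}
    in d=2).
    """
    if not (F > 0 and sigma > 0):
        raise ValueError("F and sigma must be positive")
    if d not in (2, 3):
        raise ValueError("dimension d must be 2 or 3")
    S_d = 2.0 * np.pi if d == 2 else 4.0 * np.pi
    r_m = (d * (d + 2) / S_d) ** (1.0 / (d + 2)) * F ** (1.0 / (d + 2)) * sigma ** (2.0 / (d + 2))
    f_m = r_m**2 / (2.0 * sigma**2)
    return SemicircleBeam(f_m=float(f_m), r_m=float(r_m), d=d)


def _logistic_pointwise_dose(n, lam, n_max, C=None):
    """Pointwise optimal dose under logistic death for given multiplier lambda.

    Minimises L(f) = S(n, f) + lambda*f over f in [0, C] where
    S(n, f) = n_max*n*e^{-f}/(n_max - n*(1 - e^{-f})).  Candidates: the
    boundary f=0, the interior stationary root, and the cap.
    """
    n = np.asarray(n, dtype=float)
    m = n_max

    def S(nv, f):
        ex = np.exp(-f)
        return m * nv * ex / (m - nv * (1.0 - ex))

    candidates = [np.zeros_like(n)]
    disc = m * (m - 4.0 * lam)
    if disc >= 0 and lam > 0:
        # stable conjugate form of (m - n)*[(m-2l) - sqrt(m(m-4l))]/(2 l n)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = 2.0 * lam * (m - n) / (n * ((m - 2.0 * lam) + np.sqrt(disc)))
        valid = (w > 0) & (w < 1) & np.isfinite(w)
        f_int = np.where(valid, -np.log(np.where(valid, w, 1.0)), 0.0)
        if C is not None:
            f_int = np.minimum(f_int, C)
        candidates.append(f_int)
    if C is not None:
        candidates.append(np.full_like(n, float(C)))

    best_f = candidates[0]
    best_L = S(n, best_f) + lam * best_f
    for f in candidates[1:]:
        L = S(n, f) + lam * f
        better = L < best_L
        best_f = np.where(better, f, best_f)
        best_L = np.where(better, L, best_L)
    return best_f


def optimal_continuous_logistic(
    density: RadialDensity, F: float, n_max: float, C: float | None = None
) -> ContinuousSolution:
    """Optimal continuous profile under logistic (saturable) death.

    The stationarity condition is re-derived from the exact logistic
    survival map (see module docstring); lambda is solved from the flux
    constraint by bracketed root finding.  As n_max -> inf the exponential
    optimum f = ln(n/lambda) is recovered.
    """
    if not F > 0:
        raise ValueError("flux budget F must be positive")
    R = density.domain.R
    peak = density.max_density()
    if peak >= n_max:
        raise ValueError(
            f"density ({peak:g}) must lie strictly below n_max ({n_max:g})"
        )
    if C is not None and F > C * np.pi * R**2 * (1 + 1e-12):
        raise InfeasibleFluxError(
            f"budget F={F:g} exceeds the maximum deliverable flux "
            f"C*pi*R^2={C * np.pi * R**2:g}"
        )

    def make_profile(lam):
        def profile(r):
            n = np.asarray(density.density_at(r), dtype=float)
            return _logistic_pointwise_dose(n, lam, n_max, C)

        return profile

    def residual(log_lam):
        return _flux_of(make_profile(np.exp(log_lam)), R) - F

    # flux is non-increasing in lambda; lambda is bounded above by n_max/4
    # (beyond it no interior stationary dose exists anywhere)
    hi = np.log(n_max / 4.0) - 1e-12
    lo = hi - 1.0
    while residual(lo) < 0:
        lo -= 2.0
        if hi - lo > 800:
            raise InfeasibleFluxError("flux budget unreachable on this domain")
    if residual(hi) > 0:
        lam = n_max / 4.0  # budget already exceeded at the smallest doses
    else:
        lam = float(np.exp(optimize.brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16)))
    profile = make_profile(lam)
    r_grid = np.linspace(0.0, R, _GRID_N)
    capped = C is not None and bool(np.any(np.asarray(profile(r_grid)) >= C * (1 - 1e-9)))
    return ContinuousSolution(
        lambda_mult=lam,
        profile=profile,
        support_radius=_support_radius(profile, R),
        capped=capped,
        flux=_flux_of(profile, R),
    )
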