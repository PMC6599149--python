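"""Reference study conditions and table reproduction.

The canonical parameter sets: five Gaussian tumours (sigma = 1..5 mm, each
normalised to 1e7 total cells on the R = 10 mm disc) and three Fermi-function
densities fitted to logistic-growth profiles.  Each ``reproduce_*`` function
runs the corresponding optimisation case and returns a DataFrame with the
canonical column layout (radii in mm, strengths in kill units, N in cells).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .density import Domain, fermi_density, gaussian_density, n0_for_total
from .discrete import (
    DiscreteProblem,
    mc_optimize,
    onestep_optimal,
    two_fraction_optimize,
)
from .radiation import RadiationParams

__all__ = [
    "GAUSSIAN_SIGMAS",
    "FERMI_FITS",
    "reference_gaussian",
    "reference_fermi",
    "reproduce_table2",
    "reproduce_table3",
    "reproduce_table4",
    "reproduce_table5",
    "reproduce_table8",
]

#: sigma values (mm) of the five reference Gaussian tumours
GAUSSIAN_SIGMAS = (1.0, 2.0, 3.0, 4.0, 5.0)

#: total initial cell number shared by all reference tumours
N_TOTAL = 1e7

#: canonical central densities n0 (cells/mm^2) of the reference tumours,
#: i.e. n0_for_total(1e7, sigma, 10) quoted to three significant figures
GAUSSIAN_N0 = {1.0: 1.59e6, 2.0: 3.98e5, 3.0: 1.78e5, 4.0: 1.04e5, 5.0: 7.36e4}

#: Fermi-function coefficients (a1, b1, c1) fitted to logistic-growth
#: profiles, keyed by the sigma of the seeding Gaussian
FERMI_FITS = {
    1.0: (2.0697e6, 0.4237, 0.04007),
    3.0: (1.0978e6, -0.3069, -0.004395),
    5.0: (1553387.0, -0.02081, -0.01505),
}


def reference_gaussian(sigma: float, domain: Domain = Domain()):
    """The reference Gaussian tumour of given sigma (~1e7 cells total).

    Uses the canonical 3-significant-figure n0 when sigma is one of the
    reference values, and the exact normalisation otherwise.
    """
    n0 = GAUSSIAN_N0.get(sigma) or n0_for_total(N_TOTAL, sigma, domain.R)
    return gaussian_density(n0, sigma, domain)


def reference_fermi(sigma: float, domain: Domain = Domain()):
    """The reference logistic-growth (Fermi) density for a given sigma key."""
    a1, b1, c1 = FERMI_FITS[sigma]
    return fermi_density(a1, b1, c1, domain)


def _default_radiation() -> RadiationParams:
    return RadiationParams()


def reproduce_table2(radiation: RadiationParams | None = None) -> pd.DataFrame:
    """One fraction, one radial step, exponential growth and death."""
    rad = radiation or _default_radiation()
    rows = []
    for sigma in GAUSSIAN_SIGMAS:
        density = reference_gaussian(sigma)
        prob = DiscreteProblem(density=density, radiation=rad, n_steps=1)
        res = onestep_optimal(prob)
        (r1, f1), = res.profiles[0].breaks
        rows.append(dict(sigma=sigma, n0=density.params.n0, r1=r1, f1=f1, N=res.N_final))
    return pd.DataFrame(rows)


def reproduce_table3(
    radiation: RadiationParams | None = None,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """One fraction, two radial steps, exponential growth and death."""
    rad = radiation or _default_radiation()
    rows = []
    for k, sigma in enumerate(GAUSSIAN_SIGMAS):
        density = reference_gaussian(sigma)
        prob = DiscreteProblem(density=density, radiation=rad, n_steps=2)
        res = mc_optimize(prob, n_samples=n_samples, seed=seed + k)
        b = res.profiles[0].breaks
        (r1, f1) = b[0]
        (r2, f2) = b[1] if len(b) > 1 else (r1, 0.0)
        rows.append(dict(sigma=sigma, r1=r1, r2=r2, f1=f1, f2=f2, N=res.N_final))
    return pd.DataFrame(rows)


def _two_fraction_rows(constraint_mode, radiation, n_samples, seed, tau):
    rad = radiation or _default_radiation()
    rows = []
    for k, sigma in enumerate(GAUSSIAN_SIGMAS):
        density = reference_gaussian(sigma)
        prob = DiscreteProblem(
            density=density, radiation=rad, n_steps=2, n_fractions=2,
            constraint_mode=constraint_mode, tau=tau,
        )
        res = two_fraction_optimize(prob, n_samples=n_samples, seed=seed + 10 * k)
        row = dict(sigma=sigma)
        for j, prof in enumerate(res.profiles, start=1):
            b = prof.breaks
            (r1, f1) = b[0]
            (r2, f2) = b[1] if len(b) > 1 else (r1, 0.0)
            row.update({f"r1{j}": r1, f"r2{j}": r2, f"f1{j}": f1, f"f2{j}": f2})
        row["N"] = res.N_final
        rows.append(row)
    return pd.DataFrame(rows)


def reproduce_table4(radiation=None, n_samples: int = 1_000_000, seed: int = 0,
                     tau: float = 0.0) -> pd.DataFrame:
    """Two two-step fractions, separately constrained."""
    return _two_fraction_rows("per_fraction", radiation, n_samples, seed, tau)


def reproduce_table5(radiation=None, n_samples: int = 1_000_000, seed: int = 0,
                     tau: float = 0.0) -> pd.DataFrame:
    """Two two-step fractions, mutually constrained (joint budget 2F')."""
    return _two_fraction_rows("total", radiation, n_samples, seed, tau)


def reproduce_table8(radiation=None, n_samples: int = 1_000_000, seed: int = 0) -> pd.DataFrame:
    """One two-step fraction on the logistic-growth (Fermi) densities."""
    rad = radiation or _default_radiation()
    rows = []
    for k, sigma in enumerate(sorted(FERMI_FITS)):
        density = reference_fermi(sigma)
        prob = DiscreteProblem(density=density, radiation=rad, n_steps=2)
        res = mc_optimize(prob, n_samples=n_samples, seed=seed + k)
        b = res.profiles[0].breaks
        (r1, f1) = b[0]
        (r2, f2) = b[1] if len(b) > 1 else (r1, 0.0)
        rows.append(dict(sigma=sigma, r1=r1, r2=r2, f1=f1, f2=f2, N=res.N_final))
    return pd.DataFrame(rows)
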