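"""CSV readers/writers for density profiles and step beams."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .density import Domain, GriddedDensity, RadialDensity
from .radiation import StepProfile

__all__ = [
    "write_density_csv",
    "read_density_csv",
    "write_profile_csv",
    "read_profile_csv",
]

DENSITY_COLUMNS = ["r_mm", "density_cells_per_mm2"]
PROFILE_COLUMNS = ["outer_radius_mm", "strength"]


def write_density_csv(density: RadialDensity, path, n_points: int = 257) -> None:
    """Write a density sampled on a uniform radial grid as 2-column CSV."""
    if isinstance(density, GriddedDensity):
        r, v = density.radii, density.values
    else:
        r = np.linspace(0.0, density.domain.R, n_points)
        v = np.asarray(density.density_at(r))
    pd.DataFrame({DENSITY_COLUMNS[0]: r, DENSITY_COLUMNS[1]: v}).to_csv(path, index=False)


def read_density_csv(path) -> GriddedDensity:
    df = pd.read_csv(path)
    missing = [c for c in DENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"density CSV missing columns {missing}")
    r = df[DENSITY_COLUMNS[0]].to_numpy(dtype=float)
    v = df[DENSITY_COLUMNS[1]].to_numpy(dtype=float)
    return GriddedDensity(r, v, Domain(R=float(r[-1])))


def write_profile_csv(profile: StepProfile, path) -> None:
    pd.DataFrame(
        {
            PROFILE_COLUMNS[0]: [r for r, _ in profile.breaks],
            PROFILE_COLUMNS[1]: [f for _, f in profile.breaks],
        }
    ).to_csv(path, index=False)


def read_profile_csv(path) -> StepProfile:
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV missing columns {missing}")
    return StepProfile(list(zip(df[PROFILE_COLUMNS[0]], df[PROFILE_COLUMNS[1]])))
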