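"""YAML run configuration for the command-line interface.

A config file is a nested key/value document; every model constant defaults
to the reference values (D_n=0.32 mm^2/day, rho=0.35/day, gamma=60/day,
dt=0.007 day, C=2.5, F'=25 mm^2, R=10 mm) and can be overridden per run.

Example::

    domain:    {R: 10.0, grid_n: 256}
    growth:    {D_n: 0.32, rho: 0.35, mode_a: 0}
    radiation: {gamma: 60.0, delta_t: 0.007, cap_C: 2.5, budget_Fprime: 25.0}
    density:   {kind: gaussian, n0: 1.78e5, sigma: 3.0}
    problem:   {n_steps: 2, n_fractions: 1, constraint_mode: per_fraction, tau: 0.0}
    search:    {n_samples: 1000000, seed: 0}
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .density import Domain, GrowthParams, RadialDensity, fermi_density, gaussian_density
from .io import read_density_csv
from .radiation import RadiationParams

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


@dataclass
class RunConfig:
    domain: Domain = field(default_factory=Domain)
    growth: GrowthParams = field(default_factory=GrowthParams)
    radiation: RadiationParams = field(default_factory=RadiationParams)
    density_spec: dict = field(default_factory=lambda: {"kind": "gaussian", "n0": 1.78e5, "sigma": 3.0})
    n_steps: int = 2
    n_fractions: int = 1
    constraint_mode: str = "per_fraction"
    tau: float = 0.0
    n_max: float | None = None
    optimizer: str = "discrete"
    evolve_t: float = 10.0
    evolve_dt: float | None = None
    n_samples: int = 1_000_000
    seed: int = 0

    def build_density(self) -> RadialDensity:
        spec = dict(self.density_spec)
        kind = spec.pop("kind", "gaussian")
        try:
            if kind == "gaussian":
                return gaussian_density(float(spec["n0"]), float(spec["sigma"]), self.domain)
            if kind == "fermi":
                return fermi_density(
                    float(spec["a1"]), float(spec["b1"]), float(spec["c1"]), self.domain
                )
            if kind == "csv":
                path = spec["path"]
                if not os.path.exists(path):
                    raise ConfigError(f"density.path: file not found: {path}")
                return read_density_csv(path)
        except KeyError as e:
            raise ConfigError(f"density: missing field {e.args[0]!r} for kind={kind!r}") from e
        raise ConfigError(f"density.kind: unknown kind {kind!r}")


def _section(doc: dict, name: str) -> dict:
    sec = doc.get(name, {})
    if not isinstance(sec, dict):
        raise ConfigError(f"{name}: expected a mapping, got {type(sec).__name__}")
    return sec


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")

    def build(cls, sec_name, **extra):
        sec = _section(doc, sec_name)
        try:
            return cls(**{**sec, **extra})
        except (TypeError, ValueError) as e:
            raise ConfigError(f"{sec_name}: {e}") from e

    domain = build(Domain, "domain")
    growth = build(GrowthParams, "growth")
    radiation = build(RadiationParams, "radiation")
    density_spec = _section(doc, "density") or {"kind": "gaussian", "n0": 1.78e5, "sigma": 3.0}
    problem = _section(doc, "problem")
    search = _section(doc, "search")
    cfg = RunConfig(
        domain=domain,
        growth=growth,
        radiation=radiation,
        density_spec=density_spec,
        n_steps=int(problem.get("n_steps", 2)),
        n_fractions=int(problem.get("n_fractions", 1)),
        constraint_mode=problem.get("constraint_mode", "per_fraction"),
        tau=float(problem.get("tau", 0.0)),
        n_max=(None if problem.get("n_max") is None else float(problem["n_max"])),
        optimizer=problem.get("optimizer", "discrete"),
        evolve_t=float(problem.get("evolve_t", 10.0)),
        evolve_dt=(None if problem.get("evolve_dt") is None else float(problem["evolve_dt"])),
        n_samples=int(search.get("n_samples", 1_000_000)),
        seed=int(search.get("seed", 0)),
    )
    if cfg.n_steps not in (1, 2):
        raise ConfigError(f"problem.n_steps: must be 1 or 2, got {cfg.n_steps}")
    if cfg.n_fractions not in (1, 2):
        raise ConfigError(f"problem.n_fractions: must be 1 or 2, got {cfg.n_fractions}")
    if cfg.constraint_mode not in ("per_fraction", "total"):
        raise ConfigError(f"problem.constraint_mode: {cfg.constraint_mode!r}")
    if cfg.optimizer not in ("discrete", "continuous"):
        raise ConfigError(f"problem.optimizer: {cfg.optimizer!r}")
    if cfg.tau < 0:
        raise ConfigError("problem.tau: must be >= 0")
    if cfg.n_samples < 1:
        raise ConfigError("search.n_samples: must be >= 1")
    cfg.build_density()  # validate the density spec eagerly
    return cfg
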