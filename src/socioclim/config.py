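"""Configuration: YAML parameter tables, triangular distributions, overrides.

The packaged ``data/baseline.yaml`` holds the baseline values and the
triangular (lower / mode / upper) bounds used by every experiment; users can
copy and edit it.  Parameter names used in distributions and overrides are
flat (``kappa``, ``solar_flux``, ``eps_max``...) and are resolved onto the
social / climate / forcing sections through a registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from .earth import ClimateParams
from .forcing import (
    load_historical_emissions,
    make_schedule,
    stylised_historical_emissions,
    synth_historical_emissions,
)
from .simulate import ScenarioConfig

__all__ = [
    "ParameterDistribution",
    "load_config",
    "default_config",
    "apply_overrides",
    "config_to_dict",
]

SOCIAL_FIELDS = frozenset(
    {"kappa", "beta", "delta", "fmax", "omega", "Tc", "tf", "tp", "x0"}
)
CLIMATE_FIELDS = frozenset(ClimateParams.__dataclass_fields__)
FORCING_FIELDS = frozenset({"eps_max", "s"})


@dataclass(frozen=True)
class ParameterDistribution:
    """Triangular distribution on [lower, upper] peaking at the baseline mode."""

    name: str
    lower: float
    mode: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.mode <= self.upper:
            raise ValueError(
                f"{self.name}: need lower <= mode <= upper, "
                f"got {self.lower}, {self.mode}, {self.upper}"
            )

    @property
    def degenerate(self) -> bool:
        return self.lower == self.upper

    def sample(self, rng: np.random.Generator) -> float:
        """One draw; deterministic given the generator state."""
        if self.degenerate:
            return self.mode
        return float(rng.triangular(self.lower, self.mode, self.upper))


def apply_overrides(config: ScenarioConfig, overrides: Mapping[str, float]) -> ScenarioConfig:
    """Return a config with the named flat parameters replaced.

    Unknown names raise ``KeyError``; social overrides drop any stored raw
    parameterisation so the reduced form stays authoritative.
    """
    social_ch, climate_ch, forcing_ch = {}, {}, {}
    for name, value in overrides.items():
        if name in SOCIAL_FIELDS:
            social_ch[name] = float(value)
        elif name in FORCING_FIELDS:
            forcing_ch[name] = float(value)
        elif name in CLIMATE_FIELDS:
            climate_ch[name] = float(value)
        else:
            raise KeyError(f"unknown parameter name {name!r}")
    out = config
    if social_ch:
        out = out.replace(social=out.social.with_(**social_ch))
    if climate_ch:
        out = out.replace(climate=out.climate.replace(**climate_ch))
    if forcing_ch:
        out = out.replace(schedule=out.schedule.replace(**forcing_ch))
    return out


def _build(
    raw: dict,
    emissions: Optional[str] = None,
    synthetic: bool = False,
    synthetic_seed: int = 0,
) -> tuple[ScenarioConfig, dict[str, ParameterDistribution]]:
    from .social import SocialParams  # local import keeps module load light

    def _floats(d: dict) -> dict:
        # PyYAML leaves exponents like 6.3e8 as strings; coerce numerics.
        return {k: float(v) for k, v in d.items()}

    social = SocialParams(**_floats(raw["social"]))
    climate = ClimateParams(**_floats(raw["climate"]))
    forcing = dict(raw.get("forcing", {}))
    eps_max = float(forcing.get("eps_max", 15.0))
    s = float(forcing.get("s", 50.0))
    if emissions is not None:
        hist = load_historical_emissions(emissions)
    elif synthetic:
        hist = synth_historical_emissions(end_rate=10.8, seed=synthetic_seed)
    else:
        hist = stylised_historical_emissions()
    schedule = make_schedule(hist, eps_max=eps_max, s=s)
    sim = raw.get("simulation", {})
    config = ScenarioConfig(
        social=social,
        climate=climate,
        schedule=schedule,
        start_year=float(sim.get("start_year", 1800)),
        behaviour_start_year=float(sim.get("behaviour_start_year", 2014)),
        horizon_end=float(sim.get("horizon_end", 2200)),
        rtol=float(sim.get("rtol", 1e-8)),
        atol=float(sim.get("atol", 1e-10)),
    )
    dists = {
        d["name"]: ParameterDistribution(**d) for d in raw.get("distributions", [])
    }
    return config, dists


def load_config(
    path: str | Path,
    emissions: Optional[str] = None,
    synthetic: bool = False,
    synthetic_seed: int = 0,
) -> tuple[ScenarioConfig, dict[str, ParameterDistribution]]:
    """Load a YAML parameter table; returns (config, distributions)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _build(raw, emissions=emissions, synthetic=synthetic, synthetic_seed=synthetic_seed)


def default_config(
    emissions: Optional[str] = None,
    synthetic: bool = False,
    synthetic_seed: int = 0,
) -> tuple[ScenarioConfig, dict[str, ParameterDistribution]]:
    """Baseline configuration shipped with the package."""
    text = resources.files("socioclim").joinpath("data/baseline.yaml").read_text()
    raw = yaml.safe_load(text)
    return _build(raw, emissions=emissions, synthetic=synthetic, synthetic_seed=synthetic_seed)


def config_to_dict(config: ScenarioConfig) -> dict:
    """Flatten a config back into the YAML layout (minus the emission table)."""
    social = {
        k: getattr(config.social, k)
        for k in SOCIAL_FIELDS
    }
    climate = {k: getattr(config.climate, k) for k in CLIMATE_FIELDS}
    return {
        "social": social,
        "climate": climate,
        "forcing": {"eps_max": config.schedule.eps_max, "s": config.schedule.s},
        "simulation": {
            "start_year": config.start_year,
            "behaviour_start_year": config.behaviour_start_year,
            "horizon_end": config.horizon_end,
            "rtol": config.rtol,
            "atol": config.atol,
        },
    }
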