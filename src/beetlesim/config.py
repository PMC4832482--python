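"""Flat run configuration: defaults, YAML round-trip, validation.

One :class:`RunConfig` merges the habitat, trait and engine parameter
groups plus the scenario and seed; every field defaults to the standard
model parameterization.  Unknown keys in a config file are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .engine import EngineParams
from .habitat import HABITAT_TYPES, HabitatConfig
from .population import SCENARIOS, TraitConfig, VariabilityScenario, get_scenario


@dataclass(frozen=True)
class RunConfig:
    # habitat
    habitat_type: str = "resistant"
    grid_side: int = 448
    patch_size: float = 5.0
    scattered_fraction: float = 1.0
    scattered_pa: int = 8
    # beetle traits / schedule
    energy_mean: float = 10.0
    energy_sd: float = 2.0
    efficiency_mean: float = 20.0
    efficiency_floor: float = 0.1
    cohort_size: int = 10_000
    n_cohorts: int = 10
    time_lag: int = 10
    perceptual_range: float = 15.0
    turn_angle: float = 45.0
    # engine
    pheromone_attractiveness: float = 10.0
    attack_coefficient: float = 0.9
    capacity_limit: int = 5_000
    max_steps: int = 2_000
    threshold_scale: float = 1.0
    # run
    scenario: str = "S0"
    seed: int = 0

    def __post_init__(self) -> None:
        # delegate validation to the component configs
        self.habitat_config()
        self.trait_config()
        self.engine_params()
        get_scenario(self.scenario)

    # -- component views ---------------------------------------------

    def habitat_config(self) -> HabitatConfig:
        return HabitatConfig(
            habitat_type=self.habitat_type,
            grid_side=self.grid_side,
            patch_size=self.patch_size,
            scattered_fraction=self.scattered_fraction,
            scattered_pa=self.scattered_pa,
        )

    def trait_config(self) -> TraitConfig:
        return TraitConfig(
            energy_mean=self.energy_mean,
            energy_sd=self.energy_sd,
            efficiency_mean=self.efficiency_mean,
            efficiency_floor=self.efficiency_floor,
            cohort_size=self.cohort_size,
            n_cohorts=self.n_cohorts,
            time_lag=self.time_lag,
            perceptual_range=self.perceptual_range,
            turn_angle=self.turn_angle,
        )

    def engine_params(self) -> EngineParams:
        return EngineParams(
            pheromone_attractiveness=self.pheromone_attractiveness,
            attack_coefficient=self.attack_coefficient,
            capacity_limit=self.capacity_limit,
            max_steps=self.max_steps,
            threshold_scale=self.threshold_scale,
        )

    def scenario_obj(self) -> VariabilityScenario:
        return get_scenario(self.scenario)

    # -- (de)serialization -------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict, **cli_overrides) -> "RunConfig":
        """Build a config from file values with CLI flags taking precedence."""
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(raw)
        merged.update({k: v for k, v in cli_overrides.items() if v is not None})
        return cls(**merged)

    @classmethod
    def from_file(cls, path, **cli_overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a key-value mapping")
        return cls.from_dict(raw, **cli_overrides)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable digest identifying this exact parameterization."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
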