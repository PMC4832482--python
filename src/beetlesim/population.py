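"""Dispersing beetle population: trait sampling and cohort schedule.

Each beetle carries an initial energy budget ``E`` (Gaussian, mean 10,
sd 2) and a flight efficiency ``eps`` (exponential, mean 20).  Energy is
drained by ``c = 1/eps`` per movement step, so the expected flight
endurance is ``E * eps`` steps (200 at the means).  The population
starts from the central source patch in 10 cohorts of 10,000 beetles,
staggered by 10 time steps, each beetle with a uniformly random initial
heading on the 8-direction lattice.

Variability scenarios switch individual trait variability off:

========  ===============  ===================
name      energy variable  efficiency variable
========  ===============  ===================
``S0``    yes              yes
``S1``    yes              no (eps = 20)
``S2``    no (E = 10)      no (eps = 20)
========  ===============  ===================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

N_DIRECTIONS = 8

# Beetle fate codes (shared with the engine kernels).
FLYING, ATTACKING, SUCCESS, DIED_ENERGY, DIED_RESISTANCE, EMIGRATED, CENSORED = range(7)
FATE_NAMES = (
    "flying",
    "attacking",
    "success",
    "died_energy",
    "died_resistance",
    "emigrated",
    "censored",
)
#: Fates a beetle can end a run with.
TERMINAL_FATES = (SUCCESS, DIED_ENERGY, DIED_RESISTANCE, EMIGRATED, CENSORED)


@dataclass(frozen=True)
class VariabilityScenario:
    name: str
    energy_variable: bool
    efficiency_variable: bool


S0 = VariabilityScenario("S0", True, True)
S1 = VariabilityScenario("S1", True, False)
S2 = VariabilityScenario("S2", False, False)
SCENARIOS = {"S0": S0, "S1": S1, "S2": S2}


def get_scenario(name) -> VariabilityScenario:
    if isinstance(name, VariabilityScenario):
        return name
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; expected one of S0, S1, S2")


@dataclass(frozen=True)
class TraitConfig:
    """Beetle trait-distribution parameters and the cohort schedule."""

    energy_mean: float = 10.0
    energy_sd: float = 2.0
    efficiency_mean: float = 20.0
    #: floor applied to exponential efficiency draws; keeps consumption
    #: 1/eps finite for pathological draws (< 0.5 % of samples at the
    #: default mean).
    efficiency_floor: float = 0.1
    cohort_size: int = 10_000
    n_cohorts: int = 10
    time_lag: int = 10
    perceptual_range: float = 15.0
    turn_angle: float = 45.0

    def __post_init__(self) -> None:
        if self.energy_mean <= 0 or self.energy_sd < 0:
            raise ValueError("energy distribution parameters invalid")
        if self.efficiency_mean <= 0 or self.efficiency_floor <= 0:
            raise ValueError("efficiency distribution parameters invalid")
        if self.cohort_size < 1 or self.n_cohorts < 1 or self.time_lag < 0:
            raise ValueError("cohort schedule invalid")
        if self.perceptual_range < 0:
            raise ValueError("perceptual_range must be non-negative")

    @property
    def total_beetles(self) -> int:
        return self.cohort_size * self.n_cohorts


@dataclass
class Beetle:
    """Single beetle record (the engine itself is array-backed)."""

    beetle_id: int
    cohort: int
    start_step: int
    energy: float
    efficiency: float
    heading: int
    col: int
    row: int
    fate: int = FLYING
    steps_flown: int = 0
    energy0: float = 0.0
    episode: int = -1
    tree: "tuple[int, int] | None" = None

    def __post_init__(self) -> None:
        if self.energy0 == 0.0:
            self.energy0 = self.energy

    @property
    def consumption(self) -> float:
        return 1.0 / self.efficiency


def sample_traits(
    traits: TraitConfig,
    scenario: VariabilityScenario | str,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` (energy, efficiency) pairs under a scenario.

    Energy draws <= 0 are redrawn (probability ~3e-7 at the defaults);
    efficiency draws are floored at ``efficiency_floor``.  Fixed traits
    use the distribution means and consume no random draws.
    """
    scenario = get_scenario(scenario)
    if n < 1:
        raise ValueError("n must be >= 1")
    if scenario.energy_variable:
        energy = rng.normal(traits.energy_mean, traits.energy_sd, size=n)
        bad = energy <= 0.0
        while bad.any():
            energy[bad] = rng.normal(traits.energy_mean, traits.energy_sd,
                                     size=int(bad.sum()))
            bad = energy <= 0.0
    else:
        energy = np.full(n, traits.energy_mean)
    if scenario.efficiency_variable:
        efficiency = rng.exponential(traits.efficiency_mean, size=n)
        np.maximum(efficiency, traits.efficiency_floor, out=efficiency)
    else:
        efficiency = np.full(n, traits.efficiency_mean)
    return energy, efficiency


@dataclass
class Population:
    """Array-of-records roster of the full dispersing population."""

    beetle_id: np.ndarray
    cohort: np.ndarray       # 1-based cohort index
    start_step: np.ndarray
    energy0: np.ndarray
    efficiency: np.ndarray
    heading0: np.ndarray
    source: tuple[int, int]

    @property
    def size(self) -> int:
        return self.beetle_id.shape[0]

    @property
    def consumption(self) -> np.ndarray:
        return 1.0 / self.efficiency

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.beetle_id,
                "cohort": self.cohort,
                "start_step": self.start_step,
                "energy0": self.energy0,
                "efficiency": self.efficiency,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_cohorts(
    traits: TraitConfig,
    scenario: VariabilityScenario | str,
    source: tuple[int, int],
    rng: np.random.Generator,
) -> Population:
    """Assemble the staggered population at the source patch.

    Cohort ``k`` (1-based) starts at step ``(k - 1) * time_lag``.  Draw
    order: energies, efficiencies, then initial headings.
    """
    scenario = get_scenario(scenario)
    n = traits.total_beetles
    cohort = np.repeat(np.arange(1, traits.n_cohorts + 1), traits.cohort_size)
    start_step = (cohort - 1) * traits.time_lag
    energy0, efficiency = sample_traits(traits, scenario, n, rng)
    heading0 = rng.integers(0, N_DIRECTIONS, size=n)
    return Population(
        beetle_id=np.arange(n, dtype=np.int64),
        cohort=cohort.astype(np.int64),
        start_step=start_step.astype(np.int64),
        energy0=energy0,
        efficiency=efficiency,
        heading0=heading0.astype(np.int64),
        source=source,
    )
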