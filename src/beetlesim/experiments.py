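"""Scenario matrix and replication: habitats x variability scenarios.

A plan enumerates design cells (habitat, scenario, optional sensitivity
overrides) and runs each cell with ``replicates`` independent, recorded
seeds.  Per-run summaries come back as a tidy table; per-cell
aggregation reports mean and extreme (min/max) success rates.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import EngineParams, run_simulation
from .habitat import HABITAT_TYPES, HabitatConfig, SCATTERED
from .population import SCENARIOS, TraitConfig

#: Trait/habitat parameters a sensitivity grid may override.
OVERRIDABLE = ("energy_mean", "efficiency_mean", "scattered_fraction", "scattered_pa")

#: Default sensitivity levels (+/-50 % on flight capacity; the scattered
#: habitat grid spans fraction and attractiveness of the scattered hosts).
DEFAULT_SENSITIVITY = {
    "energy_mean": [5.0, 10.0, 15.0],
    "efficiency_mean": [10.0, 20.0, 30.0],
    "scattered_fraction": [0.5, 1.0, 2.0, 5.0],
    "scattered_pa": [6, 7, 8, 9],
}


@dataclass(frozen=True)
class ExperimentPlan:
    habitats: tuple[str, ...] = HABITAT_TYPES
    scenarios: tuple[str, ...] = ("S0", "S1", "S2")
    replicates: int = 30
    base_seed: int = 0
    grid_side: int = 448
    cohort_size: int = 10_000
    n_cohorts: int = 10
    #: population scale factor; < 1 shrinks cohorts together with the
    #: density parameters (capacity limit, resistance thresholds).
    scale: float = 1.0
    overrides: Mapping[str, Sequence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for h in self.habitats:
            if h not in HABITAT_TYPES:
                raise ValueError(f"unknown habitat {h!r}")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
        for key in self.overrides:
            if key not in OVERRIDABLE:
                raise ValueError(f"cannot override {key!r}")
        if not (0 < self.scale <= 1):
            raise ValueError("scale must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown plan keys: {sorted(unknown)}")
        for key in ("habitats", "scenarios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def cell_seed(base_seed: int, label: str, replicate: int) -> int:
    """Independent, auditable seed for one (cell, replicate) pair.

    Mixes the base seed with a CRC32 of the cell label and the replicate
    index through a SeedSequence (stable across sessions and platforms).
    """
    ss = np.random.SeedSequence(
        [int(base_seed), zlib.crc32(label.encode()), int(replicate)]
    )
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def _cells(plan: ExperimentPlan):
    keys = list(plan.overrides)
    levels = [plan.overrides[k] for k in keys]
    for habitat, scenario in itertools.product(plan.habitats, plan.scenarios):
        for combo in itertools.product(*levels) if keys else [()]:
            yield habitat, scenario, dict(zip(keys, combo))


def _cell_label(habitat: str, scenario: str, over: dict) -> str:
    parts = [habitat, scenario] + [f"{k}={over[k]}" for k in sorted(over)]
    return "|".join(parts)


def run_cell(
    plan: ExperimentPlan, habitat: str, scenario: str, over: dict, replicate: int
) -> dict:
    """Run one replicate of one design cell and summarize it."""
    label = _cell_label(habitat, scenario, over)
    seed = cell_seed(plan.base_seed, label, replicate)
    hab_kwargs = dict(habitat_type=habitat, grid_side=plan.grid_side)
    trait_kwargs = dict(
        cohort_size=max(1, round(plan.cohort_size * plan.scale)),
        n_cohorts=plan.n_cohorts,
    )
    for k, v in over.items():
        if k in ("scattered_fraction", "scattered_pa"):
            hab_kwargs[k] = v
        else:
            trait_kwargs[k] = v
    params = EngineParams().scaled(plan.scale)
    result = run_simulation(
        HabitatConfig(**hab_kwargs), TraitConfig(**trait_kwargs),
        scenario, params, seed,
    )
    row = {
        "cell": label,
        "habitat": habitat,
        "scenario": scenario,
        "replicate": replicate,
        "seed": seed,
        "error": None,
    }
    row.update({k: over[k] for k in over})
    row.update(
        {
            k: v
            for k, v in result.summary().items()
            if k not in ("habitat_type", "scenario", "seed", "fate_counts")
        }
    )
    row.update({f"n_{k}": v for k, v in result.fate_counts.items()})
    return row


def run_plan(plan: ExperimentPlan, progress: bool = False) -> pd.DataFrame:
    """Execute every (cell, replicate) of the design.

    A failing run yields a row carrying the cell identity and the error
    message instead of aborting the batch.
    """
    rows = []
    for habitat, scenario, over in _cells(plan):
        for rep in range(plan.replicates):
            label = _cell_label(habitat, scenario, over)
            if progress:
                print(f"[beetlesim] {label} replicate {rep}", flush=True)
            try:
                rows.append(run_cell(plan, habitat, scenario, over, rep))
            except Exception as exc:  # noqa: BLE001 - per-cell isolation
                rows.append(
                    {
                        "cell": label,
                        "habitat": habitat,
                        "scenario": scenario,
                        "replicate": rep,
                        "seed": cell_seed(plan.base_seed, label, rep),
                        "error": f"{type(exc).__name__}: {exc}",
                        **over,
                    }
                )
    return pd.DataFrame(rows)


def aggregate_cells(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and extreme success rates (error-bar semantics)."""
    ok = runs[runs["error"].isna()] if "error" in runs else runs
    agg = ok.groupby("cell").agg(
        habitat=("habitat", "first"),
        scenario=("scenario", "first"),
        n_runs=("success_rate", "size"),
        success_mean=("success_rate", "mean"),
        success_min=("success_rate", "min"),
        success_max=("success_rate", "max"),
    )
    return agg.reset_index()
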