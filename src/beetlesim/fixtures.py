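"""Deterministic miniature inputs for tests and demos.

Three fixture kinds:

``tiny_habitat``
    An 11 x 11 lattice with hand-placed PA values around a central
    source (5, 5): a mostly non-host matrix with a few graded hosts.
``toy_population``
    Ten beetles with fixed, human-readable traits.
``scripted_rng_walk``
    A predetermined uniform-draw sequence (plus its seed) to replay a
    single-beetle trajectory exactly; consumed through
    :class:`ScriptedRNG`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .habitat import Habitat, HabitatConfig

FIXTURE_KINDS = ("tiny_habitat", "toy_population", "scripted_rng_walk")

#: Hand-placed PA lattice (11 x 11).  Non-hosts everywhere except a
#: graded cluster north-east of the source and a lone strong host in
#: the south-west.
_TINY_PA = np.zeros((11, 11), dtype=np.int64)
_TINY_PA[7, 7] = 9
_TINY_PA[7, 8] = 6
_TINY_PA[8, 6] = 3
_TINY_PA[6, 8] = 1
_TINY_PA[2, 2] = 8
_TINY_PA[5, 6] = 2


class ScriptedRNG:
    """Replays a fixed sequence of uniform draws via ``.random()``."""

    def __init__(self, draws):
        self.draws = [float(d) for d in draws]
        self.cursor = 0

    def random(self) -> float:
        if self.cursor >= len(self.draws):
            raise RuntimeError("scripted RNG exhausted")
        value = self.draws[self.cursor]
        self.cursor += 1
        return value


def tiny_habitat() -> Habitat:
    """The 11 x 11 hand-placed habitat with the source at (5, 5)."""
    config = HabitatConfig(habitat_type="resistant", grid_side=11)
    return Habitat(config, _TINY_PA.copy(), seed=None)


def toy_population_frame() -> pd.DataFrame:
    """Ten beetles with fixed traits spanning the plausible range."""
    return pd.DataFrame(
        {
            "id": np.arange(10),
            "cohort": np.repeat([1, 2], 5),
            "start_step": np.repeat([0, 10], 5),
            "energy0": [10.0, 8.0, 12.0, 9.5, 10.5, 6.0, 14.0, 10.0, 11.0, 7.5],
            "efficiency": [20.0, 5.0, 40.0, 10.0, 20.0, 60.0, 2.0, 25.0, 15.0, 30.0],
            "heading": [0, 1, 2, 3, 4, 5, 6, 7, 0, 4],
        }
    )


def make_fixture(kind: str, seed: int, out_dir) -> list[Path]:
    """Write one fixture kind to ``out_dir``; returns the created paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "tiny_habitat":
        hab = tiny_habitat()
        path = out_dir / "tiny_habitat.csv"
        hab.to_csv(path)
        meta = out_dir / "tiny_habitat.json"
        meta.write_text(
            json.dumps({"grid_side": 11, "source": [5, 5], "seed": seed})
        )
        return [path, meta]
    if kind == "toy_population":
        path = out_dir / "toy_population.csv"
        toy_population_frame().to_csv(path, index=False)
        return [path]
    if kind == "scripted_rng_walk":
        draws = np.random.default_rng(seed).random(64)
        path = out_dir / "scripted_rng_walk.json"
        path.write_text(json.dumps({"seed": seed, "draws": draws.tolist()}))
        return [path]
    raise ValueError(f"unknown fixture kind {kind!r}")
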