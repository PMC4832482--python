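"""Shared fixtures: miniature worlds and small finished runs."""

from __future__ import annotations

import numpy as np
import pytest

import beetlesim as bs
from beetlesim import fixtures as fx


@pytest.fixture
def tiny_hab():
    return fx.tiny_habitat()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_run():
    """A finished scaled run on a small grid (shared, treated read-only)."""
    return bs.run_simulation(
        bs.HabitatConfig("scattered", grid_side=64),
        bs.TraitConfig(cohort_size=200, n_cohorts=5),
        "S0",
        bs.EngineParams().scaled(0.02),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_resistant_run():
    return bs.run_simulation(
        bs.HabitatConfig("resistant", grid_side=96),
        bs.TraitConfig(cohort_size=1000, n_cohorts=5),
        "S0",
        bs.EngineParams().scaled(0.05),
        seed=3,
    )
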