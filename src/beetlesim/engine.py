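"""Discrete-time stepping core: movement, host selection, aggregation.

The hot loop lives in :mod:`beetlesim._kernels` (numba).  This module
owns the simulation state, end-of-wave colonization resolution, and a
readable pure-Python reference implementation of the per-beetle
operations (:func:`perceive`, :func:`move_beetle`, :func:`try_attack`,
:func:`advance_beetle`) that mirrors the kernel draw-for-draw and is
cross-checked against it by the test suite.

Behavioral model
----------------
A flying beetle scans all trees within its perceptual range each step.
A tree qualifies when its current attractiveness ``A`` (kairomone PA if
unattacked, pheromone level while under attack, 0 at capacity) is at
least 1 and satisfies the attack condition ``A >= kappa * E``: a
full-energy average beetle accepts only maximally attractive hosts and
the requirement relaxes linearly as its energy drains (the desperation
limit).  The beetle chases the most attractive qualifying tree
(nearest on ties) greedily on the 8-connected lattice, otherwise it
turns -45/0/+45 degrees uniformly at random and advances one patch,
paying ``c = 1/efficiency`` energy.  Landing on a qualifying tree it
joins the attack and waits; colonization is resolved once, when no
beetle flies anymore: trees at or above their resistance threshold are
infested (attackers succeed), the rest resist (attackers die).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import DIR_DX, DIR_DY, ENERGY_EPS
from .habitat import (
    Habitat,
    HabitatConfig,
    INFESTED,
    RESISTED,
    STATUS_NAMES,
    UNATTACKED,
    UNDER_ATTACK,
    generate_habitat,
    perception_offsets,
    resistance_threshold,
    resistance_thresholds,
)
from .population import (
    ATTACKING,
    CENSORED,
    DIED_ENERGY,
    DIED_RESISTANCE,
    EMIGRATED,
    FATE_NAMES,
    FLYING,
    SUCCESS,
    Beetle,
    Population,
    TraitConfig,
    VariabilityScenario,
    build_cohorts,
    get_scenario,
)


@dataclass(frozen=True)
class EngineParams:
    """Stepping-core parameters.

    ``pheromone_attractiveness`` must exceed the maximal kairomone level
    (9) so a strongly attacked host out-competes any unattacked one; the
    attack coefficient ``kappa`` sets the energy/attractiveness
    trade-off ``A >= kappa * E``.  ``pheromone_gain`` grades the
    aggregation signal with the attacker count (each attacker adds
    ``gain`` to the tree's attractiveness, capped at the pheromone
    ceiling); ``gain = inf`` gives the constant-pheromone variant where
    a single attacker already emits the full signal.  ``kappa`` and the
    pheromone parameters are the documented calibration hooks.
    ``threshold_scale`` and ``capacity_limit`` are scaled together with
    the population in reduced-size runs.
    """

    pheromone_attractiveness: float = 10.0
    attack_coefficient: float = 0.9
    pheromone_gain: float = 0.0055
    #: when the aggregation signal activates: "infested" = only once the
    #: attackers overwhelmed the host (reached its resistance
    #: threshold); "first_attacker" = from the very first attacker on;
    #: "quorum" = once ``pheromone_quorum`` attackers joined.
    pheromone_trigger: str = "infested"
    pheromone_quorum: int = 40
    #: how a beetle picks among qualifying trees in range:
    #: "attractiveness" = most attractive first (nearest on ties),
    #: "nearest" = nearest first (most attractive on ties).
    target_preference: str = "nearest"
    #: steps an attacked tree's aggregation episode may last: pioneers
    #: must attract the threshold number of conspecifics within this
    #: window, otherwise the tree sheds them (resistance mortality) and
    #: becomes attackable afresh.  inf = resolve once at wave end.
    attack_window: float = 300.0
    capacity_limit: int = 5_000
    max_steps: int = 2_000
    threshold_scale: float = 1.0
    boundary_mode: str = "absorbing"

    def __post_init__(self) -> None:
        if self.pheromone_attractiveness <= 9.0:
            raise ValueError("pheromone_attractiveness must exceed 9")
        if self.attack_coefficient <= 0:
            raise ValueError("attack_coefficient must be positive")
        if self.pheromone_gain <= 0:
            raise ValueError("pheromone_gain must be positive")
        if self.attack_window <= 0:
            raise ValueError("attack_window must be positive")
        if self.pheromone_trigger not in ("infested", "first_attacker", "quorum"):
            raise ValueError(
                "pheromone_trigger must be 'infested', 'first_attacker' or 'quorum'")
        if self.pheromone_quorum < 1:
            raise ValueError("pheromone_quorum must be >= 1")
        if self.target_preference not in ("attractiveness", "nearest"):
            raise ValueError("target_preference must be 'attractiveness' or 'nearest'")
        if self.capacity_limit < 1:
            raise ValueError("capacity_limit must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")
        if self.threshold_scale <= 0:
            raise ValueError("threshold_scale must be positive")
        if self.boundary_mode != "absorbing":
            raise ValueError("only absorbing boundaries are supported")

    def scaled(self, factor: float) -> "EngineParams":
        """Density parameters scaled for a population reduced by ``factor``."""
        return EngineParams(
            pheromone_attractiveness=self.pheromone_attractiveness,
            attack_coefficient=self.attack_coefficient,
            pheromone_gain=self.pheromone_gain / factor,
            pheromone_trigger=self.pheromone_trigger,
            pheromone_quorum=max(1, round(self.pheromone_quorum * factor)),
            target_preference=self.target_preference,
            attack_window=self.attack_window,
            capacity_limit=max(1, round(self.capacity_limit * factor)),
            max_steps=self.max_steps,
            threshold_scale=self.threshold_scale * factor,
            boundary_mode=self.boundary_mode,
        )


def current_attractiveness(pa: int, n_attackers: int,
                           params: EngineParams) -> float:
    """Attractiveness of a tree given its attacker count.

    Under the default "infested" pheromone trigger the aggregation
    signal activates only once the attackers have reached the tree's
    resistance threshold; until then the kairomone level PA stands.
    Note an infested tree is exactly one whose current attacker count
    reached the threshold (counts only reset when a pre-threshold
    attack episode expires).
    """
    if n_attackers < 0:
        raise ValueError("attacker count must be non-negative")
    if n_attackers == 0:
        return float(pa)
    if n_attackers >= params.capacity_limit:
        return 0.0
    if params.pheromone_trigger == "infested":
        activation = resistance_threshold(pa, params.threshold_scale) if pa >= 1 else 1
    elif params.pheromone_trigger == "quorum":
        activation = params.pheromone_quorum
    else:
        activation = 1
    if n_attackers < activation:
        return float(pa)
    return min(params.pheromone_attractiveness,
               pa + params.pheromone_gain * n_attackers)


def attack_condition(energy: float, attractiveness: float,
                     kappa: float = 0.9) -> bool:
    """Whether a beetle at energy ``E`` accepts a host of attractiveness ``A``.

    True iff ``A >= 1`` and ``A >= kappa * E``; monotone in both
    directions (stays true as E decreases or A increases).
    """
    if energy < 0 or attractiveness < 0:
        raise ValueError("energy and attractiveness must be non-negative")
    return attractiveness >= 1.0 and attractiveness >= kappa * energy


class Simulation:
    """Mutable state of one dispersal wave (grid + agents + clock + RNG)."""

    def __init__(
        self,
        habitat: Habitat,
        pop: Population,
        params: EngineParams,
        traits: TraitConfig,
        rng: np.random.Generator,
    ):
        self.habitat = habitat
        self.params = params
        self.traits = traits
        self.rng = rng
        self.clock = 0

        self.pa = habitat.pa  # int64 lattice
        self.n_attackers = np.zeros_like(self.pa)
        thr = resistance_thresholds(self.pa, params.threshold_scale)
        self.thresholds = np.where(
            np.isfinite(thr), thr, float(np.int64(1) << 50)
        ).astype(np.int64)
        self.infested = np.zeros_like(self.pa)
        self.episode = np.zeros_like(self.pa)
        self.status: np.ndarray | None = None  # filled by resolve_colonization

        n = pop.size
        sc, sr = pop.source
        self.pop = pop
        self.x = np.full(n, sc, dtype=np.int64)
        self.y = np.full(n, sr, dtype=np.int64)
        self.heading = pop.heading0.astype(np.int64).copy()
        self.energy = pop.energy0.astype(np.float64).copy()
        self.consumption = (1.0 / pop.efficiency).astype(np.float64)
        self.fate = np.full(n, FLYING, dtype=np.int64)
        self.steps_flown = np.zeros(n, dtype=np.int64)
        self.tree_col = np.full(n, -1, dtype=np.int64)
        self.tree_row = np.full(n, -1, dtype=np.int64)
        self.beetle_episode = np.full(n, -1, dtype=np.int64)
        self._active_buf = np.empty(n, dtype=np.int64)
        # one window entry per 0 -> 1 attacker transition; each failed
        # episode permanently consumes >= 1 beetle, hence the bound
        cap = n + habitat.grid_side * habitat.grid_side + 1
        self._pend_tree = np.zeros(cap, dtype=np.int64)
        self._pend_deadline = np.zeros(cap, dtype=np.int64)
        self._pend_state = np.zeros(2, dtype=np.int64)
        self._window = np.int64(min(params.attack_window, _kernels.NEVER))
        self._off_dx, self._off_dy, self._off_d2 = perception_offsets(
            traits.perceptual_range, habitat.config.patch_size
        )

    # -- stepping -----------------------------------------------------

    @property
    def n_flying(self) -> int:
        return int(np.count_nonzero(self.fate == FLYING))

    def fate_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.fate == code))
            for code, name in enumerate(FATE_NAMES)
        }

    def _trigger_code(self) -> int:
        trig = self.params.pheromone_trigger
        if trig == "first_attacker":
            return 1
        if trig == "quorum":
            return int(self.params.pheromone_quorum)
        return -1

    def step(self) -> int:
        """Advance the wave by one time step; returns beetles processed."""
        m = _kernels._step_once(
            self.clock,
            self.pa,
            self.n_attackers,
            self.params.capacity_limit,
            self.params.pheromone_attractiveness,
            self.params.pheromone_gain,
            self._trigger_code(),
            self.params.target_preference == "nearest",
            self.params.attack_coefficient,
            self.thresholds,
            self.infested,
            self.episode,
            self._window,
            self._pend_tree,
            self._pend_deadline,
            self._pend_state,
            self._off_dx,
            self._off_dy,
            self._off_d2,
            self.x,
            self.y,
            self.heading,
            self.energy,
            self.consumption,
            self.fate,
            self.steps_flown,
            self.tree_col,
            self.tree_row,
            self.beetle_episode,
            self.pop.start_step,
            self._active_buf,
            self.rng,
        )
        self.clock += 1
        return int(m)

    def run_wave(self) -> None:
        """Step until no beetle flies or ``max_steps``; censor leftovers."""
        while self.clock < self.params.max_steps and self.n_flying > 0:
            self.step()
        still = self.fate == FLYING
        self.fate[still] = CENSORED

    def resolve_colonization(self) -> None:
        """Final attack resolution once no beetle flies anymore.

        A tree reaching its resistance threshold (within an aggregation
        window, if one is configured) is infested and the attackers of
        its successful episode succeed; attackers of expired episodes
        and of trees still short of their threshold die of host
        resistance.
        """
        if self.n_flying:
            raise RuntimeError("cannot resolve colonization while beetles fly")
        attacked = (self.n_attackers > 0) | (self.episode > 0)
        infested = self.infested > 0
        # trees whose last open window is still short of the threshold
        status = np.full_like(self.pa, UNATTACKED)
        status[attacked & ~infested] = RESISTED
        status[infested] = INFESTED
        self.status = status
        attackers = self.fate == ATTACKING
        if attackers.any():
            tc = self.tree_col[attackers]
            tr = self.tree_row[attackers]
            won = infested[tc, tr] & (
                self.beetle_episode[attackers] == self.episode[tc, tr]
            )
            new_fate = np.where(won, SUCCESS, DIED_RESISTANCE)
            self.fate[attackers] = new_fate

    # -- exports ------------------------------------------------------

    def beetle_frame(self) -> pd.DataFrame:
        ps = self.habitat.config.patch_size
        sc, sr = self.habitat.source
        disp = ps * np.hypot(self.x - sc, self.y - sr)
        return pd.DataFrame(
            {
                "id": self.pop.beetle_id,
                "cohort": self.pop.cohort,
                "start_step": self.pop.start_step,
                "energy0": self.pop.energy0,
                "efficiency": self.pop.efficiency,
                "steps_flown": self.steps_flown,
                "final_col": self.x,
                "final_row": self.y,
                "final_x_m": ps * (self.x - sc),
                "final_y_m": ps * (self.y - sr),
                "displacement_m": disp,
                "energy_final": self.energy,
                "fate": pd.Categorical.from_codes(
                    self.fate, categories=list(FATE_NAMES)
                ),
                "tree_col": self.tree_col,
                "tree_row": self.tree_row,
            }
        )

    def tree_frame(self) -> pd.DataFrame:
        if self.status is None:
            raise RuntimeError("colonization not resolved yet")
        side = self.habitat.grid_side
        cols, rows = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        return pd.DataFrame(
            {
                "col": cols.ravel(),
                "row": rows.ravel(),
                "pa": self.pa.ravel(),
                "distance_m": self.habitat.distances().ravel(),
                "n_attackers": self.n_attackers.ravel(),
                "status": pd.Categorical.from_codes(
                    self.status.ravel(), categories=list(STATUS_NAMES)
                ),
            }
        )


@dataclass
class RunResult:
    """Complete record of one finished dispersal wave."""

    habitat_config: HabitatConfig
    traits: TraitConfig
    scenario: VariabilityScenario
    params: EngineParams
    seed: int
    clock: int
    fate_counts: dict[str, int]
    sim: Simulation = field(repr=False)

    _beetles: pd.DataFrame | None = field(default=None, repr=False)
    _trees: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_beetles(self) -> int:
        return self.sim.pop.size

    @property
    def success_rate(self) -> float:
        return self.fate_counts["success"] / self.n_beetles

    @property
    def beetles(self) -> pd.DataFrame:
        if self._beetles is None:
            self._beetles = self.sim.beetle_frame()
        return self._beetles

    @property
    def trees(self) -> pd.DataFrame:
        if self._trees is None:
            self._trees = self.sim.tree_frame()
        return self._trees

    def summary(self) -> dict:
        infested = (
            int(np.count_nonzero(self.sim.status == INFESTED))
            if self.sim.status is not None
            else 0
        )
        dens = self.sim.n_attackers[self.sim.status == INFESTED]
        return {
            "habitat_type": self.habitat_config.habitat_type,
            "scenario": self.scenario.name,
            "seed": int(self.seed),
            "n_beetles": self.n_beetles,
            "grid_side": self.habitat_config.grid_side,
            "clock": self.clock,
            "success_rate": self.success_rate,
            "fate_counts": self.fate_counts,
            "n_infested_trees": infested,
            "mean_colonization_density": float(dens.mean()) if dens.size else float("nan"),
        }


def run_simulation(
    habitat_config: HabitatConfig,
    trait_config: TraitConfig,
    scenario: VariabilityScenario | str,
    engine_params: EngineParams,
    seed: int,
) -> RunResult:
    """Simulate one full dispersal wave; bit-reproducible per seed.

    The seed feeds a :class:`numpy.random.SeedSequence` whose children
    drive habitat generation, trait/cohort sampling and the movement
    loop independently.
    """
    scenario = get_scenario(scenario)
    ss = np.random.SeedSequence(seed)
    habitat_ss, pop_ss, move_ss = ss.spawn(3)
    habitat = generate_habitat(habitat_config, habitat_ss)
    pop = build_cohorts(
        trait_config, scenario, habitat.source, np.random.default_rng(pop_ss)
    )
    sim = Simulation(habitat, pop, engine_params, trait_config,
                     np.random.default_rng(move_ss))
    sim.run_wave()
    sim.resolve_colonization()
    return RunResult(
        habitat_config=habitat_config,
        traits=trait_config,
        scenario=scenario,
        params=engine_params,
        seed=seed,
        clock=sim.clock,
        fate_counts=sim.fate_counts(),
        sim=sim,
    )


# ---------------------------------------------------------------------
# Pure-Python reference operations (mirror the kernel draw-for-draw).
# ---------------------------------------------------------------------


@dataclass
class ObjectState:
    """Minimal object-level view of the world for the reference ops.

    Carries the per-tree dynamic state (attacker counts, thresholds,
    infestation flags, attack episodes and their open windows) so the
    reference sub-step is behaviourally identical to the compiled one.
    """

    habitat: Habitat
    params: EngineParams
    traits: TraitConfig
    n_attackers: np.ndarray
    rng: object  # anything with .random() -> float in [0, 1)
    clock: int = 0

    def __post_init__(self) -> None:
        thr = resistance_thresholds(self.habitat.pa,
                                    self.params.threshold_scale)
        self.thresholds = np.where(np.isfinite(thr), thr,
                                   float(np.int64(1) << 50)).astype(np.int64)
        self.infested = np.zeros_like(self.habitat.pa)
        self.episode = np.zeros_like(self.habitat.pa)
        self.windows: list[tuple[int, int, int]] = []  # (col, row, deadline)

    def attractiveness(self, col: int, row: int) -> float:
        pa = int(self.habitat.pa[col, row])
        n = int(self.n_attackers[col, row])
        if n == 0:
            return float(pa)
        if n >= self.params.capacity_limit:
            return 0.0
        trig = self.params.pheromone_trigger
        if trig == "infested":
            activation = int(self.thresholds[col, row])
        elif trig == "quorum":
            activation = int(self.params.pheromone_quorum)
        else:
            activation = 1
        if n < activation:
            return float(pa)
        return min(self.params.pheromone_attractiveness,
                   pa + self.params.pheromone_gain * n)

    def expire_windows(self) -> None:
        """Fail open attack episodes whose aggregation window ran out."""
        keep = []
        for col, row, deadline in self.windows:
            if deadline > self.clock:
                keep.append((col, row, deadline))
                continue
            if self.infested[col, row] == 0 and self.n_attackers[col, row] > 0:
                self.episode[col, row] += 1
                self.n_attackers[col, row] = 0
        self.windows = keep


def perceive(state: ObjectState, beetle: Beetle) -> Optional[tuple[int, int]]:
    """Target tree (col, row) for a flying beetle, or None.

    Scans trees within the perceptual range in (distance, dx, dy) order;
    among those qualifying under :func:`attack_condition`, returns the
    winner of the configured target preference (nearest qualifying tree
    by default, most attractive on ties; or most attractive first),
    breaking remaining ties uniformly at random (one draw, only when
    needed).
    """
    if beetle.fate != FLYING:
        raise ValueError("perceive() requires a flying beetle")
    hab, par = state.habitat, state.params
    dx, dy, d2 = perception_offsets(
        state.traits.perceptual_range, hab.config.patch_size
    )
    kappa = par.attack_coefficient
    nearest_first = par.target_preference == "nearest"
    best: tuple[float, int] | None = None  # (attractiveness, squared dist)
    ties: list[tuple[int, int]] = []
    for k in range(len(dx)):
        c, r = beetle.col + int(dx[k]), beetle.row + int(dy[k])
        if not hab.on_grid(c, r):
            continue
        a = state.attractiveness(c, r)
        if not attack_condition(beetle.energy, a, kappa):
            continue
        dd = int(d2[k])
        if best is None:
            better = True
        elif nearest_first:
            better = dd < best[1] or (dd == best[1] and a > best[0])
        else:
            better = a > best[0] or (a == best[0] and dd < best[1])
        if better:
            best = (a, dd)
            ties = [(c, r)]
        elif a == best[0] and dd == best[1]:
            ties.append((c, r))
    if best is None:
        return None
    if len(ties) > 1:
        return ties[int(state.rng.random() * len(ties))]
    return ties[0]


def move_beetle(state: ObjectState, beetle: Beetle,
                target: Optional[tuple[int, int]] = None) -> None:
    """Advance a flying beetle one patch; may emigrate off-grid.

    With a target, the heading becomes the 8-direction step that
    maximally reduces the Euclidean distance to it; otherwise the
    heading turns -45/0/+45 degrees uniformly at random (one draw).
    Energy drops by the beetle's consumption.
    """
    if beetle.fate != FLYING:
        raise ValueError("move_beetle() requires a flying beetle")
    if target is not None:
        bx, by = target
        best_dir, best_dist = 0, float("inf")
        for d in range(8):
            ddx = beetle.col + int(DIR_DX[d]) - bx
            ddy = beetle.row + int(DIR_DY[d]) - by
            dist = ddx * ddx + ddy * ddy
            if dist < best_dist:
                best_dist, best_dir = dist, d
        beetle.heading = best_dir
    else:
        u = state.rng.random()
        beetle.heading = (beetle.heading + (int(u * 3.0) - 1) + 8) % 8
    beetle.col += int(DIR_DX[beetle.heading])
    beetle.row += int(DIR_DY[beetle.heading])
    beetle.energy -= beetle.consumption
    beetle.steps_flown += 1
    if not state.habitat.on_grid(beetle.col, beetle.row):
        beetle.fate = EMIGRATED


def try_attack(state: ObjectState, beetle: Beetle) -> bool:
    """Attack the tree on the beetle's patch if the condition holds.

    The first attacker of a fresh episode opens the tree's aggregation
    window; the tree becomes infested the moment the attacker count
    reaches its resistance threshold.
    """
    if beetle.fate != FLYING:
        raise ValueError("try_attack() requires a flying beetle")
    c, r = beetle.col, beetle.row
    a = state.attractiveness(c, r)
    if not (
        attack_condition(beetle.energy, a, state.params.attack_coefficient)
        and state.n_attackers[c, r] < state.params.capacity_limit
    ):
        return False
    if state.n_attackers[c, r] == 0 and state.infested[c, r] == 0:
        deadline = state.clock + min(state.params.attack_window,
                                     float(_kernels.NEVER))
        state.windows.append((c, r, int(deadline)))
    state.n_attackers[c, r] += 1
    beetle.fate = ATTACKING
    beetle.episode = int(state.episode[c, r])
    beetle.tree = (c, r)
    if (state.infested[c, r] == 0
            and state.n_attackers[c, r] >= state.thresholds[c, r]):
        state.infested[c, r] = 1
    return True


def advance_beetle(state: ObjectState, beetle: Beetle) -> None:
    """Full reference sub-step: perceive -> move -> try-attack.

    Equivalent, draw for draw, to ``_kernels._beetle_substep``.
    """
    target = perceive(state, beetle)
    if target == (beetle.col, beetle.row):
        attacked = try_attack(state, beetle)
        assert attacked  # perceive() filtered by the attack condition
        return
    move_beetle(state, beetle, target)
    if beetle.fate != FLYING:
        return
    if try_attack(state, beetle):
        return
    if beetle.energy <= ENERGY_EPS:
        beetle.fate = DIED_ENERGY
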