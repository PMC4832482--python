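import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import beetlesim as bs
from beetlesim import _kernels
from beetlesim.engine import (
    EngineParams,
    ObjectState,
    Simulation,
    advance_beetle,
    attack_condition,
    current_attractiveness,
    move_beetle,
    perceive,
    run_simulation,
    try_attack,
)
from beetlesim.fixtures import ScriptedRNG, tiny_habitat
from beetlesim.habitat import (
    Habitat,
    HabitatConfig,
    INFESTED,
    generate_habitat,
    perception_offsets,
    resistance_threshold,
    resistance_thresholds,
)
from beetlesim.population import (
    ATTACKING,
    Beetle,
    CENSORED,
    DIED_ENERGY,
    EMIGRATED,
    FLYING,
    SUCCESS,
    TraitConfig,
    build_cohorts,
)

#: spec'd constant-pheromone parameterization (signal from first attacker)
CONSTANT_PHER = EngineParams(
    pheromone_trigger="first_attacker",
    pheromone_gain=float("inf"),
    target_preference="attractiveness",
)


def object_state(habitat, params=None, rng=None):
    params = params or EngineParams()
    return ObjectState(
        habitat=habitat,
        params=params,
        traits=TraitConfig(),
        n_attackers=np.zeros_like(habitat.pa),
        rng=rng or ScriptedRNG([]),
    )


def make_beetle(col, row, energy, efficiency=20.0, heading=0):
    return Beetle(
        beetle_id=0,
        cohort=1,
        start_step=0,
        energy=energy,
        efficiency=efficiency,
        heading=heading,
        col=col,
        row=row,
    )


class TestCurrentAttractiveness:
    def test_unattacked_host(self):
        assert current_attractiveness(7, 0, CONSTANT_PHER) == 7.0

    def test_constant_pheromone_from_first_attacker(self):
        assert current_attractiveness(2, 1, CONSTANT_PHER) == 10.0

    def test_capacity_repellent(self):
        assert current_attractiveness(8, 5000, CONSTANT_PHER) == 0.0
        assert current_attractiveness(8, 5000, EngineParams()) == 0.0

    def test_infested_trigger_keeps_kairomone_below_threshold(self):
        params = EngineParams()
        thr = resistance_threshold(3)  # 158
        assert current_attractiveness(3, thr - 1, params) == 3.0
        above = current_attractiveness(3, thr, params)
        assert above == min(10.0, 3 + params.pheromone_gain * thr)

    def test_negative_count(self):
        with pytest.raises(ValueError):
            current_attractiveness(5, -1, EngineParams())


class TestAttackCondition:
    def test_full_energy_accepts_only_top_host(self):
        assert attack_condition(10.0, 9.0, kappa=0.9)

    def test_full_energy_rejects_mid_host(self):
        assert not attack_condition(10.0, 5.0, kappa=0.9)

    def test_desperation_limit(self):
        assert attack_condition(0.5, 1.0, kappa=0.9)

    def test_zero_attractiveness_never(self):
        assert not attack_condition(0.0, 0.0, kappa=0.9)

    @given(
        e=st.floats(min_value=0, max_value=50),
        a=st.floats(min_value=1, max_value=10),
        de=st.floats(min_value=0, max_value=10),
        da=st.floats(min_value=0, max_value=10),
    )
    def test_monotone(self, e, a, de, da):
        if attack_condition(e, a, kappa=0.9):
            assert attack_condition(max(0.0, e - de), min(10.0, a + da), kappa=0.9)


class TestPerceive:
    def test_no_qualifying_tree(self, tiny_hab):
        state = object_state(tiny_hab)
        beetle = make_beetle(5, 5, energy=20.0)  # kappa*E = 18 > any A
        assert perceive(state, beetle) is None

    def test_attacked_tree_beats_kairomone_host(self):
        # constant-pheromone, attractiveness-first parameterization
        pa = np.zeros((11, 11), dtype=np.int64)
        pa[5, 7] = 8
        hab = Habitat(HabitatConfig("resistant", grid_side=11), pa)
        state = object_state(hab, params=CONSTANT_PHER)
        state.n_attackers[7, 5] = 1  # under attack -> A = 10
        beetle = make_beetle(5, 5, energy=2.0)
        assert perceive(state, beetle) == (7, 5)

    def test_equal_attractiveness_nearest_wins(self, tiny_hab):
        pa = np.zeros((11, 11), dtype=np.int64)
        pa[5, 6] = 5  # 5 m away
        pa[5, 3] = 5  # 10 m away
        hab = Habitat(HabitatConfig("resistant", grid_side=11), pa)
        beetle = make_beetle(5, 5, energy=5.0)
        for pref in ("nearest", "attractiveness"):
            state = object_state(hab, params=EngineParams(target_preference=pref))
            assert perceive(state, beetle) == (5, 6)

    def test_exact_tie_uses_one_draw(self):
        pa = np.zeros((11, 11), dtype=np.int64)
        pa[5, 7] = 5
        pa[7, 5] = 5  # same A, same distance
        hab = Habitat(HabitatConfig("resistant", grid_side=11), pa)
        beetle = make_beetle(5, 5, energy=5.0)
        state = object_state(hab, rng=ScriptedRNG([0.7]))
        assert perceive(state, beetle) == (7, 5)  # second in scan order
        state = object_state(hab, rng=ScriptedRNG([0.2]))
        assert perceive(state, beetle) == (5, 7)

    def test_requires_flying(self, tiny_hab):
        beetle = make_beetle(5, 5, energy=5.0)
        beetle.fate = ATTACKING
        with pytest.raises(ValueError):
            perceive(object_state(tiny_hab), beetle)


class TestMoveBeetle:
    @pytest.mark.parametrize(
        "u,expected_heading",
        [(0.1, 1), (0.5, 2), (0.9, 3)],  # from N: NE / N / NW... delta -1/0/+1
    )
    def test_random_turn_three_outcomes(self, tiny_hab, u, expected_heading):
        beetle = make_beetle(5, 5, energy=10.0, heading=2)  # N
        state = object_state(tiny_hab, rng=ScriptedRNG([u]))
        move_beetle(state, beetle)
        assert beetle.heading == expected_heading

    def test_chase_rotates_to_target_bearing(self, tiny_hab):
        # heading north, cue due east -> heading becomes east immediately
        beetle = make_beetle(5, 5, energy=10.0, heading=2)
        state = object_state(tiny_hab)
        move_beetle(state, beetle, target=(7, 5))
        assert beetle.heading == 0
        assert (beetle.col, beetle.row) == (6, 5)

    def test_energy_decrement_exact(self, tiny_hab):
        beetle = make_beetle(5, 5, energy=10.0, efficiency=4.0)
        move_beetle(object_state(tiny_hab), beetle, target=(7, 5))
        assert beetle.energy == 10.0 - 0.25

    def test_emigration_absorbing(self, tiny_hab):
        beetle = make_beetle(10, 5, energy=10.0, heading=0)  # east edge, heading E
        state = object_state(tiny_hab, rng=ScriptedRNG([0.5]))
        move_beetle(state, beetle)
        assert beetle.fate == EMIGRATED

    def test_requires_flying(self, tiny_hab):
        beetle = make_beetle(5, 5, energy=1.0)
        beetle.fate = DIED_ENERGY
        with pytest.raises(ValueError):
            move_beetle(object_state(tiny_hab), beetle)


class TestTryAttack:
    def test_attack_below_capacity(self, tiny_hab):
        state = object_state(tiny_hab)
        beetle = make_beetle(7, 7, energy=5.0)  # PA 9 tree
        assert try_attack(state, beetle)
        assert beetle.fate == ATTACKING
        assert state.n_attackers[7, 7] == 1
        assert state.windows  # aggregation window opened

    def test_capacity_edge(self):
        pa = np.zeros((11, 11), dtype=np.int64)
        pa[5, 5] = 9
        hab = Habitat(HabitatConfig("resistant", grid_side=11), pa)
        params = EngineParams(capacity_limit=50)
        state = object_state(hab, params=params)
        state.n_attackers[5, 5] = 49
        state.infested[5, 5] = 1
        beetle = make_beetle(5, 5, energy=5.0)
        assert try_attack(state, beetle)
        assert state.n_attackers[5, 5] == 50
        # at capacity the tree repels: next beetle cannot attack
        other = make_beetle(5, 5, energy=0.5)
        assert not try_attack(state, other)

    def test_nonhost_never_attacked(self, tiny_hab):
        state = object_state(tiny_hab)
        beetle = make_beetle(0, 0, energy=0.1)  # PA = 0 patch
        assert not try_attack(state, beetle)
        assert state.n_attackers[0, 0] == 0

    def test_threshold_crossing_marks_infested(self):
        pa = np.zeros((11, 11), dtype=np.int64)
        pa[5, 5] = 9
        hab = Habitat(HabitatConfig("resistant", grid_side=11), pa)
        state = object_state(hab)
        thr = resistance_threshold(9)  # 30
        state.n_attackers[5, 5] = thr - 1
        assert state.infested[5, 5] == 0
        beetle = make_beetle(5, 5, energy=1.0)
        assert try_attack(state, beetle)
        assert state.infested[5, 5] == 1


class TestScriptedOracle:
    """Hand-simulated single-beetle trajectory vs the engine, draw for draw.

    Tiny habitat, beetle starts at the source (5, 5) heading east with
    E = 12 and consumption 1.  Hand derivation: with kappa = 0.9 nothing
    qualifies until E = 10 (the PA 9 tree at (7, 7) needs A >= 0.9 E).
    Steps 1-2 are random turns (draws 0.5 -> straight, 0.0 -> right),
    placing the beetle at (7, 4); from there the PA 9 tree is exactly
    15 m away, qualifies, and is chased north for three steps; the
    beetle lands on it at E = 7 and attacks (9 >= 0.9 * 7).
    """

    EXPECTED = [
        # (col, row, heading, energy, fate)
        (6, 5, 0, 11.0, FLYING),
        (7, 4, 7, 10.0, FLYING),
        (7, 5, 2, 9.0, FLYING),
        (7, 6, 2, 8.0, FLYING),
        (7, 7, 2, 7.0, ATTACKING),
    ]
    DRAWS = [0.5, 0.0]

    def run_kernel_substeps(self, rng):
        hab = tiny_habitat()
        pa = hab.pa
        natt = np.zeros_like(pa)
        thr = resistance_thresholds(pa, 1.0)
        thr = np.where(np.isfinite(thr), thr, float(np.int64(1) << 50)).astype(np.int64)
        infested = np.zeros_like(pa)
        episode = np.zeros_like(pa)
        pend_tree = np.zeros(64, np.int64)
        pend_deadline = np.zeros(64, np.int64)
        pend_state = np.zeros(2, np.int64)
        odx, ody, od2 = perception_offsets(15.0, 5.0)
        x = np.array([5], np.int64)
        y = np.array([5], np.int64)
        heading = np.array([0], np.int64)
        energy = np.array([12.0])
        consumption = np.array([1.0])
        fate = np.array([FLYING], np.int64)
        steps = np.zeros(1, np.int64)
        tcol = np.full(1, -1, np.int64)
        trow = np.full(1, -1, np.int64)
        bep = np.full(1, -1, np.int64)
        traj = []
        clock = 0
        while fate[0] == FLYING and clock < 20:
            _kernels._beetle_substep.py_func(
                0, clock, pa, natt, 5000, 10.0, 0.0055, -1, True, 0.9,
                thr, infested, episode, np.int64(300),
                pend_tree, pend_deadline, pend_state,
                odx, ody, od2,
                x, y, heading, energy, consumption, fate, steps,
                tcol, trow, bep, rng,
            )
            traj.append((int(x[0]), int(y[0]), int(heading[0]),
                         float(energy[0]), int(fate[0])))
            clock += 1
        return traj, natt, steps[0]

    def test_kernel_matches_hand_simulation(self):
        rng = ScriptedRNG(self.DRAWS)
        traj, natt, steps = self.run_kernel_substeps(rng)
        assert traj == self.EXPECTED
        assert rng.cursor == len(self.DRAWS)  # exactly two draws consumed
        assert natt[7, 7] == 1
        assert steps == 5

    def test_reference_ops_match_hand_simulation(self, tiny_hab):
        state = object_state(tiny_hab, rng=ScriptedRNG(self.DRAWS))
        beetle = make_beetle(5, 5, energy=12.0, efficiency=1.0, heading=0)
        traj = []
        while beetle.fate == FLYING:
            advance_beetle(state, beetle)
            traj.append((beetle.col, beetle.row, beetle.heading,
                         beetle.energy, beetle.fate))
        assert traj == self.EXPECTED
        assert state.n_attackers[7, 7] == 1
        assert beetle.tree == (7, 7)

    def test_scripted_replay_is_deterministic(self):
        a, _, _ = self.run_kernel_substeps(ScriptedRNG(self.DRAWS))
        b, _, _ = self.run_kernel_substeps(ScriptedRNG(self.DRAWS))
        assert a == b

    def test_jit_equals_pyfunc_with_same_generator_seed(self):
        # same bit-generator state must give the identical trajectory
        # through the compiled and the pure-Python kernel paths
        py_traj, _, _ = self.run_kernel_substeps(np.random.default_rng(99))
        jit_traj, _, _ = self._run_jit(np.random.default_rng(99))
        assert py_traj == jit_traj

    def _run_jit(self, rng):
        # identical to run_kernel_substeps but through the compiled kernel
        saved = _kernels._beetle_substep
        hab = tiny_habitat()
        pa = hab.pa
        natt = np.zeros_like(pa)
        thr = resistance_thresholds(pa, 1.0)
        thr = np.where(np.isfinite(thr), thr, float(np.int64(1) << 50)).astype(np.int64)
        infested = np.zeros_like(pa)
        episode = np.zeros_like(pa)
        pend_tree = np.zeros(64, np.int64)
        pend_deadline = np.zeros(64, np.int64)
        pend_state = np.zeros(2, np.int64)
        odx, ody, od2 = perception_offsets(15.0, 5.0)
        x = np.array([5], np.int64)
        y = np.array([5], np.int64)
        heading = np.array([0], np.int64)
        energy = np.array([12.0])
        consumption = np.array([1.0])
        fate = np.array([FLYING], np.int64)
        steps = np.zeros(1, np.int64)
        tcol = np.full(1, -1, np.int64)
        trow = np.full(1, -1, np.int64)
        bep = np.full(1, -1, np.int64)
        traj = []
        clock = 0
        while fate[0] == FLYING and clock < 20:
            saved(
                0, clock, pa, natt, 5000, 10.0, 0.0055, -1, True, 0.9,
                thr, infested, episode, np.int64(300),
                pend_tree, pend_deadline, pend_state,
                odx, ody, od2,
                x, y, heading, energy, consumption, fate, steps,
                tcol, trow, bep, rng,
            )
            traj.append((int(x[0]), int(y[0]), int(heading[0]),
                         float(energy[0]), int(fate[0])))
            clock += 1
        return traj, natt, steps[0]

    def _drive_reference(self, state):
        beetle = make_beetle(5, 5, energy=12.0, efficiency=1.0, heading=0)
        traj = []
        while beetle.fate == FLYING:
            advance_beetle(state, beetle)
            traj.append((beetle.col, beetle.row, beetle.heading,
                         beetle.energy, beetle.fate))
        return traj


class TestKernelReferenceEquivalence:
    """The compiled stepping loop equals the readable reference ops."""

    def python_run(self, habitat, pop, params, traits, seed):
        state = ObjectState(
            habitat=habitat,
            params=params,
            traits=traits,
            n_attackers=np.zeros_like(habitat.pa),
            rng=np.random.default_rng(seed),
        )
        beetles = [
            Beetle(
                beetle_id=int(pop.beetle_id[i]),
                cohort=int(pop.cohort[i]),
                start_step=int(pop.start_step[i]),
                energy=float(pop.energy0[i]),
                efficiency=float(pop.efficiency[i]),
                heading=int(pop.heading0[i]),
                col=pop.source[0],
                row=pop.source[1],
            )
            for i in range(pop.size)
        ]
        clock = 0
        while clock < params.max_steps and any(b.fate == FLYING for b in beetles):
            state.clock = clock
            state.expire_windows()
            active = [
                i for i, b in enumerate(beetles)
                if b.fate == FLYING and b.start_step <= clock
            ]
            for i in range(len(active) - 1, 0, -1):
                j = int(state.rng.random() * (i + 1))
                active[i], active[j] = active[j], active[i]
            for i in active:
                advance_beetle(state, beetles[i])
            clock += 1
        return state, beetles

    def test_full_run_matches_simulation(self, tiny_hab):
        traits = TraitConfig(cohort_size=5, n_cohorts=2, time_lag=3)
        pop = build_cohorts(traits, "S0", tiny_hab.source,
                            np.random.default_rng(21))
        params = EngineParams(capacity_limit=50, threshold_scale=0.05)
        sim = Simulation(tiny_hab, pop, params, traits,
                         np.random.default_rng(77))
        sim.run_wave()
        state, beetles = self.python_run(tiny_hab, pop, params, traits, 77)
        assert np.array_equal(sim.n_attackers, state.n_attackers)
        assert np.array_equal(sim.infested, state.infested)
        for i, b in enumerate(beetles):
            if b.fate == FLYING:  # censored by the wave driver
                continue
            assert (sim.x[i], sim.y[i]) == (b.col, b.row)
            assert sim.fate[i] == b.fate
            assert sim.energy[i] == pytest.approx(b.energy, abs=1e-12)


class TestSimulationInvariants:
    def test_fate_partition_every_step(self, tiny_hab):
        traits = TraitConfig(cohort_size=20, n_cohorts=3, time_lag=2)
        pop = build_cohorts(traits, "S0", tiny_hab.source,
                            np.random.default_rng(3))
        sim = Simulation(tiny_hab, pop, EngineParams().scaled(0.01), traits,
                         np.random.default_rng(4))
        terminal_counts = None
        for _ in range(60):
            sim.step()
            counts = sim.fate_counts()
            assert sum(counts.values()) == pop.size
            terminal = {
                k: counts[k]
                for k in ("success", "died_energy", "died_resistance",
                          "emigrated", "censored")
            }
            if terminal_counts is not None:
                for k, v in terminal.items():
                    assert v >= terminal_counts[k]  # absorbing fates only grow
            terminal_counts = terminal

    def test_cohort_activation(self, tiny_hab):
        traits = TraitConfig(cohort_size=10, n_cohorts=3, time_lag=10)
        pop = build_cohorts(traits, "S2", tiny_hab.source,
                            np.random.default_rng(0))
        sim = Simulation(tiny_hab, pop, EngineParams(), traits,
                         np.random.default_rng(0))
        assert sim.step() == 10  # only cohort 1 active at clock 0
        assert sim.clock == 1

    def test_energy_ledger(self, small_run):
        sim = small_run.sim
        spent = sim.steps_flown * sim.consumption
        assert np.allclose(spent, sim.pop.energy0 - sim.energy, atol=1e-9)

    def test_displacement_bound(self, small_run):
        b = small_run.beetles
        bound = 5.0 * np.sqrt(2.0) * b["steps_flown"].to_numpy()
        assert (b["displacement_m"].to_numpy() <= bound + 1e-9).all()

    def test_infested_density_bounds(self, small_run):
        sim = small_run.sim
        mask = sim.status == INFESTED
        if mask.any():
            thr = resistance_thresholds(sim.pa, sim.params.threshold_scale)
            assert (sim.n_attackers[mask] >= thr[mask]).all()
            assert (sim.n_attackers[mask] <= sim.params.capacity_limit).all()

    def test_nonhosts_never_attacked(self, small_run):
        sim = small_run.sim
        assert (sim.n_attackers[sim.pa == 0] == 0).all()

    def test_attacker_sum_covers_successes(self, small_run):
        # every successful beetle is sitting on its tree at the end
        assert small_run.sim.n_attackers.sum() >= small_run.fate_counts["success"]

    def test_resolve_requires_no_flyers(self, tiny_hab):
        traits = TraitConfig(cohort_size=3, n_cohorts=1)
        pop = build_cohorts(traits, "S2", tiny_hab.source,
                            np.random.default_rng(0))
        sim = Simulation(tiny_hab, pop, EngineParams(), traits,
                         np.random.default_rng(0))
        with pytest.raises(RuntimeError):
            sim.resolve_colonization()


class TestRunSimulation:
    def test_no_hosts_all_die_or_emigrate(self):
        cfg = HabitatConfig("scattered", grid_side=31, scattered_fraction=1e-12)
        traits = TraitConfig(cohort_size=1, n_cohorts=1)
        result = run_simulation(cfg, traits, "S2", EngineParams(), seed=5)
        # habitat is effectively all PA 0..3 with no beetle mass: a single
        # beetle can never overcome any threshold
        assert result.fate_counts["success"] == 0
        assert result.summary()["n_infested_trees"] == 0

    def test_single_beetle_nonhost_grid(self):
        pa = np.zeros((31, 31), dtype=np.int64)
        hab = Habitat(HabitatConfig("resistant", grid_side=31), pa)
        traits = TraitConfig(cohort_size=1, n_cohorts=1)
        pop = build_cohorts(traits, "S2", hab.source, np.random.default_rng(1))
        sim = Simulation(hab, pop, EngineParams(), traits,
                         np.random.default_rng(1))
        sim.run_wave()
        sim.resolve_colonization()
        assert sim.fate[0] in (DIED_ENERGY, EMIGRATED)
        assert (sim.status == INFESTED).sum() == 0

    def test_s2_resistant_near_total_mortality_scaled(self):
        result = run_simulation(
            HabitatConfig("resistant", grid_side=112),
            TraitConfig(cohort_size=1000),
            "S2",
            EngineParams().scaled(0.1),
            seed=0,
        )
        assert result.success_rate <= 0.10

    def test_susceptible_beats_resistant(self):
        kwargs = dict(
            trait_config=TraitConfig(cohort_size=500),
            engine_params=EngineParams().scaled(0.05),
            seed=2,
        )
        sus = run_simulation(HabitatConfig("susceptible", grid_side=96),
                             scenario="S0", **kwargs)
        res = run_simulation(HabitatConfig("resistant", grid_side=96),
                             scenario="S0", **kwargs)
        assert sus.success_rate > res.success_rate

    def test_bit_reproducible(self):
        kwargs = dict(
            habitat_config=HabitatConfig("scattered", grid_side=64),
            trait_config=TraitConfig(cohort_size=100, n_cohorts=3),
            scenario="S0",
            engine_params=EngineParams().scaled(0.02),
        )
        a = run_simulation(seed=9, **kwargs)
        b = run_simulation(seed=9, **kwargs)
        pd.testing.assert_frame_equal(a.beetles, b.beetles)
        assert np.array_equal(a.sim.n_attackers, b.sim.n_attackers)

    def test_seed_changes_outcome(self):
        kwargs = dict(
            habitat_config=HabitatConfig("scattered", grid_side=64),
            trait_config=TraitConfig(cohort_size=100, n_cohorts=3),
            scenario="S0",
            engine_params=EngineParams().scaled(0.02),
        )
        a = run_simulation(seed=1, **kwargs)
        b = run_simulation(seed=2, **kwargs)
        assert not a.beetles.equals(b.beetles)

    def test_censoring_at_max_steps(self):
        pa = np.zeros((61, 61), dtype=np.int64)
        hab = Habitat(HabitatConfig("resistant", grid_side=61), pa)
        traits = TraitConfig(cohort_size=5, n_cohorts=1)
        pop = build_cohorts(traits, "S1", hab.source, np.random.default_rng(8))
        sim = Simulation(hab, pop, EngineParams(max_steps=10), traits,
                         np.random.default_rng(8))
        sim.run_wave()
        sim.resolve_colonization()
        assert (sim.fate == CENSORED).sum() + (sim.fate == EMIGRATED).sum() == 5

    def test_summary_contents(self, small_run):
        s = small_run.summary()
        assert s["n_beetles"] == 1000
        assert 0.0 <= s["success_rate"] <= 1.0
        assert sum(s["fate_counts"].values()) == s["n_beetles"]


class TestEngineParams:
    def test_pheromone_ceiling_must_exceed_kairomone(self):
        with pytest.raises(ValueError):
            EngineParams(pheromone_attractiveness=9.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(attack_coefficient=0.0),
            dict(pheromone_gain=0.0),
            dict(capacity_limit=0),
            dict(max_steps=0),
            dict(attack_window=0),
            dict(pheromone_trigger="sometimes"),
            dict(target_preference="farthest"),
            dict(boundary_mode="wrap"),
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            EngineParams(**kwargs)

    def test_scaled(self):
        p = EngineParams().scaled(0.1)
        assert p.capacity_limit == 500
        assert p.threshold_scale == pytest.approx(0.1)
        assert p.pheromone_gain == pytest.approx(0.055)
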