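import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fidf.swarm_core import (
    Behavior,
    Swarm,
    SwarmConfig,
    acceleration_schedule,
    adapt_behavior,
    attractors_of,
    build_hierarchy,
    hhpso_velocity_update,
    inertia_weight,
    position_update,
    pso_velocity_update,
)


class FixedRng:
    """Stub random source emitting preset uniform draws."""

    def __init__(self, *values):
        self.values = list(values)

    def random(self, n):
        v = self.values.pop(0)
        return np.full(n, v) if np.isscalar(v) else np.asarray(v)

    def integers(self, high):
        return 0


class TestSchedules:
    def test_endpoints_and_midpoint(self):
        cfg = SwarmConfig(n_t=100)
        assert acceleration_schedule(0, cfg) == (2.5, 0.5)
        assert acceleration_schedule(100, cfg) == (0.5, 2.5)
        assert acceleration_schedule(50, cfg) == (1.5, 1.5)

    def test_c1_decreasing_c2_increasing(self):
        cfg = SwarmConfig(n_t=50)
        c1s, c2s = zip(*(acceleration_schedule(t, cfg) for t in range(51)))
        assert all(a > b for a, b in zip(c1s, c1s[1:]))
        assert all(a < b for a, b in zip(c2s, c2s[1:]))

    def test_inertia_decreasing(self):
        cfg = SwarmConfig(n_t=10)
        ws = [inertia_weight(t, cfg) for t in range(11)]
        assert ws[0] == cfg.omega_max and ws[-1] == cfg.omega_min
        assert all(a > b for a, b in zip(ws, ws[1:]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SwarmConfig(n_t=0)
        with pytest.raises(ValueError):
            SwarmConfig(n=50, layers=7)
        with pytest.raises(ValueError):
            SwarmConfig(theta=1.0)


class TestVelocityUpdates:
    def test_zero_when_everything_coincides(self):
        x = np.array([0.2, 0.8])
        v = pso_velocity_update(
            np.zeros(2), x, x, x, 0.5, 2.0, 2.0, 0.2, np.random.default_rng(0)
        )
        assert np.all(v == 0)

    def test_direct_substitution(self):
        # V' = 0.5*1 + 1*1*0.2 + 1*1*0.4 = 1.1, then clamped at vmax
        v = pso_velocity_update(
            np.array([1.0]), np.array([0.0]), np.array([0.4]), np.array([0.2]),
            0.5, 1.0, 1.0, 10.0, FixedRng(1.0, 1.0),
        )
        assert v[0] == pytest.approx(1.1)

    def test_zero_random_draws_give_pure_inertia(self):
        v = pso_velocity_update(
            np.array([0.5, -0.5]), np.zeros(2), np.ones(2), np.ones(2),
            0.7, 2.0, 2.0, 10.0, FixedRng(0.0, 0.0),
        )
        assert np.allclose(v, 0.7 * np.array([0.5, -0.5]))

    def test_clamped_to_vmax(self):
        v = pso_velocity_update(
            np.array([5.0]), np.zeros(1), np.ones(1), np.ones(1),
            1.0, 2.0, 2.0, 0.2, np.random.default_rng(0),
        )
        assert np.all(np.abs(v) <= 0.2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pso_velocity_update(
                np.zeros(3), np.zeros(2), np.zeros(3), np.zeros(3),
                0.5, 1.0, 1.0, 0.2, np.random.default_rng(0),
            )

    def test_no_attractors_matches_standard_update(self):
        rng1, rng2 = np.random.default_rng(4), np.random.default_rng(4)
        args = (np.array([0.1, -0.1]), np.array([0.3, 0.6]),
                np.array([0.9, 0.2]), np.array([0.5, 0.5]))
        v_pso = pso_velocity_update(*args, 0.6, 1.5, 1.5, 0.5, rng1)
        v_hh = hhpso_velocity_update(
            args[0], args[1], args[2], args[3], np.empty((0, 2)),
            0.6, 1.5, 1.5, 0.5, 0.5, rng2,
        )
        assert np.array_equal(v_pso, v_hh)

    def test_attractor_at_own_position_contributes_nothing(self):
        x = np.array([0.4, 0.4])
        v = hhpso_velocity_update(
            np.zeros(2), x, x, x, x[None, :], 0.5, 1.0, 1.0, 0.5, 1.0,
            np.random.default_rng(0),
        )
        assert np.all(v == 0)

    def test_two_attractor_substitution(self):
        # other terms zero; 0.5*1*0.2 + 0.5*1*(-0.1) = 0.05
        x = np.zeros(1)
        attractors = np.array([[0.2], [-0.1]])
        v = hhpso_velocity_update(
            np.zeros(1), x, x, x, attractors, 0.5, 1.0, 1.0, 0.5, 1.0,
            FixedRng(0.0, 0.0, 1.0, 1.0),
        )
        assert v[0] == pytest.approx(0.05)


class TestPositionUpdate:
    def test_direct_and_clamped(self):
        assert position_update(np.array([0.5]), np.array([0.3]))[0] == pytest.approx(0.8)
        assert position_update(np.array([0.9]), np.array([0.5]))[0] == 1.0
        assert position_update(np.array([0.1]), np.array([-0.5]))[0] == 0.0

    def test_zero_velocity_is_identity(self):
        x = np.array([0.1, 0.9])
        assert np.array_equal(position_update(x, np.zeros(2)), x)

    @given(
        x=st.floats(0, 1), v=st.floats(-10, 10)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_position_always_in_unit_interval(self, x, v):
        out = position_update(np.array([x]), np.array([v]))
        assert 0.0 <= out[0] <= 1.0


class TestHierarchy:
    def test_sorted_into_singleton_layers(self):
        layers = build_hierarchy(np.array([0.3, 0.1, 0.2]), 3)
        assert layers.tolist() == [[1], [2], [0]]

    def test_fifty_particles_five_layers(self):
        layers = build_hierarchy(np.random.default_rng(0).random(50), 5)
        assert layers.shape == (5, 10)

    def test_ties_fill_in_index_order(self):
        layers = build_hierarchy(np.zeros(6), 3)
        assert layers.tolist() == [[0, 1], [2, 3], [4, 5]]

    def test_indivisible_population_rejected(self):
        with pytest.raises(ValueError):
            build_hierarchy(np.zeros(7), 3)

    def test_attractors_top_layer_strictly_better(self):
        fitness = np.arange(20, dtype=float)
        layers = build_hierarchy(fitness, 2)
        assert sorted(attractors_of(layers, fitness, 2).tolist()) == [0, 1]
        assert attractors_of(layers, fitness, 0).size == 0

    def test_attractors_lower_layer_is_superior_layer(self):
        fitness = np.arange(30, dtype=float)
        layers = build_hierarchy(fitness, 3)
        assert sorted(attractors_of(layers, fitness, 25).tolist()) == list(range(10, 20))

    def test_unknown_particle_rejected(self):
        layers = build_hierarchy(np.zeros(4), 2)
        with pytest.raises(KeyError):
            attractors_of(layers, np.zeros(4), 99)


class TestBehaviorAdaptation:
    def test_no_trigger_keeps_behavior(self):
        cfg = SwarmConfig(stagnation_limit=10)
        b, c = adapt_behavior(
            Behavior.FULL, 3, np.zeros(4), np.ones((1, 4)), cfg,
            np.random.default_rng(0),
        )
        assert b is Behavior.FULL and c == 3

    def test_stagnation_triggers_switch_and_reset(self):
        cfg = SwarmConfig(stagnation_limit=10)
        for seed in range(5):
            b, c = adapt_behavior(
                Behavior.FULL, 10, np.zeros(4), np.empty((0, 4)), cfg,
                np.random.default_rng(seed),
            )
            assert b is not Behavior.FULL and c == 0

    def test_crowding_triggers_switch(self):
        cfg = SwarmConfig(stagnation_limit=10, crowding_epsilon=1e-3)
        x = np.full(4, 0.5)
        b, c = adapt_behavior(
            Behavior.SOCIAL_ONLY, 0, x, x[None, :], cfg, np.random.default_rng(1)
        )
        assert b is not Behavior.SOCIAL_ONLY and c == 0


class TestSwarmRuns:
    def _run(self, seed, iters=60, hierarchical=True):
        cfg = SwarmConfig(n=20, layers=4, n_t=iters, seed=seed)
        swarm = Swarm(6, cfg, hierarchical=hierarchical)
        rng = np.random.default_rng(1234)
        traj = []
        for t in range(iters):
            fitness = swarm.positions.sum(axis=1) + rng.random(cfg.n)
            swarm.evaluate(fitness)
            swarm.rank()
            swarm.move(t)
            traj.append((swarm.positions.copy(), swarm.velocities.copy(),
                         swarm.global_best_fitness))
        return swarm, traj

    def test_bounds_hold_every_iteration(self):
        swarm, traj = self._run(0)
        for pos, vel, _ in traj:
            assert np.all((pos >= 0) & (pos <= 1))
            assert np.all(np.abs(vel) <= swarm.cfg.vmax)

    def test_global_best_non_increasing(self):
        _, traj = self._run(1)
        best = [g for _, _, g in traj]
        assert all(a >= b for a, b in zip(best, best[1:]))

    def test_global_best_is_min_personal_best(self):
        swarm, _ = self._run(2)
        assert swarm.global_best_fitness == pytest.approx(
            swarm.personal_best_fitness.min()
        )

    def test_identical_seeds_identical_trajectories(self):
        _, t1 = self._run(5)
        _, t2 = self._run(5)
        for (p1, v1, g1), (p2, v2, g2) in zip(t1, t2):
            assert np.array_equal(p1, p2) and np.array_equal(v1, v2) and g1 == g2

    def test_personal_best_never_worse_than_seen(self):
        cfg = SwarmConfig(n=8, layers=4, n_t=40, seed=9)
        swarm = Swarm(5, cfg)
        rng = np.random.default_rng(55)
        seen_best = np.full(cfg.n, np.inf)
        for t in range(40):
            fitness = rng.random(cfg.n)
            swarm.evaluate(fitness)
            seen_best = np.minimum(seen_best, fitness)
            assert np.all(swarm.personal_best_fitness <= seen_best + 1e-15)
            swarm.rank()
            swarm.move(t)
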