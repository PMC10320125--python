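"""Glowworm Swarm Optimization engine: update rules, neighborhoods, movement."""

import numpy as np
import pytest

import glowdock as gd
from glowdock.gso import (
    Glowworm,
    GSOParameters,
    find_neighbors,
    luciferin_update,
    move_glowworm,
    run_swarm,
    select_target,
    update_vision_range,
)
from glowdock.pose import Pose
from glowdock.sampling import Swarm


def _worm(x, y, luciferin, wid, vision=5.0):
    return Glowworm(Pose([x, y, 0.0]), luciferin, vision, id=wid)


class TestLuciferinUpdate:
    def test_formula(self):
        params = GSOParameters(rho=0.4, gamma=0.6)
        assert np.isclose(luciferin_update(5.0, 2.0, params), 4.2)

    def test_full_decay_returns_scaled_objective(self):
        params = GSOParameters(rho=1.0, gamma=1.0)
        assert luciferin_update(123.0, 2.5, params) == 2.5

    def test_fixed_point_is_gamma_j_over_rho(self):
        params = GSOParameters()
        ell, J = 0.0, 7.0
        for _ in range(200):
            ell = luciferin_update(ell, J, params)
        assert np.isclose(ell, params.gamma * J / params.rho)
        assert np.isclose(params.gamma / params.rho, 1.5)


class TestFindNeighbors:
    def test_equal_luciferin_gives_empty_sets(self):
        pop = [_worm(i, 0, 3.0, i) for i in range(4)]
        assert all(find_neighbors(w, pop) == [] for w in pop)

    def test_brighter_agent_outside_range_excluded(self):
        a = _worm(0, 0, 1.0, 0, vision=2.0)
        b = _worm(2.0, 0, 5.0, 1)  # exactly at the (open) boundary
        assert find_neighbors(a, [a, b]) == []

    def test_matches_exhaustive_double_loop_oracle(self, rng):
        pop = [
            Glowworm(Pose(rng.normal(size=3) * 3), float(rng.random() * 10),
                     float(rng.random() * 6), id=i)
            for i in range(6)
        ]
        for agent in pop:
            oracle = []
            for other in pop:  # brute force, no shortcuts
                if other.id == agent.id:
                    continue
                d = np.linalg.norm(other.pose.translation - agent.pose.translation)
                if d < agent.vision_range and other.luciferin > agent.luciferin:
                    oracle.append(other.id)
            assert sorted(n.id for n in find_neighbors(agent, pop)) == sorted(oracle)


class TestSelectTarget:
    def test_single_neighbor_always_chosen(self, rng):
        a = _worm(0, 0, 1.0, 0)
        b = _worm(1, 0, 4.0, 1)
        assert select_target(a, [b], rng) is b

    def test_roulette_frequencies_match_excess_ratios(self):
        a = _worm(0, 0, 1.0, 0)
        n1, n2 = _worm(1, 0, 2.0, 1), _worm(0, 1, 3.0, 2)
        rng = np.random.default_rng(2024)
        counts = {1: 0, 2: 0}
        for _ in range(100_000):
            counts[select_target(a, [n1, n2], rng).id] += 1
        assert abs(counts[1] / 100_000 - 1 / 3) < 0.01
        assert abs(counts[2] / 100_000 - 2 / 3) < 0.01

    def test_equal_excess_is_symmetric(self):
        a = _worm(0, 0, 1.0, 0)
        n1, n2 = _worm(1, 0, 3.0, 1), _worm(0, 1, 3.0, 2)
        rng = np.random.default_rng(7)
        freq = sum(select_target(a, [n1, n2], rng).id == 1 for _ in range(100_000)) / 100_000
        assert abs(freq - 0.5) < 0.01


class TestMoveGlowworm:
    def test_step_equal_to_distance_lands_on_target(self):
        params = GSOParameters(s=5.0)
        a = _worm(0, 0, 1.0, 0)
        b = _worm(3, 4, 2.0, 1)
        moved = move_glowworm(a, b, params)
        assert np.allclose(moved.translation, b.pose.translation, atol=1e-6)

    def test_zero_distance_is_noop(self):
        params = GSOParameters()
        a = _worm(1, 1, 1.0, 0)
        b = Glowworm(a.pose.copy(), 2.0, 5.0, id=1)
        assert np.allclose(move_glowworm(a, b, params).translation, a.pose.translation)

    def test_translation_distance_shrinks_by_step(self):
        params = GSOParameters(s=0.5)
        a = _worm(0, 0, 1.0, 0)
        b = _worm(10, 0, 2.0, 1)
        moved = move_glowworm(a, b, params)
        d = np.linalg.norm(b.pose.translation - moved.translation)
        assert np.isclose(d, 10.0 - 0.5)

    def test_quaternion_stays_unit_and_canonical(self, rng):
        params = GSOParameters(s=1.0)
        a = Glowworm(gd.random_pose([0, 0, 0], 3, 0, rng), 1.0, 5.0, id=0)
        b = Glowworm(gd.random_pose([0, 0, 0], 3, 0, rng), 2.0, 5.0, id=1)
        moved = move_glowworm(a, b, params)
        assert np.isclose(np.linalg.norm(moved.rotation), 1.0, atol=1e-9)
        assert moved.rotation[0] >= 0


class TestUpdateVisionRange:
    def test_formula(self):
        params = GSOParameters(beta=0.08, n_t=5, r_s=3.0)
        assert np.isclose(update_vision_range(2.0, 7, params), 1.84)

    def test_clamped_to_rs(self):
        params = GSOParameters(beta=10.0, n_t=5, r_s=3.0)
        assert update_vision_range(2.9, 0, params) == 3.0

    def test_clamped_to_zero(self):
        params = GSOParameters(beta=10.0, n_t=1, r_s=3.0)
        assert update_vision_range(0.1, 30, params) == 0.0


def three_gaussian_objective(pose: Pose) -> float:
    """Surrogate 2-D landscape with maxima at (0,0), (6,6), (-7,4)."""
    x, y = pose.translation[0], pose.translation[1]
    total = 0.0
    for (mx, my, h) in ((0.0, 0.0, 3.0), (6.0, 6.0, 2.5), (-7.0, 4.0, 2.0)):
        total += h * np.exp(-(((x - mx) ** 2 + (y - my) ** 2) / 2.0))
    return total


def _surrogate_swarm(n_agents, params, seed):
    rng = np.random.default_rng(seed)
    worms = [
        Glowworm(Pose([*rng.uniform(-10, 10, 2), 0.0]), params.ell0,
                 params.initial_vision or params.r_s / 2.0, id=i)
        for i in range(n_agents)
    ]
    return Swarm(id=0, center=np.zeros(3), radius=10.0, glowworms=worms)


class TestRunSwarm:
    def test_localizes_multiple_gaussian_maxima(self):
        params = GSOParameters(steps=100, r_s=6.0, s=0.3)
        swarm = _surrogate_swarm(50, params, seed=42)
        run_swarm(swarm, three_gaussian_objective, params, seed=42)
        maxima = np.array([[0.0, 0.0], [6.0, 6.0], [-7.0, 4.0]])
        found = set()
        for w in swarm.glowworms:
            d = np.linalg.norm(maxima - w.pose.translation[:2], axis=1)
            if d.min() <= 0.5:
                found.add(int(d.argmin()))
        assert len(found) >= 2

    def test_constant_objective_freezes_population(self):
        params = GSOParameters(steps=10)
        swarm = _surrogate_swarm(20, params, seed=0)
        before = [w.pose.translation.copy() for w in swarm.glowworms]
        run_swarm(swarm, lambda pose: 1.0, params, seed=0)
        after = [w.pose.translation for w in swarm.glowworms]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_default_parameters_run_100_iterations(self):
        params = GSOParameters()
        assert params.steps == 100
        swarm = _surrogate_swarm(5, params, seed=1)
        _, trace = run_swarm(swarm, three_gaussian_objective, params, seed=1)
        assert len(trace) == 100

    def test_identical_seeds_reproduce_trajectories(self):
        params = GSOParameters(steps=30, s=0.3)
        a = _surrogate_swarm(20, params, seed=5)
        b = _surrogate_swarm(20, params, seed=5)
        run_swarm(a, three_gaussian_objective, params, seed=5)
        run_swarm(b, three_gaussian_objective, params, seed=5)
        for wa, wb in zip(a.glowworms, b.glowworms):
            assert np.array_equal(wa.pose.translation, wb.pose.translation)
            assert wa.luciferin == wb.luciferin

    def test_running_best_score_non_decreasing(self):
        params = GSOParameters(steps=50, s=0.3)
        swarm = _surrogate_swarm(30, params, seed=3)
        _, trace = run_swarm(swarm, three_gaussian_objective, params, seed=3)
        running = np.maximum.accumulate(trace)
        assert np.all(np.diff(running) >= 0)

    def test_non_finite_objective_never_attracts(self):
        params = GSOParameters(steps=5)

        def exploding(pose):
            x = pose.translation[0]
            return np.nan if x > 0 else 1.0 + 0.01 * x

        swarm = _surrogate_swarm(20, params, seed=8)
        run_swarm(swarm, exploding, params, seed=8)
        bad = [w for w in swarm.glowworms if w.pose.translation[0] > 0]
        assert all(w.score == -np.inf for w in bad)
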