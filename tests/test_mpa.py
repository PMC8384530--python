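"""Marine Predators Algorithm mechanics, primitives and optimization power."""

import json
from pathlib import Path

import numpy as np
import pytest

from mpacnn.mpa import (
    EliteMatrix,
    MPAConfig,
    PreyPopulation,
    abs1d,
    brownian_step,
    compute_cf,
    fads_effect,
    init_population,
    levy_step,
    optimize,
    phase1_update,
    phase2_update,
    phase3_update,
    phase_for_iteration,
    sphere,
)

import reference_mpa as ref

FIXTURES = Path(__file__).parent / "fixtures"


def make_pop(rng, n=4, d=3, lo=-5.0, hi=5.0):
    cfg = MPAConfig(d=d, x_min=lo, x_max=hi, n=n, max_iter=9, seed=0)
    positions = rng.uniform(lo, hi, size=(n, d))
    pop = PreyPopulation(positions=positions, costs=np.array([sphere(p) for p in positions]))
    elite = EliteMatrix(top_predator=rng.uniform(lo, hi, size=d), top_cost=0.0)
    return cfg, pop, elite


class TestPrimitives:
    def test_cf_boundary_values(self):
        assert compute_cf(0, 200) == pytest.approx(1.0)
        assert compute_cf(100, 200) == pytest.approx(0.5)
        assert compute_cf(200, 200) == 0.0
        with pytest.raises(ValueError):
            compute_cf(201, 200)

    def test_cf_monotone_decreasing_on_grid(self):
        grid = [compute_cf(it, 200) for it in range(201)]
        assert all(a >= b for a, b in zip(grid, grid[1:]))
        assert all(0.0 <= v <= 1.0 for v in grid)

    def test_brownian_moments(self):
        rng = np.random.default_rng(7)
        x = brownian_step((100_000,), rng)
        assert abs(x.mean()) < 3 / np.sqrt(x.size)
        assert abs(x.var() - 1.0) < 3 * np.sqrt(2.0 / x.size)

    def test_brownian_seed_reproducibility(self):
        a = brownian_step((10,), np.random.default_rng(3))
        b = brownian_step((10,), np.random.default_rng(3))
        c = brownian_step((10,), np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_levy_tail_index_near_alpha(self):
        rng = np.random.default_rng(11)
        x = np.abs(levy_step((1_000_000,), 1.5, rng))
        # regress log exceedance on log t over one decade of thresholds
        ts = np.logspace(1, 2, 12)
        exceed = np.array([(x > t).mean() for t in ts])
        slope = np.polyfit(np.log(ts), np.log(exceed), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.15)

    def test_levy_alpha_two_has_far_lighter_tails(self):
        # the stable family approaches the Gaussian as alpha -> 2: rare long
        # jumps all but vanish relative to alpha = 1.5
        x2 = np.abs(levy_step((200_000,), 2.0, np.random.default_rng(5)))
        x15 = np.abs(levy_step((200_000,), 1.5, np.random.default_rng(6)))
        assert (x15 > 10).mean() > 30 * max((x2 > 10).mean(), 1e-6)

    def test_levy_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            levy_step((3,), 2.5, np.random.default_rng(0))


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MPAConfig(d=2, x_min=1.0, x_max=-1.0)
        with pytest.raises(ValueError):
            MPAConfig(d=2, x_min=-1.0, x_max=1.0, n=1)
        with pytest.raises(ValueError):
            MPAConfig(d=2, x_min=-1.0, x_max=1.0, max_iter=2)
        with pytest.raises(ValueError):
            MPAConfig(d=2, x_min=-1.0, x_max=1.0, fads=1.5)

    def test_phase_dispatch_partitions_budget(self):
        phases = [phase_for_iteration(it, 9) for it in range(9)]
        assert phases == [1, 1, 1, 2, 2, 2, 3, 3, 3]
        # every phase non-empty for any budget >= 3
        for t in (3, 4, 5, 7, 200):
            seen = {phase_for_iteration(it, t) for it in range(t)}
            assert seen == {1, 2, 3}


class TestInitPopulation:
    def test_positions_within_bounds_and_uniform_moments(self):
        cfg = MPAConfig(d=4, x_min=-1.0, x_max=1.0, n=1000, max_iter=3)
        pop = init_population(cfg, sphere, np.random.default_rng(0))
        assert (pop.positions >= -1).all() and (pop.positions <= 1).all()
        se = np.sqrt(1 / 3 / 1000)  # std of the mean of U(-1,1)
        assert (np.abs(pop.positions.mean(axis=0)) < 3 * se).all()

    def test_seeded_rerun_identical(self):
        cfg = MPAConfig(d=3, x_min=0.0, x_max=1.0, n=20, max_iter=3)
        a = init_population(cfg, sphere, np.random.default_rng(9))
        b = init_population(cfg, sphere, np.random.default_rng(9))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.costs, b.costs)

    def test_nonfinite_objective_propagates(self):
        cfg = MPAConfig(d=2, x_min=-1.0, x_max=1.0, n=5, max_iter=3)
        with pytest.raises(ValueError, match="non-finite"):
            init_population(cfg, lambda x: float("nan"), np.random.default_rng(0))


class TestPhaseTranscription:
    """Each phase matches an entrywise scalar transcription on a shared stream."""

    def test_phase1_matches_scalar_oracle(self, rng):
        cfg, pop, elite = make_pop(rng)
        stream = np.random.default_rng(42)
        out = phase1_update(pop, elite, cfg, np.random.default_rng(42))
        rb = stream.standard_normal((4, 3))
        r = stream.random((4, 3))
        expected = ref.ref_phase1(pop.positions, elite.top_predator, cfg.P,
                                  rb, r, cfg.x_min, cfg.x_max)
        np.testing.assert_allclose(out.positions, expected, atol=1e-12)

    def test_phase2_matches_scalar_oracle(self, rng):
        cfg, pop, elite = make_pop(rng)
        cf = compute_cf(4, 9)
        stream = np.random.default_rng(43)
        out = phase2_update(pop, elite, cfg, np.random.default_rng(43), cf)
        n1 = 2
        rl = cfg.levy_scale * ref.ref_levy_from_normals(
            stream.standard_normal((n1, 3)), stream.standard_normal((n1, 3)), 1.5)
        r = stream.random((n1, 3))
        rb = stream.standard_normal((2, 3))
        expected = ref.ref_phase2(pop.positions, elite.top_predator, cfg.P, cf,
                                  rl, r, rb, cfg.x_min, cfg.x_max)
        np.testing.assert_allclose(out.positions, expected, atol=1e-12)

    def test_phase3_matches_scalar_oracle(self, rng):
        cfg, pop, elite = make_pop(rng)
        cf = compute_cf(7, 9)
        stream = np.random.default_rng(44)
        out = phase3_update(pop, elite, cfg, np.random.default_rng(44), cf)
        rl = cfg.levy_scale * ref.ref_levy_from_normals(
            stream.standard_normal((4, 3)), stream.standard_normal((4, 3)), 1.5)
        expected = ref.ref_phase3(pop.positions, elite.top_predator, cfg.P, cf,
                                  rl, cfg.x_min, cfg.x_max)
        np.testing.assert_allclose(out.positions, expected, atol=1e-12)

    def test_fads_both_branches_match_scalar_oracle(self, rng):
        cfg, pop, elite = make_pop(rng)
        cf = compute_cf(4, 9)
        for seed in range(12):  # seeds hit both branches of the r <= FADs split
            stream = np.random.default_rng(seed)
            out = fads_effect(pop, cfg, cf, np.random.default_rng(seed))
            r = stream.random()
            if r <= cfg.fads:
                u = (stream.random((4, 3)) < cfg.fads).astype(float)
                rand_box = cfg.x_min + stream.random((4, 3)) * (cfg.x_max - cfg.x_min)
                expected = ref.ref_fads(pop.positions, cfg.fads, cf, r, u, rand_box,
                                        None, None, cfg.x_min, cfg.x_max)
            else:
                r1 = stream.permutation(4)
                r2 = stream.permutation(4)
                expected = ref.ref_fads(pop.positions, cfg.fads, cf, r, None, None,
                                        r1, r2, cfg.x_min, cfg.x_max)
            np.testing.assert_allclose(out.positions, expected, atol=1e-12)

    def test_phase_stubs_zero_step_leaves_prey_unchanged(self, rng):
        cfg, pop, elite = make_pop(rng)

        class ZeroUniform:
            def standard_normal(self, shape):
                return np.ones(shape)

            def random(self, shape=None):
                return np.zeros(shape) if shape else 0.0

        out = phase1_update(pop, elite, cfg, ZeroUniform())
        np.testing.assert_array_equal(out.positions, pop.positions)

    def test_fads_small_population_rejected(self, rng):
        cfg = MPAConfig(d=2, x_min=-1.0, x_max=1.0, n=2, max_iter=3)
        pop = PreyPopulation(positions=np.zeros((2, 2)), costs=np.zeros(2))
        with pytest.raises(ValueError):
            fads_effect(pop, cfg, 0.5, np.random.default_rng(0))


class TestOptimize:
    def test_history_monotone_and_feasible(self):
        cfg = MPAConfig(d=6, x_min=-10.0, x_max=10.0, n=12, max_iter=60, seed=5)
        res = optimize(sphere, cfg)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))
        assert (np.abs(res.best_position) <= 10).all()
        assert res.best_cost == pytest.approx(sphere(res.best_position))

    def test_constant_objective(self):
        cfg = MPAConfig(d=3, x_min=-1.0, x_max=1.0, n=8, max_iter=12, seed=0)
        res = optimize(lambda x: 7.25, cfg)
        assert res.best_cost == 7.25

    def test_seed_determinism(self):
        cfg = MPAConfig(d=4, x_min=-5.0, x_max=5.0, n=10, max_iter=30, seed=17)
        a = optimize(sphere, cfg)
        b = optimize(sphere, cfg)
        assert a.history == b.history
        np.testing.assert_array_equal(a.best_position, b.best_position)

    def test_abs1d_locates_minimum_in_most_seeds(self):
        hits = 0
        for seed in range(20):
            cfg = MPAConfig(d=1, x_min=0.0, x_max=1.0, n=10, max_iter=60, seed=seed)
            res = optimize(abs1d, cfg)
            hits += abs(res.best_position[0] - 0.3) < 0.05
        assert hits >= 18

    def test_memoryless_variant_still_monotone_history(self):
        cfg = MPAConfig(d=4, x_min=-5.0, x_max=5.0, n=10, max_iter=30, seed=2,
                        memory_saving=False)
        res = optimize(sphere, cfg)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))


def test_sphere_matches_independent_reference_runs():
    """Full-loop agreement with the frozen scalar-transcription reference."""
    fixture = json.loads((FIXTURES / "sphere_reference.json").read_text())
    s = fixture["settings"]
    finals = []
    for seed in s["seeds"][:5]:
        cfg = MPAConfig(d=s["d"], x_min=s["bounds"][0], x_max=s["bounds"][1],
                        n=s["n"], max_iter=s["max_iter"], seed=seed)
        finals.append(optimize(sphere, cfg).best_cost)
    for ours, ref_cost in zip(finals, fixture["per_seed_final_cost"][:5]):
        assert ours == pytest.approx(ref_cost, rel=1e-9)
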