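"""Bee-colony operators: initialization statistics, neighbor feasibility,
local-search monotonicity, full-loop behavior."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import beezone as bz
from beezone.iabc import (alter_repair, generate_neighbor, replace_region_poor,
                          replace_region_rect, swap_local_search)

W = bz.Weights(0.4, 0.3, 0.3)
SPEC = bz.CompactnessSpec(3)


def _uniform_grid(n):
    return bz.SuitabilityGrid(eco=np.full((n, n), 0.5), dev=np.full((n, n), 0.5))


class TestCompleteRandomInit:
    def test_quota_forced_when_all_cells_needed(self, rng):
        grid = bz.random_instance(4, 4, rng, blocked_fraction=0.3)
        q = grid.n_configurable
        x = bz.init_complete_random(grid, q, rng)
        assert np.array_equal(x, grid.configurable)

    def test_seed_determinism(self, grid4):
        a = bz.init_complete_random(grid4, 5, np.random.default_rng(7))
        b = bz.init_complete_random(grid4, 5, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_quota_exceeding_eligible_cells_rejected(self, grid4):
        with pytest.raises(bz.ConfigurationError):
            bz.init_complete_random(grid4, 17, np.random.default_rng(0))

    def test_uniform_selection_frequency(self, rng):
        grid = _uniform_grid(3)
        counts = np.zeros(9)
        n_draws = 10_000
        for _ in range(n_draws):
            counts += bz.init_complete_random(grid, 1, rng).ravel()
        p = 1 / 9
        sigma = np.sqrt(p * (1 - p) / n_draws)
        assert np.all(np.abs(counts / n_draws - p) <= 3 * sigma + 1e-12)


class TestPseudoRandomInit:
    def test_pure_greedy_is_top_q(self, grid4):
        x = bz.init_pseudo_random(grid4, 5, W, np.random.default_rng(0),
                                  best_fraction=1.0)
        s = bz.site_score(grid4, W).ravel()
        expected = np.argsort(-s, kind="stable")[:5]
        assert set(np.flatnonzero(x.ravel())) == set(expected)

    def test_invariants_hold(self, rng):
        grid = bz.random_instance(8, 8, rng, blocked_fraction=0.2)
        for _ in range(20):
            x = bz.init_pseudo_random(grid, 6, W, rng, best_fraction=0.5)
            assert x.sum() == 6
            assert not np.any(x & ~grid.configurable)

    def test_equal_scores_give_uniform_roulette(self, rng):
        grid = _uniform_grid(3)  # site score constant
        counts = np.zeros(9)
        n_draws = 6_000
        for _ in range(n_draws):
            counts += bz.init_pseudo_random(grid, 1, W, rng,
                                            best_fraction=0.0).ravel()
        p = 1 / 9
        sigma = np.sqrt(p * (1 - p) / n_draws)
        assert np.all(np.abs(counts / n_draws - p) <= 3 * sigma + 1e-12)

    def test_zero_scores_fall_back_to_uniform(self, rng):
        grid = bz.SuitabilityGrid(eco=np.zeros((4, 4)), dev=np.ones((4, 4)))
        x = bz.init_pseudo_random(grid, 5, bz.Weights(0.5, 0.5, 0.0), rng,
                                  best_fraction=0.0)
        assert x.sum() == 5


class TestPopulation:
    def test_pure_complete_random_population(self, grid4):
        cfg = bz.IABCConfig(q=4, weights=W, sn=4, init_pseudo_prob=0.0)
        pop = bz.initialize_population(grid4, cfg, np.random.default_rng(3))
        assert len(pop) == 4
        for fs in pop:
            assert fs.trials == 0
            assert fs.fitness == pytest.approx(
                bz.evaluate_fitness(fs.x, grid4, W, SPEC, 4))

    def test_greedy_population_is_identical(self, grid4):
        cfg = bz.IABCConfig(q=4, weights=W, sn=3, init_pseudo_prob=1.0,
                            init_best_fraction=1.0)
        pop = bz.initialize_population(grid4, cfg, np.random.default_rng(3))
        assert np.array_equal(pop[0].x, pop[1].x)
        assert np.array_equal(pop[0].x, pop[2].x)


class TestRoulette:
    def test_symmetric_fitnesses(self, rng):
        counts = np.zeros(4)
        for _ in range(10_000):
            counts[bz.roulette_select([0.3, 0.3, 0.3, 0.3], rng)] += 1
        p = 0.25
        sigma = np.sqrt(p * (1 - p) / 10_000)
        assert np.all(np.abs(counts / 10_000 - p) <= 3 * sigma)

    def test_proportional_frequencies(self, rng):
        fits = [0.2, 0.3, 0.5]
        counts = np.zeros(3)
        for _ in range(10_000):
            counts[bz.roulette_select(fits, rng)] += 1
        for j, p in enumerate(fits):
            sigma = np.sqrt(p * (1 - p) / 10_000)
            assert abs(counts[j] / 10_000 - p) <= 3 * sigma

    def test_single_positive_always_wins(self, rng):
        for _ in range(50):
            assert bz.roulette_select([0.0, 0.0, 0.7, 0.0], rng) == 2

    def test_all_zero_falls_back_to_uniform(self, rng):
        seen = {bz.roulette_select([0.0, 0.0], rng) for _ in range(100)}
        assert seen == {0, 1}


class TestReplaceRegions:
    def test_rect_identical_neighbor_is_noop(self, grid4, rng):
        x = bz.init_complete_random(grid4, 5, rng)
        out, region = replace_region_rect(x, x, rng)
        assert np.array_equal(out, x)
        assert region.any()

    def test_rect_semantics(self, rng):
        # inside the region the result equals the partner, outside the source
        grid = _uniform_grid(8)
        for _ in range(50):
            xa = bz.init_complete_random(grid, 10, rng)
            xb = bz.init_complete_random(grid, 10, rng)
            out, region = replace_region_rect(xa, xb, rng)
            assert np.array_equal(out[region], xb[region])
            assert np.array_equal(out[~region], xa[~region])

    def test_poor_region_targets_worst_cell(self, rng):
        eco = np.full((4, 4), 1.0)
        eco[2, 3] = 0.0  # unique worst protected site
        grid = bz.SuitabilityGrid(eco=eco, dev=np.zeros((4, 4)))
        x = np.zeros((4, 4), dtype=bool)
        x[2, 2] = x[2, 3] = x[1, 1] = True
        xb = ~x  # arbitrary partner
        out, region = replace_region_poor(x, xb, grid, bz.Weights(1, 0, 0), 3,
                                          np.random.default_rng(0))
        assert region[2, 3]

    def test_poor_region_identical_neighbor_is_noop(self, grid4, rng):
        x = bz.init_complete_random(grid4, 5, rng)
        out, _ = replace_region_poor(x, x, grid4, W, 5, rng)
        assert np.array_equal(out, x)


class TestAlterRepair:
    def test_balanced_input_returned_as_is(self, grid4, rng):
        x = bz.init_complete_random(grid4, 5, rng)
        region = np.zeros((4, 4), dtype=bool)
        out = alter_repair(x, region, grid4, W, SPEC, 5, "best", rng)
        assert np.array_equal(out, x)

    @pytest.mark.parametrize("strategy", ["best", "random"])
    def test_quota_restored_over_random_moves(self, strategy, rng):
        grid = bz.random_instance(8, 8, rng, blocked_fraction=0.15)
        q = 12
        for _ in range(250):
            xa = bz.init_complete_random(grid, q, rng)
            xb = bz.init_complete_random(grid, q, rng)
            xm, region = replace_region_rect(xa, xb, rng)
            out = alter_repair(xm, region, grid, W, SPEC, q, strategy, rng)
            if out is not None:
                assert out.sum() == q
                assert not np.any(out & ~grid.configurable)

    def test_best_strategy_removes_least_valuable_cell(self):
        # one surplus protected cell: A1 should drop the zero-score one
        eco = np.ones((5, 5))
        eco[4, 4] = 0.0
        grid = bz.SuitabilityGrid(eco=eco, dev=np.zeros((5, 5)))
        x = np.zeros((5, 5), dtype=bool)
        x[0, 0] = x[0, 1] = x[1, 0] = x[4, 4] = True  # q should be 3
        region = np.zeros((5, 5), dtype=bool)
        region[0, :2] = True
        out = alter_repair(x, region, grid, bz.Weights(1, 0, 0), SPEC, 3,
                           "best", np.random.default_rng(0))
        assert out is not None and not out[4, 4] and out.sum() == 3

    def test_infeasible_repair_returns_none(self, grid4, rng):
        x = bz.init_complete_random(grid4, 5, rng)
        xm = x.copy()
        xm[np.argwhere(~x)[0][0], np.argwhere(~x)[0][1]] = True  # count 6
        region = np.ones((4, 4), dtype=bool)  # nowhere outside to repair
        assert alter_repair(xm, region, grid4, W, SPEC, 5, "random", rng) is None


class TestGenerateNeighbor:
    def test_identical_partner_returns_same_solution(self, grid4, rng):
        cfg = bz.IABCConfig(q=5, weights=W)
        x = bz.init_complete_random(grid4, 5, rng)
        out, degenerate = generate_neighbor(x, x, grid4, cfg, rng)
        assert np.array_equal(out, x)
        assert not degenerate

    @given(seed=st.integers(0, 2**16))
    def test_output_always_feasible(self, seed):
        r = np.random.default_rng(seed)
        grid = bz.random_instance(8, 8, r, blocked_fraction=0.2)
        q = min(10, grid.n_configurable)
        cfg = bz.IABCConfig(q=q, weights=W)
        xa = bz.init_complete_random(grid, q, r)
        xb = bz.init_complete_random(grid, q, r)
        out, _ = generate_neighbor(xa, xb, grid, cfg, r)
        assert out.sum() == q
        assert not np.any(out & ~grid.configurable)


class TestSwapLocalSearch:
    def test_restores_separable_optimum_after_one_displacement(self):
        rng = np.random.default_rng(5)
        grid = bz.random_instance(5, 5, rng, blocked_fraction=0.0)
        w = bz.Weights(0.6, 0.4, 0.0)
        q = 6
        opt = bz.density_slice(grid, w, q).x
        f_opt = bz.evaluate_fitness(opt, grid, w, SPEC, q)
        # displace one optimal cell to the worst free cell
        s = bz.site_score(grid, w)
        worst_free = np.unravel_index(
            np.argmin(np.where(~opt, s, np.inf)), (5, 5))
        best_in = np.unravel_index(np.argmin(np.where(opt, s, np.inf)), (5, 5))
        x = opt.copy()
        x[best_in] = False
        x[worst_free] = True
        cfg = bz.IABCConfig(q=q, weights=w, swap_count_range=(3, 3))
        fs = bz.FoodSource(x, bz.evaluate_fitness(x, grid, w, SPEC, q))
        out = swap_local_search(fs, grid, cfg, np.random.default_rng(0))
        assert out.fitness == pytest.approx(f_opt)

    def test_local_optimum_returned_unchanged(self):
        grid = _uniform_grid(4)
        # uniform landscape with a full corner block: compactness-optimal
        x = np.zeros((4, 4), dtype=bool)
        x[:2, :2] = True
        cfg = bz.IABCConfig(q=4, weights=W, swap_count_range=(5, 5))
        fs = bz.FoodSource(x, bz.evaluate_fitness(x, grid, W, SPEC, 4))
        out = swap_local_search(fs, grid, cfg, np.random.default_rng(0))
        assert out is fs

    def test_fitness_never_decreases(self, rng):
        cfg_cache = {}
        for _ in range(500):
            grid = bz.random_instance(6, 6, rng, blocked_fraction=0.1)
            q = min(8, grid.n_configurable)
            cfg = cfg_cache.setdefault(q, bz.IABCConfig(
                q=q, weights=W, swap_count_range=(2, 6)))
            x = bz.init_complete_random(grid, q, rng)
            fs = bz.FoodSource(x, bz.evaluate_fitness(x, grid, W, SPEC, q))
            out = swap_local_search(fs, grid, cfg, rng)
            assert out.fitness >= fs.fitness - 1e-12


class TestRunIABC:
    def test_zero_cycles_returns_best_initial_source(self, grid4):
        cfg = bz.IABCConfig(q=4, weights=W, sn=5, mcn=0, rng_seed=11)
        res = bz.run_iabc(grid4, cfg)
        pop = bz.initialize_population(grid4, cfg, np.random.default_rng(11))
        assert res.best_fitness == pytest.approx(max(fs.fitness for fs in pop))
        assert len(res.fitness_trace) == 1

    def test_seeded_runs_are_bit_reproducible(self, grid4):
        cfg = bz.IABCConfig(q=4, weights=W, sn=4, mcn=20, rng_seed=42)
        r1 = bz.run_iabc(grid4, cfg)
        r2 = bz.run_iabc(grid4, cfg)
        assert np.array_equal(r1.best_solution.x, r2.best_solution.x)
        assert np.array_equal(r1.fitness_trace, r2.fitness_trace)
        assert r1.scout_events == r2.scout_events

    def test_trace_nondecreasing_and_final_solution_valid(self, rng):
        grid = bz.random_instance(10, 10, rng, blocked_fraction=0.2)
        cfg = bz.IABCConfig(q=12, weights=W, sn=6, mcn=30, limit=10, rng_seed=2)
        res = bz.run_iabc(grid, cfg)
        assert np.all(np.diff(res.fitness_trace) >= 0)
        assert res.best_fitness == res.fitness_trace[-1]
        res.best_solution.validate(grid, 12)

    def test_scouts_fire_under_tight_limit(self, rng):
        grid = bz.random_instance(6, 6, rng, blocked_fraction=0.0)
        cfg = bz.IABCConfig(q=5, weights=W, sn=4, mcn=40, limit=3, rng_seed=3)
        res = bz.run_iabc(grid, cfg)
        assert res.scout_events > 0

    def test_infeasible_quota_rejected(self, grid4):
        cfg = bz.IABCConfig(q=20, weights=W)
        with pytest.raises(bz.ConfigurationError):
            bz.run_iabc(grid4, cfg)

    def test_trace_frame_columns(self, grid4):
        cfg = bz.IABCConfig(q=4, weights=W, sn=3, mcn=5, rng_seed=1)
        frame = bz.run_iabc(grid4, cfg).to_frame()
        assert list(frame.columns) == ["iteration", "global_best_fitness",
                                       "ecological", "development",
                                       "compactness"]
        assert len(frame) == 6


def test_config_validation():
    with pytest.raises(bz.ConfigurationError):
        bz.IABCConfig(q=0)
    with pytest.raises(bz.ConfigurationError):
        bz.IABCConfig(q=5, sn=1)
    with pytest.raises(bz.ConfigurationError):
        bz.IABCConfig(q=5, init_pseudo_prob=1.5)
    with pytest.raises(bz.ConfigurationError):
        bz.IABCConfig(q=5, swap_count_range=(7, 3))
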