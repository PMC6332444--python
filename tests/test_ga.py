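import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from sasmd.ga import (GAConfig, aggregate_objective, entropy, evolve,
                      init_populations, narrow_space, update_probabilities)

BOUNDS = [(-math.pi, math.pi), (0.0, math.pi / 2)]


class TestInitPopulations:
    def test_counts_and_bounds(self):
        cfg = GAConfig(m=16, pop_size=20)
        pops = init_populations(BOUNDS, cfg, np.random.default_rng(0))
        assert len(pops) == 16
        total = sum(len(p.individuals) for p in pops)
        assert total == 320
        for p in pops:
            assert np.all(p.individuals >= p.lower)
            assert np.all(p.individuals <= p.upper)

    def test_deterministic_per_seed(self):
        cfg = GAConfig()
        a = init_populations(BOUNDS, cfg, np.random.default_rng(3))
        b = init_populations(BOUNDS, cfg, np.random.default_rng(3))
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.individuals, pb.individuals)

    def test_members_uniform_about_midpoint(self):
        cfg = GAConfig(m=16, pop_size=50)
        pops = init_populations(BOUNDS, cfg, np.random.default_rng(1))
        x = np.vstack([p.individuals for p in pops])
        lo = np.array([b[0] for b in BOUNDS])
        hi = np.array([b[1] for b in BOUNDS])
        se = (hi - lo) / np.sqrt(12 * len(x))
        assert np.all(np.abs(x.mean(axis=0) - (lo + hi) / 2) < 3 * se)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            init_populations([(0.0, 0.0)], GAConfig(), np.random.default_rng(0))


class TestProbabilities:
    def test_equal_fitnesses_give_uniform(self):
        p = update_probabilities(np.full(16, 2.5))
        assert np.allclose(p, 1 / 16)

    def test_dominant_population_takes_almost_all_mass(self):
        p = update_probabilities([0.0, 1e9])
        assert p[0] > 0.99 and p[1] < 0.01

    def test_better_fitness_gets_higher_probability(self):
        f = np.array([3.0, 1.0, 2.0, 5.0])
        for strategy in ("softmax", "rank"):
            p = update_probabilities(f, strategy)
            assert np.argsort(p).tolist() == np.argsort(-f).tolist()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=16),
           st.floats(-1000, 1000))
    def test_shift_invariance(self, f, c):
        f = np.asarray(f)
        # exclude spreads at the float-cancellation scale of the shift
        assume(np.ptp(f) == 0 or np.ptp(f) > 1e-3)
        p1 = update_probabilities(f)
        p2 = update_probabilities(f + c)
        assert np.allclose(p1, p2, atol=1e-12)
        assert p1.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            update_probabilities([1.0, np.inf])


class TestEntropy:
    def test_uniform_sixteen_is_ln_sixteen(self):
        assert entropy(np.full(16, 1 / 16)) == pytest.approx(math.log(16), abs=1e-12)

    def test_degenerate_distribution_has_zero_entropy(self):
        p = np.zeros(8)
        p[0] = 1.0
        assert entropy(p) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=16))
    def test_bounded_by_ln_m(self, w):
        p = np.asarray(w) / np.sum(w)
        h = entropy(p)
        assert -1e-12 <= h <= math.log(len(p)) + 1e-12

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            entropy([0.5, 0.6])


class TestNarrowSpace:
    def make_pop(self):
        cfg = GAConfig(m=2, pop_size=10)
        pop = init_populations(BOUNDS, cfg, np.random.default_rng(0))[0]
        pop.best_member = np.array([0.5, 0.4])
        pop.best_fitness = 1.0
        return pop

    def test_zero_probability_keeps_extent(self):
        pop = self.make_pop()
        e0 = pop.space_size.copy()
        narrow_space(pop, 0.0, 1, np.random.default_rng(0))
        assert np.allclose(pop.space_size, e0)
        # centred on the best member, clamped to the initial box
        assert np.allclose(pop.lower,
                           np.maximum(pop.best_member - 0.5 * e0, pop.initial_lower))
        assert np.allclose(pop.upper,
                           np.minimum(pop.best_member + 0.5 * e0, pop.initial_upper))

    def test_unit_probability_collapses_to_best(self):
        pop = self.make_pop()
        narrow_space(pop, 1.0, 1, np.random.default_rng(0))
        assert np.allclose(pop.space_size, 0.0)
        assert np.allclose(pop.lower, pop.best_member)
        assert np.allclose(pop.upper, pop.best_member)

    def test_constant_probability_recursion(self):
        pop = self.make_pop()
        e0 = pop.space_size.copy()
        for k in range(1, 8):
            narrow_space(pop, 0.3, k, np.random.default_rng(k))
            assert np.allclose(pop.space_size, 0.7**k * e0, atol=1e-12)

    def test_members_redrawn_inside_new_bounds(self):
        pop = self.make_pop()
        narrow_space(pop, 0.8, 1, np.random.default_rng(1))
        assert np.all(pop.individuals >= pop.lower - 1e-12)
        assert np.all(pop.individuals <= pop.upper + 1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_bounds_never_leave_initial_box(self, ps):
        pop = self.make_pop()
        rng = np.random.default_rng(0)
        for k, pj in enumerate(ps, start=1):
            pop.best_member = rng.uniform(-4, 4, 2)  # even wild best members
            narrow_space(pop, pj, k, rng)
            assert np.all(pop.lower >= pop.initial_lower - 1e-12)
            assert np.all(pop.upper <= pop.initial_upper + 1e-12)


class TestAggregate:
    def test_entropy_weight_zero_reduces_to_expected_fitness(self):
        cfg = GAConfig(entropy_weights=(1.0, 0.0))
        f = np.array([1.0, 2.0, 3.0])
        p = np.array([0.5, 0.3, 0.2])
        assert aggregate_objective(f, p, cfg) == pytest.approx((p * f).sum())

    def test_uniform_p_gives_mean_fitness(self):
        cfg = GAConfig(entropy_weights=(1.0, 0.0))
        f = np.array([1.0, 5.0])
        assert aggregate_objective(f, [0.5, 0.5], cfg) == pytest.approx(3.0)

    def test_simplex_minimizer_is_degenerate_on_best(self):
        """Fine grid over the m=2 simplex: the scalarized objective is
        minimized by all mass on the better population."""
        cfg = GAConfig(entropy_weights=(1.0, 0.1))
        f = np.array([1.0, 2.0])
        grid = np.linspace(0.0, 1.0, 2001)
        vals = [aggregate_objective(f, [q, 1 - q], cfg) for q in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(1.0, abs=1e-3)


class TestEvolve:
    def quad(self, X):
        X = np.atleast_2d(X)
        return (X[:, 0] - 0.8) ** 2 + 2.0 * (X[:, 1] - 0.5) ** 2

    def test_finds_quadratic_minimum_against_grid(self):
        gx = np.linspace(BOUNDS[0][0], BOUNDS[0][1], 500)
        gy = np.linspace(BOUNDS[1][0], BOUNDS[1][1], 200)
        G = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
        grid_best = self.quad(G).min()
        best_x, best_f, hist = evolve(self.quad, BOUNDS, GAConfig(seed=0),
                                      vectorized=True)
        assert abs(best_f - grid_best) < 1e-3
        assert np.allclose(best_x, [0.8, 0.5], atol=1e-2)

    def test_best_fitness_is_monotone_non_increasing(self):
        _, _, hist = evolve(self.quad, BOUNDS, GAConfig(seed=1), vectorized=True)
        assert np.all(np.diff(hist.best_f) <= 0)
        assert all(0 <= h <= math.log(16) + 1e-12 for h in hist.H)

    def test_deterministic_per_seed(self):
        r1 = evolve(self.quad, BOUNDS, GAConfig(seed=7), vectorized=True)
        r2 = evolve(self.quad, BOUNDS, GAConfig(seed=7), vectorized=True)
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]

    def test_bimodal_global_basin_found_in_most_seeds(self):
        def bimodal(X):
            X = np.atleast_2d(X)
            g = -np.exp(-((X[:, 0] + 1.5) ** 2 + (X[:, 1] - 0.9) ** 2) / 0.25)
            h = -0.5 * np.exp(-((X[:, 0] - 1.5) ** 2 + (X[:, 1] - 0.4) ** 2) / 0.25)
            return g + h

        hits = 0
        for seed in range(20):
            best_x, _, _ = evolve(bimodal, BOUNDS, GAConfig(seed=seed),
                                  vectorized=True)
            if np.linalg.norm(best_x - [-1.5, 0.9]) < 0.3:
                hits += 1
        assert hits >= 18

    def test_non_finite_fitness_quarantined(self):
        def leaky(X):
            X = np.atleast_2d(X)
            out = self.quad(X)
            out[X[:, 0] < -2.0] = np.nan
            return out

        best_x, best_f, hist = evolve(leaky, BOUNDS, GAConfig(seed=3),
                                      vectorized=True)
        assert np.isfinite(best_f)
        assert hist.n_nonfinite > 0
        assert abs(best_f) < 1e-2

    def test_no_evaluation_outside_design_space(self):
        lo = np.array([b[0] for b in BOUNDS])
        hi = np.array([b[1] for b in BOUNDS])

        def checked(X):
            X = np.atleast_2d(X)
            assert np.all(X >= lo - 1e-12) and np.all(X <= hi + 1e-12)
            return self.quad(X)

        evolve(checked, BOUNDS, GAConfig(seed=5), vectorized=True)

    def test_discrete_toy_links_probability_and_aggregate_to_best(self):
        """With constant per-population fitnesses, the best population gets
        the top probability and the scalarized optimum is the plain
        minimum -- the coupled and the direct formulations agree."""
        f = np.array([4.0, 2.0, 9.0, 7.0])
        p = update_probabilities(f)
        assert int(np.argmax(p)) == int(np.argmin(f))
        cfg = GAConfig(entropy_weights=(1.0, 0.1))
        # exhaustive enumeration over degenerate distributions
        cand = [aggregate_objective(f, np.eye(4)[j], cfg) for j in range(4)]
        assert int(np.argmin(cand)) == int(np.argmin(f))
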