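import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from ptmpack.energy import PackingSystem
from ptmpack.fixtures import make_packing_puzzle
from ptmpack.ga import (GAConfig, Population, blx_crossover, clip_angles, evolve,
                        init_population, mutate_polynomial, mutate_von_mises,
                        sbx_beta, sbx_crossover, tournament_select)
from ptmpack.mcmc import PackingTask
from ptmpack.rotamers import LibrarySet, Rotamer, RotamerLibrary

PI = math.pi

angle_arrays = st.lists(st.floats(-PI + 1e-9, PI), min_size=1, max_size=8).map(np.array)


class TestConfig:
    def test_defaults_match_published_settings(self):
        cfg = GAConfig()
        assert cfg.crossover_prob == 0.9
        assert cfg.mutation_prob == 0.15
        assert cfg.elitism_fraction == 0.15
        assert cfg.tournament_fraction == pytest.approx(1.0 / 20.0)
        assert cfg.blx_alpha == 0.5
        assert cfg.sbx_eta == 12
        assert cfg.population_size == 300
        assert cfg.generations == 40

    def test_tournament_size_rounding(self):
        assert GAConfig(population_size=300).tournament_size == 15
        assert GAConfig(population_size=10).tournament_size == 1

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=0)


class TestInit:
    def test_uniform_genes_pass_ks(self, puzzle_system):
        cfg = GAConfig(population_size=2000, init_mode="uniform", seed=0)
        rng = np.random.default_rng(0)
        pop = init_population(puzzle_system, cfg, None, rng)
        flat = pop.genes.ravel()
        assert kstest(flat, "uniform", args=(-PI, 2 * PI)).pvalue > 0.001
        assert np.all(pop.sigma > 0) and np.all(pop.sigma <= 0.5)

    def test_rotamer_mode_single_rotamer_degenerate(self, puzzle):
        lib = RotamerLibrary("SER", 1, (Rotamer((-60.0,), (8.0,), 1.0),))
        libs = LibrarySet(by_code={"SER": lib})
        system = PackingSystem(puzzle.structure, puzzle.movable)
        pop = init_population(system, GAConfig(population_size=20), libs,
                              np.random.default_rng(1))
        assert np.allclose(pop.genes, math.radians(-60.0))
        assert np.allclose(pop.sigma, math.radians(8.0))

    def test_rotamer_mode_without_libraries_rejected(self, puzzle_system):
        with pytest.raises(ValueError, match="librar"):
            init_population(puzzle_system, GAConfig(), None, np.random.default_rng(0))


class TestTournament:
    def make_pop(self, fitness):
        n = len(fitness)
        return Population(np.zeros((n, 1)), np.full((n, 1), 0.1),
                          np.array(fitness, dtype=float))

    def test_full_tournament_returns_global_best(self):
        pop = self.make_pop([5.0, 1.0, 3.0, 4.0])
        rng = np.random.default_rng(0)
        assert all(tournament_select(pop, 4, rng) == 1 for _ in range(20))

    def test_k1_is_uniform(self):
        pop = self.make_pop(list(range(10)))
        rng = np.random.default_rng(1)
        counts = np.bincount([tournament_select(pop, 1, rng) for _ in range(20_000)],
                             minlength=10)
        assert np.all(np.abs(counts / 20_000 - 0.1) < 0.02)

    def test_k2_rank_probabilities(self):
        # P(rank r wins | k=2, N) = 2 (N - 1 - r) / (N (N - 1)), ranks 0-based
        N = 10
        pop = self.make_pop(list(range(N)))
        rng = np.random.default_rng(2)
        n = 100_000
        counts = np.bincount([tournament_select(pop, 2, rng) for _ in range(n)],
                             minlength=N)
        for r in range(N):
            expected = 2.0 * (N - 1 - r) / (N * (N - 1))
            assert counts[r] / n == pytest.approx(expected, abs=0.01)

    def test_out_of_range_k_rejected(self):
        pop = self.make_pop([1.0, 2.0])
        with pytest.raises(ValueError):
            tournament_select(pop, 3, np.random.default_rng(0))


class TestBLX:
    @given(p1=angle_arrays, data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_alpha_zero_contained_in_parent_interval(self, p1, data):
        p2 = data.draw(st.lists(st.floats(-PI + 1e-9, PI),
                                min_size=len(p1), max_size=len(p1)).map(np.array))
        rng = np.random.default_rng(0)
        c1, c2 = blx_crossover(p1, p2, 0.0, rng)
        lo, hi = np.minimum(p1, p2), np.maximum(p1, p2)
        for c in (c1, c2):
            assert np.all(c >= lo - 1e-12) and np.all(c <= hi + 1e-12)

    def test_alpha_half_doubles_interval(self):
        rng = np.random.default_rng(3)
        draws = np.array([blx_crossover(np.array([-1.0]), np.array([1.0]), 0.5, rng)[0][0]
                          for _ in range(20_000)])
        # children uniform over [-2, 2]; no clipping needed inside (-pi, pi)
        assert draws.min() < -1.8 and draws.max() > 1.8
        assert kstest(draws, "uniform", args=(-2.0, 4.0)).pvalue > 0.001

    def test_identical_parents_give_identical_children(self):
        p = np.array([0.3, -2.0])
        c1, c2 = blx_crossover(p, p, 0.5, np.random.default_rng(0))
        assert np.allclose(c1, p) and np.allclose(c2, p)

    def test_results_clipped_to_domain(self):
        rng = np.random.default_rng(4)
        p1, p2 = np.array([-3.0]), np.array([3.0])
        for _ in range(200):
            c1, c2 = blx_crossover(p1, p2, 0.5, rng)
            for c in (c1, c2):
                assert -PI < c[0] <= PI


class TestSBX:
    def test_beta_at_half_is_one(self):
        for eta in (1.0, 5.0, 12.0, 30.0):
            assert sbx_beta(0.5, eta) == pytest.approx(1.0, abs=1e-12)

    def test_beta_small_mu_limit(self):
        assert sbx_beta(1e-12, 12.0) < 0.15

    def test_beta_closed_form_value(self):
        assert sbx_beta(0.9, 12.0) == pytest.approx(5.0 ** (1.0 / 13.0), abs=1e-12)

    def test_beta_mu_one_capped_finite(self):
        assert np.isfinite(sbx_beta(1.0, 12.0))

    @given(p1=angle_arrays, data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mean_preservation_before_clipping(self, p1, data):
        p2 = data.draw(st.lists(st.floats(-PI / 2, PI / 2),
                                min_size=len(p1), max_size=len(p1)).map(np.array))
        p1 = np.clip(p1, -PI / 2, PI / 2)  # keep offspring inside the domain
        rng = np.random.default_rng(0)
        beta = sbx_beta(rng.uniform(size=p1.shape), 12.0)
        c1, c2 = sbx_crossover(p1, p2, 12.0, rng, beta=np.minimum(beta, 1.0))
        assert np.allclose(c1 + c2, p1 + p2, atol=1e-9)

    def test_beta_one_copies_parents(self):
        p1, p2 = np.array([0.3, -1.0]), np.array([-0.5, 2.0])
        c1, c2 = sbx_crossover(p1, p2, 12.0, np.random.default_rng(0),
                               beta=np.ones(2))
        assert np.allclose(c1, p1) and np.allclose(c2, p2)

    def test_beta_half_hand_values(self):
        c1, c2 = sbx_crossover(np.array([0.0]), np.array([1.0]), 12.0,
                               np.random.default_rng(0), beta=np.array([0.5]))
        assert c1[0] == pytest.approx(0.25)
        assert c2[0] == pytest.approx(0.75)


class TestMutation:
    def test_von_mises_tiny_sigma_keeps_gene(self):
        genes = np.array([0.4])
        # sigma is floored at 1 degree, so the draw stays within a few
        # hundredths of a radian of the original gene
        out = mutate_von_mises(genes, np.array([1e-6]), np.random.default_rng(0))
        assert out[0] == pytest.approx(0.4, abs=0.06)

    def test_von_mises_spread_matches_concentration(self):
        sigma = 0.2  # k = 25
        rng = np.random.default_rng(1)
        draws = np.array([mutate_von_mises(np.array([0.0]), np.array([sigma]), rng)[0]
                          for _ in range(10_000)])
        z = abs(np.mean(np.exp(1j * draws)))
        circ_sigma = math.sqrt(-2.0 * math.log(z))
        assert abs(circ_sigma - sigma) / sigma < 0.15

    def test_von_mises_output_in_domain(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            out = mutate_von_mises(np.array([3.1]), np.array([1.0]), rng)
            assert -PI < out[0] <= PI

    def test_polynomial_symmetric_at_center(self):
        rng = np.random.default_rng(3)
        draws = np.array([mutate_polynomial(np.array([0.0]), 20.0, rng)[0]
                          for _ in range(100_000)])
        assert abs(draws.mean()) < 0.01

    def test_polynomial_respects_bounds(self):
        rng = np.random.default_rng(4)
        for x0 in (-3.0, 0.0, 3.0):
            for _ in range(300):
                out = mutate_polynomial(np.array([x0]), 20.0, rng)
                assert -PI < out[0] <= PI

    def test_polynomial_large_eta_vanishing_perturbation(self):
        rng = np.random.default_rng(5)
        draws = np.array([mutate_polynomial(np.array([0.5]), 1e7, rng)[0]
                          for _ in range(200)])
        assert np.max(np.abs(draws - 0.5)) < 1e-3


class TestEvolve:
    def test_zero_generations_with_single_rotamer_library(self, puzzle):
        lib = RotamerLibrary("SER", 1, (Rotamer((-60.0,), (8.0,), 1.0),))
        libs = LibrarySet(by_code={"SER": lib})
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        cfg = GAConfig(population_size=10, generations=0, init_mode="rotamer", seed=0)
        result = evolve(task, cfg, library_set=libs)
        assert np.allclose(result.best_genes, -60.0, atol=1e-9)

    def test_reaches_enumeration_minimum(self, puzzle, puzzle_system):
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        hits = 0
        for seed in range(10):
            r = evolve(task, GAConfig(init_mode="uniform", seed=seed),
                       system=puzzle_system)
            hits += r.best_energy <= puzzle.oracle_energy + 0.1
        assert hits >= 9

    def test_elitism_keeps_best_fitness_non_increasing(self, puzzle, puzzle_system):
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        log = []
        evolve(task, GAConfig(population_size=60, generations=25,
                              init_mode="uniform", seed=5),
               system=puzzle_system, log=log)
        best = [row[1] for row in log]
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_deterministic_under_seed(self, puzzle, puzzle_system):
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        cfg = GAConfig(population_size=40, generations=10, init_mode="uniform", seed=7)
        r1 = evolve(task, cfg, system=puzzle_system)
        r2 = evolve(task, cfg, system=puzzle_system)
        assert r1.best_energy == r2.best_energy
        assert np.allclose(r1.best_genes, r2.best_genes)

    def test_all_genes_in_domain_after_evolution(self, puzzle, puzzle_system):
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        r = evolve(task, GAConfig(population_size=30, generations=15,
                                  init_mode="uniform", seed=8),
                   system=puzzle_system)
        rad = np.radians(r.best_genes)
        assert np.all(rad > -PI - 1e-9) and np.all(rad <= PI + 1e-9)


def test_clip_angles_half_open():
    x = np.array([-4.0, -PI, 0.0, PI, 4.0])
    out = clip_angles(x)
    assert np.all(out > -PI) and np.all(out <= PI)
    assert out[1] == PI and out[3] == PI
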