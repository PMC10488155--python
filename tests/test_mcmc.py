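import math

import numpy as np
import pytest
from scipy.special import i0, i1

from ptmpack.energy import PackingSystem
from ptmpack.fixtures import make_packing_puzzle
from ptmpack.geometry import wrap_degrees
from ptmpack.mcmc import (MCMCConfig, PackingTask, VonMisesParams,
                          metropolis_accept, propose_offrotamer_move,
                          propose_rotamer_move, repack_mcmc, sample_von_mises)
from ptmpack.rotamers import LibrarySet, Rotamer, RotamerLibrary


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-1.0, t, rng) for t in (0.1, 1.0, 10.0))

    def test_zero_delta_accepted(self):
        rng = np.random.default_rng(0)
        assert metropolis_accept(0.0, 1.0, rng)

    def test_acceptance_at_delta_equal_temperature(self):
        rng = np.random.default_rng(42)
        n = 100_000
        acc = sum(metropolis_accept(2.5, 2.5, rng) for _ in range(n))
        assert acc / n == pytest.approx(math.exp(-1.0), abs=0.005)


class TestVonMises:
    def test_high_concentration_pins_to_mode(self):
        rng = np.random.default_rng(1)
        draws = [sample_von_mises(VonMisesParams(0.7, 1e6), rng) for _ in range(200)]
        assert max(abs(d - 0.7) for d in draws) < 0.01

    def test_low_concentration_is_nearly_uniform(self):
        rng = np.random.default_rng(2)
        d = np.array([sample_von_mises(VonMisesParams(0.0, 1e-6), rng)
                      for _ in range(10_000)])
        resultant = abs(np.mean(np.exp(1j * d)))
        assert resultant < 0.05

    def test_moments_match_bessel_ratio(self):
        mu, k = 1.0, 4.0
        rng = np.random.default_rng(3)
        d = np.array([sample_von_mises(VonMisesParams(mu, k), rng)
                      for _ in range(100_000)])
        z = np.mean(np.exp(1j * d))
        assert np.angle(z) == pytest.approx(mu, abs=0.01)
        assert abs(z) == pytest.approx(i1(k) / i0(k), abs=0.01)

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValueError):
            VonMisesParams(0.0, 0.0)
        with pytest.raises(ValueError):
            VonMisesParams(0.0, math.inf)


class TestProposals:
    def test_single_rotamer_always_its_mean(self, puzzle, puzzle_system):
        lib = RotamerLibrary("SER", 1, (Rotamer((-60.0,), (8.0,), 1.0),))
        libs = LibrarySet(by_code={"SER": lib})
        rng = np.random.default_rng(0)
        sys1 = PackingSystem(puzzle.structure, puzzle.movable[:1])
        for _ in range(20):
            r, chi = propose_rotamer_move(sys1, libs, rng)
            assert r == 0 and chi[0] == pytest.approx(-60.0)

    def test_residue_choice_uniform(self, puzzle, puzzle_system):
        rng = np.random.default_rng(5)
        counts = np.zeros(puzzle_system.n_residues)
        n = 10_000
        for _ in range(n):
            r, _ = propose_rotamer_move(puzzle_system, puzzle.libraries, rng)
            counts[r] += 1
        assert np.all(np.abs(counts / n - 1.0 / 3.0) < 0.02)

    def test_offrotamer_spread_recovers_sigma(self):
        sigma_deg = 10.0
        lib = RotamerLibrary("SER", 1, (Rotamer((0.0,), (sigma_deg,), 1.0),))
        libs = LibrarySet(by_code={"SER": lib})
        pz = make_packing_puzzle(1, [2], seed=0)
        system = PackingSystem(pz.structure, pz.movable)
        rng = np.random.default_rng(6)
        chis = np.array([propose_offrotamer_move(system, libs, rng)[1][0]
                         for _ in range(10_000)])
        z = np.mean(np.exp(1j * np.radians(chis)))
        circ_sigma = math.degrees(math.sqrt(-2.0 * math.log(abs(z))))
        assert abs(circ_sigma - sigma_deg) / sigma_deg < 0.15

    def test_offrotamer_leaves_library_grid(self, puzzle, puzzle_system):
        lib = RotamerLibrary("SER", 1, (Rotamer((-60.0,), (20.0,), 1.0),))
        libs = LibrarySet(by_code={"SER": lib})
        rng = np.random.default_rng(7)
        off_grid = 0
        n = 2000
        for _ in range(n):
            _, chi = propose_offrotamer_move(puzzle_system, libs, rng)
            if abs(float(wrap_degrees(chi[0] + 60.0))) > 0.1:
                off_grid += 1
        assert off_grid / n > 0.99


class TestRepack:
    def test_zero_steps_returns_input(self, puzzle, puzzle_system):
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        result = repack_mcmc(task, MCMCConfig(steps=0, seed=0), puzzle.libraries,
                             system=puzzle_system)
        sc = puzzle_system.current_sidechain_coords()
        assert result.best_energy == pytest.approx(puzzle_system.energy(sc), abs=1e-9)
        orig = puzzle.structure.models[0][0].coords()
        assert np.allclose(result.structure.models[0][0].coords(), orig)

    def test_two_state_toy_picks_clash_free(self):
        pz = make_packing_puzzle(1, [2], seed=0)
        task = PackingTask(pz.structure, pz.site, movable=pz.movable)
        result = repack_mcmc(task, MCMCConfig(steps=200, seed=3), pz.libraries)
        assert result.best_energy == pytest.approx(pz.oracle_energy, abs=1e-9)

    def test_reaches_exhaustive_minimum(self, puzzle, puzzle_system):
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        hits = 0
        for seed in range(20):
            r = repack_mcmc(task, MCMCConfig(steps=5000, seed=seed),
                            puzzle.libraries, system=puzzle_system)
            hits += r.best_energy <= puzzle.oracle_energy + 1e-9
        assert hits >= 19

    def test_deterministic_under_seed(self, puzzle, puzzle_system):
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        r1 = repack_mcmc(task, MCMCConfig(steps=500, seed=11), puzzle.libraries,
                         system=puzzle_system)
        r2 = repack_mcmc(task, MCMCConfig(steps=500, seed=11), puzzle.libraries,
                         system=puzzle_system)
        assert np.array_equal(r1.energy_trace, r2.energy_trace)
        assert np.allclose(r1.best_genes, r2.best_genes)

    def test_best_so_far_trace_non_increasing(self, puzzle, puzzle_system):
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        r = repack_mcmc(task, MCMCConfig(steps=1000, seed=4), puzzle.libraries,
                        system=puzzle_system)
        best = np.minimum.accumulate(r.energy_trace)
        assert np.all(np.diff(best) <= 1e-12)
        assert r.best_energy == pytest.approx(min(best.min(), r.energy_trace[0]))

    def test_rotamer_mode_stays_on_grid_off_mode_does_not(self, puzzle, puzzle_system):
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        r = repack_mcmc(task, MCMCConfig(steps=400, seed=2), puzzle.libraries,
                        system=puzzle_system)
        grid = {-60.0, -120.0, 180.0, -90.0, -150.0}
        for g in r.best_genes:
            assert min(abs(float(wrap_degrees(g - v))) for v in grid) < 1e-9
        r_off = repack_mcmc(task, MCMCConfig(steps=400, mode="off_rotamer", seed=2),
                            puzzle.libraries, system=puzzle_system)
        devs = [min(abs(float(wrap_degrees(g - v))) for v in grid)
                for g in r_off.best_genes]
        assert max(devs) > 0.1

    def test_boltzmann_stationary_occupancy(self):
        """Two-state chain: occupancy of the high-energy state matches
        exp(-dE/T) / (1 + exp(-dE/T)) (uniform proposals, T = 1)."""
        pz = make_packing_puzzle(1, [2], seed=0)
        combos, energies = pz.enumerate_energies()
        dE = float(abs(energies[0] - energies[1]))
        e_high = float(max(energies))
        task = PackingTask(pz.structure, pz.site, movable=pz.movable)
        r = repack_mcmc(task, MCMCConfig(steps=100_000, temperature=1.0, seed=9),
                        pz.libraries)
        occ_high = float(np.mean(np.isclose(r.energy_trace, e_high, atol=1e-9)))
        expected = math.exp(-dE) / (1.0 + math.exp(-dE))
        assert occ_high == pytest.approx(expected, abs=0.02)

    def test_missing_library_raises_at_setup(self, puzzle, puzzle_system):
        task = PackingTask(puzzle.structure, puzzle.site, movable=puzzle.movable)
        with pytest.raises(ValueError, match="no rotamer library"):
            repack_mcmc(task, MCMCConfig(steps=10, seed=0),
                        LibrarySet(), system=puzzle_system)
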