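import numpy as np
import pytest

from ptmpack.energy import (PLATEAU, SLOPE, X_CUT, X_PLATEAU, X_WELL, PackingSystem,
                            evdw, interaction_pairs, load_param_table, pair_params,
                            region_energy)
from ptmpack.fixtures import FixtureSpec, make_toy_structure
from ptmpack.structure import Atom, Residue, Structure


def brute_pairs(structure, movable_atoms, table, reg):
    """O(n^2) reimplementation of the pair enumeration rules."""
    from ptmpack.energy import (_bond_adjacency, _model_atom_table,
                                bonded_exclusions)
    residues, names, elements, res_idx, coords = _model_atom_table(structure, 0, reg)
    adj = _bond_adjacency(residues, names, res_idx, coords, reg)
    excluded = bonded_exclusions(adj)
    keys = [(residues[ri].id, nm) for ri, nm in zip(res_idx, names)]
    movable = {k for k, key in enumerate(keys) if key in set(movable_atoms)}
    out = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if i not in movable and j not in movable:
                continue
            if (i, j) in excluded:
                continue
            pp = pair_params(elements[i], elements[j], table)
            if np.linalg.norm(coords[i] - coords[j]) < X_CUT * pp.sigma_ij:
                out.add((keys[i], keys[j]))
    return out


class TestEvdw:
    def test_plateau_value_any_parameters(self, param_table):
        rng = np.random.default_rng(0)
        for _ in range(20):
            E = rng.uniform(0.01, 1.0)
            s = rng.uniform(2.0, 4.0)
            assert evdw(0.5 * s, Eij=E, sigma_ij=s) == pytest.approx(PLATEAU)

    def test_zero_beyond_cutoff(self):
        assert evdw(2.0 * 3.2, Eij=0.2, sigma_ij=3.2) == 0.0
        assert evdw(100.0, Eij=0.5, sigma_ij=3.0) == 0.0

    def test_well_depth_at_ten_ninths(self):
        # both adjacent branch formulas evaluate to -Eij at x = 10/9
        E, s = 0.2, 3.0
        x = X_WELL
        left = E * (10.0 - 9.0 * x) - E
        right = E / 4.0 * (9.0 * x - 10.0) ** 2 - E
        assert left == pytest.approx(-E)
        assert right == pytest.approx(-E)
        assert evdw(x * s, Eij=E, sigma_ij=s) == pytest.approx(-E, abs=1e-12)

    def test_continuity_at_all_breakpoints(self):
        rng = np.random.default_rng(1)
        eps = 1e-9
        for _ in range(100):
            E = rng.uniform(0.0, 1.0)
            s = rng.uniform(1.5, 4.5)
            for xb in (X_PLATEAU, 1.0, X_WELL, X_CUT):
                lo = evdw((xb - eps) * s, Eij=E, sigma_ij=s)
                hi = evdw((xb + eps) * s, Eij=E, sigma_ij=s)
                assert abs(lo - hi) < 1e-6

    def test_bounded_and_minimum_at_well(self):
        E, s = 0.3, 3.0
        x = np.linspace(1e-3, 3.0, 4001)
        vals = evdw(x * s, Eij=E, sigma_ij=s)
        assert np.all(vals <= PLATEAU + 1e-12)
        assert np.all(vals >= -E - 1e-12)
        assert vals.min() == pytest.approx(-E, abs=1e-6)
        assert x[int(np.argmin(vals))] == pytest.approx(X_WELL, abs=1e-3)

    def test_monotone_down_then_up(self):
        E, s = 0.25, 3.0
        x = np.linspace(1e-3, X_WELL, 2000)
        vals = evdw(x * s, Eij=E, sigma_ij=s)
        assert np.all(np.diff(vals) <= 1e-12)
        x2 = np.linspace(X_WELL, 3.0, 2000)
        vals2 = evdw(x2 * s, Eij=E, sigma_ij=s)
        assert np.all(np.diff(vals2) >= -1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            evdw(-0.1, Eij=0.1, sigma_ij=3.0)

    def test_zero_well_depth_kills_attraction_only(self):
        s = 3.0
        assert evdw(1.05 * s, Eij=0.0, sigma_ij=s) == 0.0
        assert evdw(0.9 * s, Eij=0.0, sigma_ij=s) == pytest.approx(SLOPE * 0.1)


class TestPairParams:
    def test_identical_types(self, param_table):
        p = param_table.get("C")
        pp = pair_params("C", "C", param_table)
        assert pp.Eij == pytest.approx(p.well_depth)
        assert pp.sigma_ij == pytest.approx(2 * p.radius)

    def test_carbon_oxygen_hand_arithmetic(self, param_table):
        c, o = param_table.get("C"), param_table.get("O")
        pp = pair_params("C", "O", param_table)
        assert pp.Eij == pytest.approx(np.sqrt(c.well_depth * o.well_depth), abs=1e-12)
        assert pp.sigma_ij == pytest.approx(c.radius + o.radius, abs=1e-12)

    def test_unknown_type_names_offender(self, param_table):
        with pytest.raises(KeyError, match="Xx"):
            pair_params("C", "Xx", param_table)


class TestInteractionPairs:
    def test_bonded_and_distant_pairs_excluded(self, param_table, reg):
        # chi1 = 180 in a helix puts OG within range of the carbonyl O
        st = make_toy_structure(FixtureSpec(["SER"], chi_assignment=[[180.0]]))
        res = st.models[0][0]
        pairs = interaction_pairs(st, [(res.id, "OG"), (res.id, "CB")],
                                  param_table, reg=reg)
        names = {frozenset((a[1], b[1])) for a, b, _, _ in pairs}
        assert frozenset(("CB", "OG")) not in names  # 1-2 bond
        assert frozenset(("N", "OG")) not in names  # 1-3 via CB... CA path
        assert frozenset(("O", "OG")) in names  # 4 bonds apart, in range

    def test_random_cloud_matches_brute_force(self, param_table, reg):
        rng = np.random.default_rng(4)
        residues = [
            Residue("DUM", "X", i + 1,
                    atoms=[Atom("C", "C", rng.uniform(0, 12, size=3), het=True)])
            for i in range(20)
        ]
        st = Structure([residues])
        movable = [(residues[i].id, "C") for i in range(5)]
        got = {frozenset((a, b)) for a, b, _, _ in
               interaction_pairs(st, movable, param_table, reg=reg)}
        expected = {frozenset(p) for p in brute_pairs(st, movable, param_table, reg)}
        assert got == expected


class TestRegionEnergy:
    def test_isolated_residue_zero(self, param_table, reg):
        st = make_toy_structure(FixtureSpec(["SER"], "extended", [[-60.0]]))
        # single extended serine: the only in-range pair is OG..O (attractive or 0)
        e = region_energy(st, [("A", 1)], param_table, reg=reg)
        assert e <= 0.5

    def test_forced_plateau_contact(self, param_table, reg):
        st = make_toy_structure(FixtureSpec(["SER"], "extended", [[-60.0]]))
        res = st.models[0][0]
        dummy = Residue("DUM", "Z", 99, atoms=[
            Atom("C", "C", res["OG"].pos + np.array([0.4, 0.0, 0.0]), het=True)])
        st2 = Structure([st.models[0] + [dummy]])
        base = region_energy(st, [("A", 1)], param_table, reg=reg)
        e = region_energy(st2, [("A", 1)], param_table, reg=reg)
        assert e - base >= PLATEAU - 1e-9

    def test_three_residue_system_matches_brute_force(self, param_table, reg, puzzle):
        movable = puzzle.movable
        pairs = interaction_pairs(puzzle.structure, [
            (res.id, a.name) for res in puzzle.structure.models[0]
            if res.id in set(movable) for a in res.atoms
            if a.name not in ("N", "CA", "C", "O")
        ], param_table, reg=reg)
        brute = sum(evdw(d, pp) for _, _, d, pp in pairs)
        assert region_energy(puzzle.structure, movable, param_table, reg=reg) == \
            pytest.approx(brute, abs=1e-9)


class TestPackingSystem:
    def test_energy_matches_region_energy(self, puzzle, puzzle_system, param_table, reg):
        sc = puzzle_system.current_sidechain_coords()
        assert puzzle_system.energy(sc) == pytest.approx(
            region_energy(puzzle.structure, puzzle.movable, param_table, reg=reg),
            abs=1e-9)

    def test_incremental_equals_full_recompute(self, puzzle, puzzle_system):
        system = puzzle_system
        sc = system.current_sidechain_coords()
        rng = np.random.default_rng(8)
        total = system.energy(sc)
        for _ in range(25):
            r = int(rng.integers(system.n_residues))
            chi = rng.uniform(-180.0, 180.0, size=system.chi_counts[r])
            new = system.rebuild_residue(r, chi[None])[0]
            delta = (system.residue_energy(r, new, sc)
                     - system.residue_energy(r, sc[system.res_slices[r]], sc))
            sc[system.res_slices[r]] = new
            total += delta
            assert total == pytest.approx(system.energy(sc), abs=1e-8)

    def test_rebuild_all_respects_genes(self, puzzle_system, reg):
        genes = np.array([-60.0, 60.0, 180.0])
        coords = puzzle_system.rebuild_all(genes[None])[0]
        st = puzzle_system.apply_to_structure(genes)
        from ptmpack.structure import compute_chi
        for rid, expected in zip(puzzle_system.movable_ri, genes):
            res = st.models[0][rid]
            assert compute_chi(res, reg=reg)[0] == pytest.approx(expected, abs=1e-6)
        assert coords.shape == (puzzle_system.n_mov, 3)
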