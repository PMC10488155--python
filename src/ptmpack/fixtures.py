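"""Synthetic test structures with known ground truth.

Everything here is generated, never downloaded: ideal-geometry backbones with
side chains at prescribed chi angles, multi-model ensembles whose chi angles
follow known circular mixtures (for library-recovery checks), clash fixtures
with an exact number of steric overlaps, and small enumerable packing puzzles
whose global optimum is computed by exhaustive search.  Ground truth is
always returned alongside (or attached to) the structure, never encoded in
the PDB payload itself.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .energy import PackingSystem, ParamTable, load_param_table, evdw, X_CUT
from .geometry import place_atom, wrap_degrees
from .rotamers import LibrarySet, Rotamer, RotamerLibrary
from .structure import Atom, Residue, Structure, rebuild_sidechain
from .topology import TopologyRegistry, registry as default_registry

__all__ = [
    "FixtureSpec",
    "PackingPuzzle",
    "make_toy_structure",
    "make_clash_fixture",
    "make_library_ensemble",
    "make_packing_puzzle",
]

# ideal backbone internal coordinates (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8

_BACKBONE_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-119.0, 113.0),
    "extended": (180.0, 180.0),
}


@dataclass
class FixtureSpec:
    sequence: list  # residue codes
    backbone: str = "helix"  # helix | strand | extended
    chi_assignment: list | None = None  # per-residue chi vectors (degrees), or None
    chain: str = "A"
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in _BACKBONE_DIHEDRALS:
            raise ValueError(f"unknown backbone type {self.backbone!r}")


def _build_backbone(n: int, phi: float, psi: float):
    """N/CA/C/O coordinates for an n-residue chain at fixed (phi, psi)."""
    coords = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    c_dir = place_atom(np.array([0.0, 1.0, 0.0]), N, CA, _B_CA_C, _A_N_CA_C, 150.0)
    C = c_dir
    for i in range(n):
        coords.append([N, CA, C, None])
        if i + 1 < n:
            N_next = place_atom(N, CA, C, _B_C_N, _A_CA_C_N, psi)
            CA_next = place_atom(CA, C, N_next, _B_N_CA, _A_C_N_CA, 180.0)  # omega trans
            C_next = place_atom(C, N_next, CA_next, _B_CA_C, _A_N_CA_C, phi)
            N, CA, C = N_next, CA_next, C_next
    # carbonyl O: dihedral psi+180 about N-CA-C (points opposite the next N)
    for i, (Ni, CAi, Ci, _) in enumerate(coords):
        coords[i][3] = place_atom(Ni, CAi, Ci, _B_C_O, _A_CA_C_O, psi + 180.0)
    return coords


def make_toy_structure(spec: FixtureSpec,
                       reg: TopologyRegistry | None = None) -> Structure:
    """Ideal-geometry chain with side chains at the prescribed chi angles.

    The generated structure carries ``ground_truth_chi`` — a list of the chi
    vectors used, one per residue — as a plain attribute.
    """
    reg = reg or default_registry()
    phi, psi = _BACKBONE_DIHEDRALS[spec.backbone]
    n = len(spec.sequence)
    backbone = _build_backbone(n, phi, psi)
    residues = []
    truth = []
    for i, code in enumerate(spec.sequence):
        code = code.upper()
        topo = reg.get(code)
        if spec.chi_assignment is not None and spec.chi_assignment[i] is not None:
            chi = np.atleast_1d(np.asarray(spec.chi_assignment[i], dtype=float))
        else:
            chi = np.full(topo.chi_count, -60.0)
        if chi.size != topo.chi_count:
            raise ValueError(
                f"residue {i} ({code}): expected {topo.chi_count} chi values, got {chi.size}")
        N, CA, C, O = backbone[i]
        res = Residue(code, spec.chain, i + 1, atoms=[
            Atom("N", "N", N), Atom("CA", "C", CA), Atom("C", "C", C), Atom("O", "O", O),
        ])
        rebuild_sidechain(res, chi, reg=reg)
        residues.append(res)
        truth.append(chi.copy())
    st = Structure([residues], source_id=f"toy-{spec.backbone}-{'-'.join(spec.sequence)}")
    st.ground_truth_chi = truth
    return st


def make_clash_fixture(n_atoms: int, n_overlap_pairs: int, overlap: float = 0.5,
                       seed: int = 0, radius: float = 1.70) -> Structure:
    """Isolated carbon atoms with exactly ``n_overlap_pairs`` overlapping pairs.

    Overlapping pairs are separated by ``2 * radius - overlap``; every other
    pair is farther than the contact distance plus 1 Angstrom.  Atoms belong
    to one-atom DUM residues, so no pair is covalently excluded.
    """
    if n_overlap_pairs * 2 > n_atoms:
        raise ValueError("n_overlap_pairs must not exceed n_atoms / 2")
    if n_overlap_pairs and overlap <= 0:
        raise ValueError("overlap must be positive")
    spacing = 8.0
    side = int(math.ceil(n_atoms ** (1.0 / 3.0)))
    grid = [np.array([i, j, k], dtype=float) * spacing
            for i in range(side) for j in range(side) for k in range(side)]
    if len(grid) < n_atoms:
        raise ValueError("infeasible packing")
    positions = grid[:n_atoms]
    d_pair = 2.0 * radius - overlap
    if d_pair <= 0 or d_pair + 1.0 > spacing - d_pair:
        raise ValueError("infeasible packing for requested overlap")
    for p in range(n_overlap_pairs):
        positions[2 * p + 1] = positions[2 * p] + np.array([d_pair, 0.0, 0.0])
    residues = [
        Residue("DUM", "X", i + 1, atoms=[Atom("C", "C", pos, het=True)])
        for i, pos in enumerate(positions)
    ]
    st = Structure([residues], source_id=f"clash-{n_atoms}-{n_overlap_pairs}")
    st.ground_truth_overlaps = n_overlap_pairs
    return st


def make_library_ensemble(residue_code: str, cluster_spec, n_obs: int, seed: int = 0,
                          reg: TopologyRegistry | None = None):
    """Single-residue structures with chi drawn from a wrapped-normal mixture.

    ``cluster_spec`` is a list of (chi_mean_vector_deg, sigma_vector_deg,
    weight); weights must sum to 1.  Returns (structures, truth) where truth
    records the component assignment of every observation.
    """
    reg = reg or default_registry()
    weights = np.array([w for _, _, w in cluster_spec], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("cluster weights must sum to 1")
    k = reg.get(residue_code).chi_count
    rng = np.random.default_rng(seed)
    # exact component counts (largest-remainder rounding), shuffled: the
    # ensemble composition matches the requested weights exactly, so library
    # frequency recovery is limited only by clustering, not sampling noise
    raw = weights * n_obs
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n_obs - counts.sum()]:
        counts[i] += 1
    assignments = rng.permutation(np.repeat(np.arange(len(cluster_spec)), counts))
    structures = []
    chis = []
    for i, comp in enumerate(assignments):
        mean, sigma, _ = cluster_spec[comp]
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        if mean.size != k or sigma.size != k:
            raise ValueError(f"cluster chi vectors must have length {k}")
        chi = wrap_degrees(mean + rng.normal(0.0, sigma))
        st = make_toy_structure(FixtureSpec([residue_code], backbone="extended",
                                            chi_assignment=[chi]), reg)
        st.source_id = f"ens-{residue_code}-{i}"
        structures.append(st)
        chis.append(chi)
    truth = {"assignments": assignments, "chi": np.array(chis),
             "cluster_spec": cluster_spec}
    return structures, truth


@dataclass
class PackingPuzzle:
    structure: Structure
    site: tuple
    movable: list  # residue ids
    grids: list  # per residue, array (n_rotamers, chi_count) of chi values (deg)
    libraries: LibrarySet
    oracle_energy: float
    oracle_assignment: tuple  # argmin rotamer index per residue

    def enumerate_energies(self, table: ParamTable | None = None,
                           reg: TopologyRegistry | None = None):
        """Exhaustive energies over the rotamer grid (combo tuples, energies)."""
        return _enumerate(self.structure, self.movable, self.grids, table, reg)


def _enumerate(structure, movable, grids, table=None, reg=None):
    system = PackingSystem(structure, movable, table, 0, reg)
    combos = list(itertools.product(*[range(len(g)) for g in grids]))
    G = system.gene_count
    genes = np.empty((len(combos), G))
    slices = system.gene_slices()
    for c, combo in enumerate(combos):
        for r, j in enumerate(combo):
            genes[c, slices[r]] = grids[r][j]
    energies = np.empty(len(combos))
    for start in range(0, len(combos), 2000):
        chunk = slice(start, start + 2000)
        energies[chunk] = system.energy(system.rebuild_all(genes[chunk]))
    return combos, energies


# chi1 grid for the serine puzzle: on an extended backbone each of these
# values is free of intrinsic side-chain/backbone strain, so puzzle energies
# are governed by the placed dummies (and any inter-residue contacts)
_GRID_CHI1 = np.array([-60.0, 180.0, -120.0, -90.0, -150.0])


def make_packing_puzzle(n_movable: int, grid_sizes, seed: int = 0,
                        table: ParamTable | None = None,
                        reg: TopologyRegistry | None = None) -> PackingPuzzle:
    """Enumerable serine-chain puzzle with dummy context atoms forcing clashes.

    Each movable residue gets a chi1 rotamer grid; for every rotamer except
    one (chosen by the seeded RNG) a fixed dummy oxygen is placed on the
    CB->OG axis just inside the interaction cutoff measured from CB, so it
    penalises exactly that rotamer's hydroxyl and nothing else.  The global
    optimum over the grid is computed by exhaustive enumeration.
    """
    reg = reg or default_registry()
    table = table or load_param_table()
    if isinstance(grid_sizes, int):
        grid_sizes = [grid_sizes] * n_movable
    if len(grid_sizes) != n_movable:
        raise ValueError("grid_sizes must have one entry per movable residue")
    if np.prod([float(g) for g in grid_sizes]) > 1e4:
        raise ValueError("puzzle exceeds the enumerable bound (product of grids <= 1e4)")
    if any(g < 1 or g > len(_GRID_CHI1) for g in grid_sizes):
        raise ValueError(f"grid sizes must be in 1..{len(_GRID_CHI1)}")

    rng = np.random.default_rng(seed)
    spec = FixtureSpec(["SER"] * n_movable, backbone="extended",
                       chi_assignment=[[-60.0]] * n_movable)
    st = make_toy_structure(spec, reg)
    residues = st.models[0]
    movable = [r.id for r in residues]
    grids = [np.array([[v] for v in _GRID_CHI1[:g]]) for g in grid_sizes]

    # candidate OG/CB positions per residue and rotamer
    dummies = []
    og_positions = []
    cb_positions = []
    for i, res in enumerate(residues):
        ogs = []
        for chi in grids[i][:, 0]:
            tmp = res.copy()
            rebuild_sidechain(tmp, [chi], reg=reg)
            ogs.append(tmp["OG"].pos.copy())
        og_positions.append(ogs)
        cb_positions.append(res["CB"].pos.copy())

    # contact distances: dummy is an oxygen
    sigma_o_o = 2.0 * table.get("O").radius
    sigma_o_c = table.get("O").radius + table.get("C").radius
    reach = X_CUT * sigma_o_c + 0.01  # stay beyond the cutoff from every CB

    dummy_targets = []
    for i, res in enumerate(residues):
        if len(grids[i]) < 2:
            continue
        good = int(rng.integers(len(grids[i])))
        for j in range(len(grids[i])):
            if j == good:
                continue
            cb = cb_positions[i]
            u = og_positions[i][j] - cb
            u = u / np.linalg.norm(u)
            cand = cb + reach * u
            # a dummy that would graze another residue's CB is simply not
            # placed: that rotamer goes unpenalised and the landscape is
            # whatever the enumeration below says
            if any(np.linalg.norm(cand - c) < X_CUT * sigma_o_c - 1e-9
                   for c in cb_positions):
                continue
            dummies.append(cand)
            dummy_targets.append((i, j))

    # verify: dummies clear every CB (so chi-independent terms vanish) and
    # genuinely penalise the rotamer they target; neighbouring grid points may
    # pick up milder penalties — the exhaustive enumeration below is the truth
    for d, (i, j) in zip(dummies, dummy_targets):
        for cb in cb_positions:
            if np.linalg.norm(d - cb) < X_CUT * sigma_o_c - 1e-9:
                raise ValueError("infeasible packing: dummy touches a CB")
        penalty = evdw(np.linalg.norm(d - og_positions[i][j]), Eij=0.0,
                       sigma_ij=sigma_o_o)
        if penalty <= 0.5:
            raise ValueError("infeasible packing: dummy fails to penalise its rotamer")

    context = [
        Residue("DUM", "Z", 900 + i, atoms=[Atom("O", "O", pos, het=True)])
        for i, pos in enumerate(dummies)
    ]
    st = Structure([residues + context], source_id=f"puzzle-{n_movable}-{seed}")

    combos, energies = _enumerate(st, movable, grids, table, reg)
    best = int(np.argmin(energies))

    libs_by_id = {}
    for i, res in enumerate(residues):
        rot = tuple(
            Rotamer(tuple(g), tuple([8.0] * len(g)), 1.0 / len(grids[i]))
            for g in grids[i]
        )
        libs_by_id[res.id] = RotamerLibrary("SER", grids[i].shape[1], rot)
    libraries = LibrarySet(by_id=libs_by_id)

    return PackingPuzzle(
        structure=st,
        site=movable[n_movable // 2],
        movable=movable,
        grids=grids,
        libraries=libraries,
        oracle_energy=float(energies[best]),
        oracle_assignment=tuple(combos[best]),
    )
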