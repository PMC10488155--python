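"""Flat-top Lennard-Jones clash energy and region energies over movable side chains.

The score is a capped van-der-Waals-like function of the normalised distance
x = d / sigma_ij: a constant plateau of 10 below x = 0.8254, a linear
repulsive ramp of slope 57.273 down to zero at x = 1, a shallow attractive
well of depth E_ij with its minimum at x = 10/9, and zero beyond x = 4/3.
The same function serves as the Metropolis energy and the GA fitness.

``PackingSystem`` precompiles a movable region (atom tables, pair parameters,
1-2/1-3/1-4 bonded exclusions and batched side-chain rebuild plans) so that
packers can score thousands of candidate conformations per second.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import place_atom
from .structure import Structure, Residue, compute_chi, _normalize_id
from .topology import BACKBONE_ATOMS, TopologyRegistry, registry as default_registry

__all__ = [
    "PLATEAU",
    "SLOPE",
    "AtomTypeParam",
    "PairParam",
    "ParamTable",
    "load_param_table",
    "evdw",
    "pair_params",
    "interaction_pairs",
    "region_energy",
    "bonded_exclusions",
    "PackingSystem",
]

PLATEAU = 10.0
SLOPE = 57.273
# the plateau ends exactly where the linear ramp reaches the plateau height;
# 0.8254 is this value rounded to four decimals
X_PLATEAU = 1.0 - PLATEAU / SLOPE
X_WELL = 10.0 / 9.0
X_CUT = 4.0 / 3.0


@dataclass(frozen=True)
class AtomTypeParam:
    type_key: str
    well_depth: float  # kcal/mol
    radius: float  # Angstrom

    def __post_init__(self):
        if self.well_depth < 0 or self.radius <= 0:
            raise ValueError(f"invalid parameters for type {self.type_key!r}")


@dataclass(frozen=True)
class PairParam:
    Eij: float
    sigma_ij: float

    def __post_init__(self):
        if self.Eij < 0 or self.sigma_ij <= 0:
            raise ValueError("invalid pair parameters")


class ParamTable:
    """Atom-type parameter table keyed by element symbol."""

    def __init__(self, params: dict):
        self._params = {k.upper(): v for k, v in params.items()}

    def __contains__(self, key: str) -> bool:
        return key.upper() in self._params

    def get(self, key: str) -> AtomTypeParam:
        try:
            return self._params[key.upper()]
        except KeyError:
            raise KeyError(f"no energy parameters for atom type {key!r}") from None

    def arrays(self, keys):
        depth = np.array([self.get(k).well_depth for k in keys])
        radius = np.array([self.get(k).radius for k in keys])
        return depth, radius


def load_param_table(path=None) -> ParamTable:
    """Load the (element, well depth, radius) table; default is the embedded one."""
    if path is None:
        text = (resources.files("ptmpack") / "data" / "energy_params.txt").read_text()
    else:
        text = Path(path).read_text()
    params = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, depth, radius = line.split()
        params[key] = AtomTypeParam(key.upper(), float(depth), float(radius))
    if not params:
        raise ValueError("empty parameter table")
    return ParamTable(params)


def pair_params(type_i: str, type_j: str, table: ParamTable) -> PairParam:
    """Combine atom-type parameters: geometric-mean depth, summed radii."""
    pi, pj = table.get(type_i), table.get(type_j)
    return PairParam(Eij=float(np.sqrt(pi.well_depth * pj.well_depth)),
                     sigma_ij=pi.radius + pj.radius)


def evdw(d, pair=None, Eij=None, sigma_ij=None):
    """Flat-top Lennard-Jones clash score at distance(s) ``d`` (Angstrom).

    Accepts either a :class:`PairParam` or broadcastable ``Eij``/``sigma_ij``
    arrays.  Vectorised over all arguments.
    """
    if pair is not None:
        Eij, sigma_ij = pair.Eij, pair.sigma_ij
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    Eij = np.asarray(Eij, dtype=float)
    x = d / np.asarray(sigma_ij, dtype=float)
    out = np.zeros(np.broadcast(x, Eij).shape)
    x, Eij = np.broadcast_to(x, out.shape), np.broadcast_to(Eij, out.shape)

    m = x <= X_PLATEAU
    out[m] = PLATEAU
    m = (x > X_PLATEAU) & (x <= 1.0)
    out[m] = SLOPE * (1.0 - x[m])
    m = (x > 1.0) & (x <= X_WELL)
    out[m] = Eij[m] * (10.0 - 9.0 * x[m]) - Eij[m]
    m = (x > X_WELL) & (x <= X_CUT)
    out[m] = Eij[m] / 4.0 * (9.0 * x[m] - 10.0) ** 2 - Eij[m]
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# bonded topology over a whole model


def _model_atom_table(structure: Structure, model_index: int,
                      reg: TopologyRegistry):
    """Flat atom table for one model: residues, names, elements, coordinates."""
    residues = list(structure.models[model_index])
    names, elements, res_idx, coords = [], [], [], []
    for ri, res in enumerate(residues):
        for a in res.atoms:
            names.append(a.name)
            elements.append(a.element or a.name[0])
            res_idx.append(ri)
            coords.append(a.pos)
    return residues, names, elements, np.array(res_idx), np.array(coords, dtype=float)


def _bond_adjacency(residues, names, res_idx, coords, reg: TopologyRegistry):
    """Covalent bond adjacency from residue templates plus peptide C-N links."""
    n = len(names)
    index = {}
    for i, (ri, nm) in enumerate(zip(res_idx, names)):
        index[(int(ri), nm)] = i
    adj = [set() for _ in range(n)]

    def link(i, j):
        adj[i].add(j)
        adj[j].add(i)

    for ri, res in enumerate(residues):
        if res.code not in reg:
            continue
        for a, b in reg.get(res.code).bonds:
            ia, ib = index.get((ri, a)), index.get((ri, b))
            if ia is not None and ib is not None:
                link(ia, ib)
    # peptide bonds by geometry: C(i)-N(j) closer than 1.8 A
    c_atoms = [i for i in range(n) if names[i] == "C"]
    n_atoms = [i for i in range(n) if names[i] == "N"]
    for i in c_atoms:
        for j in n_atoms:
            if res_idx[i] != res_idx[j]:
                if np.linalg.norm(coords[i] - coords[j]) < 1.8:
                    link(i, j)
    return adj


def bonded_exclusions(adj) -> set:
    """Unordered atom-index pairs separated by at most 3 covalent bonds."""
    excluded = set()
    for start in range(len(adj)):
        seen = {start: 0}
        frontier = [start]
        for depth in range(1, 4):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        for v in seen:
            if v != start:
                excluded.add((min(start, v), max(start, v)))
    return excluded


def interaction_pairs(structure: Structure, movable_atoms, table: ParamTable | None = None,
                      model_index: int = 0, reg: TopologyRegistry | None = None):
    """All candidate scoring pairs touching the movable atom set.

    ``movable_atoms`` is a set of (residue id, atom name).  Returns a list of
    ((res_id_i, name_i), (res_id_j, name_j), distance, PairParam) for
    unordered pairs with at least one movable member, excluding pairs within
    three covalent bonds and pairs beyond the 4/3-sigma cutoff.
    """
    reg = reg or default_registry()
    table = table or load_param_table()
    residues, names, elements, res_idx, coords = _model_atom_table(
        structure, model_index, reg)
    adj = _bond_adjacency(residues, names, res_idx, coords, reg)
    excluded = bonded_exclusions(adj)

    keys = [(residues[ri].id, nm) for ri, nm in zip(res_idx, names)]
    movable = {k for k, key in enumerate(keys) if key in set(map(tuple, movable_atoms))}
    out = []
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            if i not in movable and j not in movable:
                continue
            if (i, j) in excluded:
                continue
            pp = pair_params(elements[i], elements[j], table)
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < X_CUT * pp.sigma_ij:
                out.append((keys[i], keys[j], d, pp))
    return out


def region_energy(structure: Structure, movable_residues, table: ParamTable | None = None,
                  model_index: int = 0, reg: TopologyRegistry | None = None) -> float:
    """Total clash score over pairs involving the movable residues' side chains."""
    reg = reg or default_registry()
    movable_atoms = []
    for rid in movable_residues:
        res = structure.find(rid, model_index) if not isinstance(rid, Residue) else rid
        for a in res.atoms:
            if a.name not in BACKBONE_ATOMS:
                movable_atoms.append((res.id, a.name))
    pairs = interaction_pairs(structure, movable_atoms, table, model_index, reg)
    return float(sum(evdw(d, pp) for _, _, d, pp in pairs))


# ---------------------------------------------------------------------------
# compiled movable region


class PackingSystem:
    """Precompiled movable region for fast repeated conformer scoring.

    Movable residues' side chains (CB outward) are rebuilt from chi vectors
    by batched internal-coordinate construction; everything else — other
    residues, waters, ions, ligands and the movable residues' own backbones —
    is fixed context.  Energies are summed over non-bonded pairs involving at
    least one movable side-chain atom, identical to :func:`region_energy`.
    """

    def __init__(self, structure: Structure, movable_ids, table: ParamTable | None = None,
                 model_index: int = 0, reg: TopologyRegistry | None = None):
        self.reg = reg or default_registry()
        self.table = table or load_param_table()
        self.structure = structure
        self.model_index = model_index

        residues, names, elements, res_idx, coords = _model_atom_table(
            structure, model_index, self.reg)
        self.residues = residues
        id2ri = {res.id: ri for ri, res in enumerate(residues)}
        self.movable_ri = [id2ri[_normalize_id(m)] for m in movable_ids]
        movable_set = set(self.movable_ri)

        # side-chain slots per movable residue follow the template build order;
        # a global atom table interleaves fixed atoms and movable slots
        self.templates = [self.reg.get(residues[ri].code).template for ri in self.movable_ri]
        self.chi_counts = [self.reg.get(residues[ri].code).chi_count for ri in self.movable_ri]

        full_names, full_elements, full_res, fixed_mask, fixed_coords = [], [], [], [], []
        mov_slot = []  # (residue slot r, template atom t) per movable atom, in global order
        for ri, res in enumerate(residues):
            if ri in movable_set:
                r = self.movable_ri.index(ri)
                for a in res.atoms:
                    if a.name in BACKBONE_ATOMS:
                        full_names.append(a.name)
                        full_elements.append(a.element or a.name[0])
                        full_res.append(ri)
                        fixed_mask.append(True)
                        fixed_coords.append(a.pos)
                for t in self.templates[r].atoms:
                    full_names.append(t.name)
                    full_elements.append(t.element)
                    full_res.append(ri)
                    fixed_mask.append(False)
                    fixed_coords.append(np.zeros(3))
                    mov_slot.append((r, t))
            else:
                for a in res.atoms:
                    full_names.append(a.name)
                    full_elements.append(a.element or a.name[0])
                    full_res.append(ri)
                    fixed_mask.append(True)
                    fixed_coords.append(a.pos)

        self.names = full_names
        self.fixed_mask = np.array(fixed_mask)
        self.n_atoms = len(full_names)
        self.mov_index = np.where(~self.fixed_mask)[0]
        self.fix_index = np.where(self.fixed_mask)[0]
        self.n_mov = len(self.mov_index)
        self.fixed_coords = np.array(fixed_coords, dtype=float)[self.fix_index]
        self._atom_res = np.array(full_res)

        # per-movable-atom residue slot and per-residue slices into the movable array
        self.mov_res_slot = np.array([r for r, _ in mov_slot])
        self.res_slices = []
        for r in range(len(self.movable_ri)):
            idx = np.where(self.mov_res_slot == r)[0]
            self.res_slices.append(idx)

        # bonded exclusions over the full (movable-slot) atom table
        adj = _bond_adjacency(residues, full_names, np.array(full_res),
                              self._approx_coords(), self.reg)
        excluded = bonded_exclusions(adj)

        depth, radius = self.table.arrays(full_elements)
        Eij = np.sqrt(np.outer(depth, depth))
        Sij = radius[:, None] + radius[None, :]

        # movable x fixed
        self.E_mf = Eij[np.ix_(self.mov_index, self.fix_index)]
        self.S_mf = Sij[np.ix_(self.mov_index, self.fix_index)]
        self.mask_mf = np.ones_like(self.E_mf, dtype=bool)
        # movable x movable (upper triangle only)
        self.E_mm = Eij[np.ix_(self.mov_index, self.mov_index)]
        self.S_mm = Sij[np.ix_(self.mov_index, self.mov_index)]
        self.mask_mm = np.triu(np.ones((self.n_mov, self.n_mov), dtype=bool), k=1)
        for (i, j) in excluded:
            fi, fj = self.fixed_mask[i], self.fixed_mask[j]
            if not fi and fj:
                self.mask_mf[self._mov_pos(i), self._fix_pos(j)] = False
            elif fi and not fj:
                self.mask_mf[self._mov_pos(j), self._fix_pos(i)] = False
            elif not fi and not fj:
                a, b = self._mov_pos(i), self._mov_pos(j)
                self.mask_mm[min(a, b), max(a, b)] = False

        # rebuild plans: per movable residue, backbone anchor coordinates and
        # per-template-atom parent slots (negative = backbone anchor index)
        self._plans = []
        for r, ri in enumerate(self.movable_ri):
            res = residues[ri]
            anchors = {n: res[n].pos for n in ("N", "CA", "C")}
            plan = []
            name_to_slot = {}
            for s, t in enumerate(self.templates[r].atoms):
                parents = []
                for pn in t.parents:
                    if pn in name_to_slot:
                        parents.append(name_to_slot[pn])
                    else:
                        parents.append(("bb", pn))
                name_to_slot[t.name] = s
                plan.append((t, parents))
            self._plans.append((anchors, plan))

        self._mov_pos_cache = {int(g): p for p, g in enumerate(self.mov_index)}

    # -- index helpers ------------------------------------------------------

    def _mov_pos(self, global_idx):
        return int(np.searchsorted(self.mov_index, global_idx))

    def _fix_pos(self, global_idx):
        return int(np.searchsorted(self.fix_index, global_idx))

    def _approx_coords(self):
        """Coordinates for bond detection: fixed atoms real, movable atoms rebuilt
        at chi = 0 (bond connectivity does not depend on chi)."""
        coords = np.zeros((self.n_atoms, 3))
        coords[self.fix_index] = self.fixed_coords
        # plans are not built yet at call time; rebuild directly from templates
        pos_by_slot = {}
        mslot = 0
        for r, ri in enumerate(self.movable_ri):
            res = self.residues[ri]
            pos = {n: res[n].pos for n in ("N", "CA", "C")}
            for t in self.templates[r].atoms:
                p = place_atom(pos[t.parents[0]], pos[t.parents[1]], pos[t.parents[2]],
                               t.bond_length, t.angle, t.dihedral_value)
                pos[t.name] = p
                pos_by_slot[mslot] = p
                mslot += 1
        for s, g in enumerate(self.mov_index):
            coords[g] = pos_by_slot[s]
        return coords

    # -- conformer construction --------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.movable_ri)

    @property
    def gene_count(self) -> int:
        return int(sum(self.chi_counts))

    def gene_slices(self):
        """Per-residue slices into a concatenated chi ('gene') vector."""
        out, start = [], 0
        for k in self.chi_counts:
            out.append(slice(start, start + k))
            start += k
        return out

    def rebuild_residue(self, r: int, chi_deg) -> np.ndarray:
        """Coordinates (B, n_atoms_r, 3) of residue r's side chain at chi (B, k) degrees."""
        chi = np.atleast_2d(np.asarray(chi_deg, dtype=float))
        anchors, plan = self._plans[r]
        B = chi.shape[0]
        out = np.empty((B, len(plan), 3))
        placed = {}
        for s, (t, parents) in enumerate(plan):
            ppos = []
            for p in parents:
                if isinstance(p, tuple):
                    ppos.append(np.broadcast_to(anchors[p[1]], (B, 3)))
                else:
                    ppos.append(placed[p])
            if t.dihedral_kind == "chi":
                dih = chi[:, t.chi_index - 1] + t.dihedral_value
            else:
                dih = np.full(B, t.dihedral_value)
            pos = place_atom(ppos[0], ppos[1], ppos[2], t.bond_length, t.angle, dih)
            placed[s] = pos
            out[:, s, :] = pos
        return out

    def rebuild_all(self, genes_deg) -> np.ndarray:
        """Movable side-chain coordinates (B, n_mov, 3) from gene matrix (B, G) degrees."""
        genes = np.atleast_2d(np.asarray(genes_deg, dtype=float))
        B = genes.shape[0]
        coords = np.empty((B, self.n_mov, 3))
        for r, sl in enumerate(self.gene_slices()):
            coords[:, self.res_slices[r], :] = self.rebuild_residue(r, genes[:, sl])
        return coords

    def initial_chi(self) -> np.ndarray:
        """Concatenated current chi (degrees) of the movable residues; NaN if absent."""
        out = []
        for ri in self.movable_ri:
            out.append(compute_chi(self.residues[ri], reg=self.reg))
        return np.concatenate(out) if out else np.zeros(0)

    def current_sidechain_coords(self) -> np.ndarray | None:
        """Actual side-chain coordinates from the structure, in slot order.

        Returns None when any movable template atom is missing (e.g. after
        stripping); callers then rebuild from chi instead.
        """
        coords = np.empty((self.n_mov, 3))
        s = 0
        for r, ri in enumerate(self.movable_ri):
            res = self.residues[ri]
            for t in self.templates[r].atoms:
                a = res.get(t.name)
                if a is None:
                    return None
                coords[s] = a.pos
                s += 1
        return coords

    # -- energies ------------------------------------------------------------

    def energy(self, sidechain_coords) -> np.ndarray:
        """Total region score for side-chain coordinates (B, n_mov, 3) or (n_mov, 3)."""
        sc = np.asarray(sidechain_coords, dtype=float)
        squeeze = sc.ndim == 2
        if squeeze:
            sc = sc[None]
        d_mf = np.linalg.norm(sc[:, :, None, :] - self.fixed_coords[None, None, :, :],
                              axis=-1)
        e = evdw(d_mf, Eij=self.E_mf[None], sigma_ij=self.S_mf[None])
        e = np.where(self.mask_mf[None], e, 0.0).sum(axis=(1, 2))
        if self.n_mov > 1:
            d_mm = np.linalg.norm(sc[:, :, None, :] - sc[:, None, :, :], axis=-1)
            d_mm = np.where(self.mask_mm[None], d_mm, 1e6)
            e2 = evdw(d_mm, Eij=self.E_mm[None], sigma_ij=self.S_mm[None])
            e = e + np.where(self.mask_mm[None], e2, 0.0).sum(axis=(1, 2))
        return float(e[0]) if squeeze else e

    def residue_context_energy(self, r: int, res_coords) -> np.ndarray:
        """Score of residue r's side chain against the fixed context plus its
        own non-bonded intra-residue pairs; batched over (B, n_atoms_r, 3)."""
        rc = np.asarray(res_coords, dtype=float)
        squeeze = rc.ndim == 2
        if squeeze:
            rc = rc[None]
        idx = self.res_slices[r]
        d_mf = np.linalg.norm(rc[:, :, None, :] - self.fixed_coords[None, None, :, :],
                              axis=-1)
        e = np.where(self.mask_mf[idx][None],
                     evdw(d_mf, Eij=self.E_mf[idx][None], sigma_ij=self.S_mf[idx][None]),
                     0.0).sum(axis=(1, 2))
        d_in = np.linalg.norm(rc[:, :, None, :] - rc[:, None, :, :], axis=-1)
        mask_in = self.mask_mm[np.ix_(idx, idx)]
        d_in = np.where(mask_in[None], d_in, 1e6)
        e = e + np.where(mask_in[None],
                         evdw(d_in, Eij=self.E_mm[np.ix_(idx, idx)][None],
                              sigma_ij=self.S_mm[np.ix_(idx, idx)][None]),
                         0.0).sum(axis=(1, 2))
        return e[0] if squeeze else e

    def cross_energy(self, r: int, q: int, coords_r, coords_q) -> np.ndarray:
        """Pairwise score between candidate coordinate sets of residues r and q.

        ``coords_r`` is (A, n_r, 3) and ``coords_q`` is (B, n_q, 3); the result
        is an (A, B) table."""
        ir, iq = self.res_slices[r], self.res_slices[q]
        cr = np.asarray(coords_r, dtype=float)
        cq = np.asarray(coords_q, dtype=float)
        mask = self.mask_mm[np.ix_(ir, iq)] | self.mask_mm[np.ix_(iq, ir)].T
        d = np.linalg.norm(cr[:, None, :, None, :] - cq[None, :, None, :, :], axis=-1)
        e = np.where(mask[None, None],
                     evdw(d, Eij=self.E_mm[np.ix_(ir, iq)][None, None],
                          sigma_ij=self.S_mm[np.ix_(ir, iq)][None, None]),
                     0.0)
        return e.sum(axis=(2, 3))

    def residue_energy(self, r: int, res_coords, sidechain_coords) -> float:
        """Score of all pairs touching residue r's side chain, holding the rest
        of the movable region at ``sidechain_coords``."""
        idx = self.res_slices[r]
        rc = np.asarray(res_coords, dtype=float)
        d_mf = np.linalg.norm(rc[:, None, :] - self.fixed_coords[None, :, :], axis=-1)
        e = float(np.where(self.mask_mf[idx], evdw(d_mf, Eij=self.E_mf[idx],
                                                   sigma_ij=self.S_mf[idx]), 0.0).sum())
        other = np.setdiff1d(np.arange(self.n_mov), idx)
        if other.size:
            oc = sidechain_coords[other]
            d = np.linalg.norm(rc[:, None, :] - oc[None, :, :], axis=-1)
            mask = self.mask_mm[np.ix_(idx, other)] | self.mask_mm[np.ix_(other, idx)].T
            e += float(np.where(mask, evdw(d, Eij=self.E_mm[np.ix_(idx, other)],
                                           sigma_ij=self.S_mm[np.ix_(idx, other)]),
                                0.0).sum())
        # intra-residue non-bonded pairs
        d_in = np.linalg.norm(rc[:, None, :] - rc[None, :, :], axis=-1)
        d_in = np.where(np.eye(len(idx), dtype=bool), 1e6, d_in)
        mask_in = self.mask_mm[np.ix_(idx, idx)]
        e += float(np.where(mask_in, evdw(d_in, Eij=self.E_mm[np.ix_(idx, idx)],
                                          sigma_ij=self.S_mm[np.ix_(idx, idx)]), 0.0).sum())
        return e

    def apply_to_structure(self, genes_deg, structure: Structure | None = None) -> Structure:
        """Write side chains rebuilt at ``genes_deg`` into a copy of the structure."""
        from .structure import rebuild_sidechain  # local import to avoid cycle

        target = (structure or self.structure).copy()
        for r, ri in enumerate(self.movable_ri):
            rid = self.residues[ri].id
            res = target.find(rid, self.model_index)
            sl = self.gene_slices()[r]
            chi = np.asarray(genes_deg, dtype=float)[sl]
            if chi.size:
                rebuild_sidechain(res, chi, reg=self.reg)
            else:
                rebuild_sidechain(res, np.zeros(0), reg=self.reg)
        return target
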