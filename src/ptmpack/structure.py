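"""Hierarchical structure model and PDB I/O.

A :class:`Structure` holds one or more models, each a flat ordered list of
:class:`Residue` objects; a residue holds :class:`Atom` records.  Coordinates
are Cartesian Angstrom; dihedrals at this layer are degrees in (-180, 180].

Parsing and serialisation of the fixed-column PDB format are delegated to
gemmi; this module applies the altloc policy (highest occupancy wins, ties
resolved toward 'A'), validates coordinate fields with line numbers, and maps
the gemmi hierarchy onto the package's own containers.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import dihedral, place_atom
from .topology import BACKBONE_ATOMS, TopologyRegistry, registry as default_registry

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "compute_chi",
    "strip_sidechains",
    "rebuild_sidechain",
    "neighbors_within",
]

# residues never treated as repackable polymer material
_SOLVENT = {"HOH", "WAT", "DOD"}
_IONS = {"NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "CU", "CO", "NI", "BR", "IOD", "CD", "SO4", "PO4"}


class PDBParseError(ValueError):
    """Raised for malformed PDB input; carries the offending line number."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""
    het: bool = False

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy(),
                    self.occupancy, self.bfactor, self.altloc, self.het)


@dataclass
class Residue:
    code: str
    chain: str
    seqnum: int
    icode: str = ""
    atoms: list = field(default_factory=list)
    model_index: int = 0

    @property
    def id(self):
        """(chain, seqnum, icode) — unique within a model."""
        return (self.chain, self.seqnum, self.icode)

    def get(self, name: str):
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __getitem__(self, name: str) -> Atom:
        a = self.get(name)
        if a is None:
            raise KeyError(f"residue {self.code} {self.id}: no atom {name!r}")
        return a

    def has(self, *names) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    @property
    def has_backbone(self) -> bool:
        return self.has("N", "CA", "C")

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)

    def copy(self) -> "Residue":
        return Residue(self.code, self.chain, self.seqnum, self.icode,
                       [a.copy() for a in self.atoms], self.model_index)

    def is_polymer(self, reg: TopologyRegistry | None = None) -> bool:
        if self.code in _SOLVENT or self.code in _IONS:
            return False
        reg = reg or default_registry()
        return self.code in reg and self.has_backbone


@dataclass
class Structure:
    models: list  # list of list[Residue]
    source_id: str = ""

    def __post_init__(self):
        if not self.models:
            raise ValueError("structure must contain at least one model")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residues(self, model_index: int | None = None):
        """Iterate residues; over all models when model_index is None."""
        if model_index is not None:
            yield from self.models[model_index]
        else:
            for model in self.models:
                yield from model

    def find(self, res_id, model_index: int = 0) -> Residue:
        chain, seqnum, icode = _normalize_id(res_id)
        for r in self.models[model_index]:
            if r.chain == chain and r.seqnum == seqnum and r.icode == icode:
                return r
        raise KeyError(f"residue {res_id!r} not found in model {model_index}")

    def copy(self) -> "Structure":
        return Structure([[r.copy() for r in m] for m in self.models], self.source_id)


def _normalize_id(res_id):
    if isinstance(res_id, Residue):
        return res_id.id
    if len(res_id) == 2:
        return (res_id[0], int(res_id[1]), "")
    chain, seqnum, icode = res_id
    return (chain, int(seqnum), icode or "")


# ---------------------------------------------------------------------------
# PDB reading / writing


def _validate_coordinate_lines(text: str) -> None:
    for ln, line in enumerate(text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldstr = line[lo:hi].strip()
                try:
                    float(fieldstr)
                except ValueError:
                    raise PDBParseError(
                        f"line {ln}: malformed {what}-coordinate field {fieldstr!r}"
                    ) from None


def _apply_altloc_policy(res: gemmi.Residue):
    """Yield one gemmi atom per atom name: highest occupancy, ties toward 'A'."""
    by_name: dict = {}
    for at in res:
        key = at.name
        prev = by_name.get(key)
        if prev is None:
            by_name[key] = at
            continue
        # blank altloc sorts before 'A'; prefer higher occupancy, then
        # lexicographically smaller altloc label
        if (at.occ, -ord(at.altloc or " ")) > (prev.occ, -ord(prev.altloc or " ")):
            by_name[key] = at
    return list(by_name.values())


def read_pdb(text_or_path, source_id: str = "") -> Structure:
    """Parse PDB-format text (or a path to it) into a :class:`Structure`.

    MODEL blocks become distinct models; altlocs are collapsed per the
    highest-occupancy policy; residue codes are kept verbatim, registered or
    not.  Raises :class:`PDBParseError` with a line number for malformed
    coordinate fields and for empty input.
    """
    if isinstance(text_or_path, (str, os.PathLike)) and os.path.exists(str(text_or_path)):
        path = str(text_or_path)
        with open(path) as fh:
            text = fh.read()
        source_id = source_id or os.path.basename(path)
    else:
        text = str(text_or_path)
    if not text.strip():
        raise PDBParseError("empty PDB input")
    _validate_coordinate_lines(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBParseError("no models found in PDB input")

    models = []
    for mi, model in enumerate(st):
        residues = []
        for chain in model:
            for gres in chain:
                atoms = []
                for gat in _apply_altloc_policy(gres):
                    atoms.append(Atom(
                        name=gat.name,
                        element=gat.element.name,
                        pos=np.array([gat.pos.x, gat.pos.y, gat.pos.z]),
                        occupancy=gat.occ,
                        bfactor=gat.b_iso,
                        altloc=gat.altloc or "",
                        het=gres.het_flag == "H",
                    ))
                residues.append(Residue(
                    code=gres.name,
                    chain=chain.name,
                    seqnum=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    atoms=atoms,
                    model_index=mi,
                ))
        models.append(residues)
    return Structure(models, source_id=source_id)


def write_pdb(structure: Structure) -> str:
    """Serialise a :class:`Structure` to PDB-format text (fixed columns)."""
    st = gemmi.Structure()
    st.name = structure.source_id or "ptmpack"
    for mi, model in enumerate(structure.models):
        gmodel = gemmi.Model(mi + 1)
        chains: dict = {}
        for res in model:
            if res.chain not in chains:
                chains[res.chain] = gemmi.Chain(res.chain)
            gres = gemmi.Residue()
            gres.name = res.code
            gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
            gres.het_flag = "H" if any(a.het for a in res.atoms) else "A"
            for a in res.atoms:
                if len(a.name) > 4:
                    raise ValueError(f"atom name {a.name!r} exceeds 4 characters")
                gat = gemmi.Atom()
                gat.name = a.name
                gat.element = gemmi.Element(a.element or a.name[0])
                gat.pos = gemmi.Position(*a.pos)
                gat.occ = a.occupancy
                gat.b_iso = a.bfactor
                gat.altloc = "\0"
                gres.add_atom(gat)
            chains[res.chain].add_residue(gres)
        for ch in chains.values():
            gmodel.add_chain(ch)
        st.add_model(gmodel)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True, numbered_ter=False))


# ---------------------------------------------------------------------------
# chi angles, stripping, rebuilding, neighborhoods


def compute_chi(residue: Residue, chi_definition=None, reg: TopologyRegistry | None = None) -> np.ndarray:
    """Chi angles of a residue in degrees, NaN where a defining atom is missing."""
    if chi_definition is None:
        reg = reg or default_registry()
        chi_definition = reg.get(residue.code).chi
    out = np.full(chi_definition.chi_count, np.nan)
    for k, quad in enumerate(chi_definition.chi_atoms):
        atoms = [residue.get(n) for n in quad]
        if any(a is None for a in atoms):
            continue
        out[k] = dihedral(*(a.pos for a in atoms))
    return out


def strip_sidechains(structure: Structure, selection=None,
                     reg: TopologyRegistry | None = None) -> Structure:
    """Remove all side-chain atoms (CB included) from selected polymer residues.

    ``selection`` is None (all polymer residues) or an iterable of residue
    ids.  Returns a new structure; the removed atoms are recorded on it as
    ``stripped_atoms`` — a list of (model_index, residue id, atom name).
    """
    reg = reg or default_registry()
    wanted = None
    if selection is not None:
        wanted = {_normalize_id(s) for s in selection}
    out = structure.copy()
    audit = []
    for mi, model in enumerate(out.models):
        for res in model:
            if not res.is_polymer(reg):
                continue
            if wanted is not None and res.id not in wanted:
                continue
            kept, removed = [], []
            for a in res.atoms:
                (kept if a.name in BACKBONE_ATOMS else removed).append(a)
            res.atoms = kept
            audit.extend((mi, res.id, a.name) for a in removed)
    out.stripped_atoms = audit
    return out


def rebuild_sidechain(residue: Residue, chi_vector, template=None,
                      reg: TopologyRegistry | None = None) -> Residue:
    """Place side-chain atoms from chi angles (degrees) by internal coordinates.

    The residue is modified in place and returned.  Backbone N, CA, C must be
    present.  Atoms already present with a template name are replaced; the
    rebuilt positions satisfy ``compute_chi(residue) == chi_vector``.
    """
    reg = reg or default_registry()
    topo = reg.get(residue.code)
    template = template or topo.template
    chi_vector = np.atleast_1d(np.asarray(chi_vector, dtype=float))
    if chi_vector.size != topo.chi_count:
        raise ValueError(
            f"{residue.code}: expected {topo.chi_count} chi angles, got {chi_vector.size}"
        )
    if not residue.has_backbone:
        raise ValueError(f"residue {residue.id}: backbone N/CA/C required for rebuild")

    pos = {a.name: a.pos for a in residue.atoms if a.name in BACKBONE_ATOMS}
    new_atoms = []
    for t in template.atoms:
        if t.dihedral_kind == "chi":
            dih = chi_vector[t.chi_index - 1] + t.dihedral_value
        else:
            dih = t.dihedral_value
        p = place_atom(pos[t.parents[0]], pos[t.parents[1]], pos[t.parents[2]],
                       t.bond_length, t.angle, dih)
        pos[t.name] = p
        new_atoms.append(Atom(t.name, t.element, p, het=any(a.het for a in residue.atoms)))

    backbone = [a for a in residue.atoms if a.name in BACKBONE_ATOMS]
    residue.atoms = backbone + new_atoms
    return residue


def neighbors_within(structure: Structure, site, radius: float,
                     model_index: int = 0, reg: TopologyRegistry | None = None) -> list:
    """Polymer residues with any atom within ``radius`` of any site atom.

    The site residue itself is always included.  Waters, ions and residues
    without a registered topology are never returned (they remain fixed
    context for energies).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    reg = reg or default_registry()
    site_res = structure.find(site, model_index)
    site_xyz = site_res.coords()
    out = []
    for res in structure.models[model_index]:
        if not res.is_polymer(reg):
            continue
        if res is site_res:
            out.append(res)
            continue
        xyz = res.coords()
        if xyz.size == 0:
            continue
        d2 = np.sum((xyz[:, None, :] - site_xyz[None, :, :]) ** 2, axis=-1)
        if np.min(d2) <= radius * radius:
            out.append(res)
    return out
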