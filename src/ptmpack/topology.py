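"""Residue topology registry: chi definitions, side-chain build templates, bonds.

Covers the 20 canonical amino acids plus five common modified residues:
SEP (phosphoserine), TPO (phosphothreonine), PTR (O-phosphotyrosine),
MLY (N-dimethyl-lysine) and CSO (S-hydroxycysteine).  The numeric template
data (ideal bond lengths, angles and reference dihedrals) lives in
``data/residue_topology.txt`` and can be regenerated or extended; chi
definitions can additionally be overridden at run time from a flat text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "ChiDefinition",
    "TemplateAtom",
    "SidechainTemplate",
    "ResidueTopology",
    "TopologyRegistry",
    "default_registry",
    "PTM_CODES",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
PTM_CODES = ("SEP", "TPO", "PTR", "MLY", "CSO")


@dataclass(frozen=True)
class ChiDefinition:
    """Ordered list of 4-atom-name tuples defining a residue's chi angles."""

    residue_code: str
    chi_atoms: tuple  # tuple of 4-tuples of atom names

    @property
    def chi_count(self) -> int:
        return len(self.chi_atoms)

    def __post_init__(self):
        for quad in self.chi_atoms:
            if len(quad) != 4 or len(set(quad)) != 4:
                raise ValueError(
                    f"{self.residue_code}: chi tuple must hold 4 distinct atom names, got {quad}"
                )


@dataclass(frozen=True)
class TemplateAtom:
    """One side-chain atom's internal-coordinate build record.

    The atom is placed at distance ``bond_length`` from ``parents[2]``, with
    bond angle ``angle`` at parents[2] and a dihedral about the
    parents[1]-parents[2] axis that is either a chi angle (plus a fixed
    offset, e.g. for branch atoms) or a fixed value.
    """

    name: str
    element: str
    parents: tuple  # (great-grandparent, grandparent, parent) atom names
    bond_length: float  # Angstrom
    angle: float  # degrees
    dihedral_kind: str  # "chi" | "fixed"
    chi_index: int = 0  # 1-based, for kind == "chi"
    dihedral_value: float = 0.0  # offset (chi) or absolute dihedral (fixed), degrees


@dataclass(frozen=True)
class SidechainTemplate:
    residue_code: str
    atoms: tuple  # TemplateAtom, in topological build order

    def __post_init__(self):
        placed = set(BACKBONE_ATOMS)
        for a in self.atoms:
            if not all(p in placed for p in a.parents):
                raise ValueError(
                    f"{self.residue_code}: parents of {a.name} not placed before it"
                )
            if not (0.8 < a.bond_length < 2.2):
                raise ValueError(
                    f"{self.residue_code}: implausible bond length {a.bond_length} for {a.name}"
                )
            placed.add(a.name)


@dataclass(frozen=True)
class ResidueTopology:
    code: str
    chi: ChiDefinition
    template: SidechainTemplate
    bonds: tuple  # tuple of (name, name) pairs, heavy atoms, within residue

    @property
    def chi_count(self) -> int:
        return self.chi.chi_count

    @property
    def sidechain_atom_names(self) -> tuple:
        return tuple(a.name for a in self.template.atoms)


class TopologyRegistry:
    """Lookup of :class:`ResidueTopology` by 3-letter residue code."""

    def __init__(self, topologies: dict):
        self._topologies = dict(topologies)

    def __contains__(self, code: str) -> bool:
        return code.upper() in self._topologies

    def get(self, code: str) -> ResidueTopology:
        try:
            return self._topologies[code.upper()]
        except KeyError:
            raise KeyError(f"residue code {code!r} is not registered") from None

    def codes(self):
        return sorted(self._topologies)

    def chi_count(self, code: str) -> int:
        return self.get(code).chi_count

    def with_chi_overrides(self, path) -> "TopologyRegistry":
        """Return a copy with chi definitions replaced from a flat text file.

        Each line: ``CODE chi_index atom1 atom2 atom3 atom4``.  All chi
        indices for an overridden code must be supplied together; template
        build records are kept as-is.
        """
        overrides: dict = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 'CODE k A B C D', got {raw!r}")
            code, k = parts[0].upper(), int(parts[1])
            overrides.setdefault(code, {})[k] = tuple(parts[2:])
        topo = dict(self._topologies)
        for code, quads in overrides.items():
            if code not in topo:
                raise KeyError(f"cannot override unknown residue code {code!r}")
            ordered = tuple(quads[k] for k in sorted(quads))
            if sorted(quads) != list(range(1, len(quads) + 1)):
                raise ValueError(f"chi indices for {code} must be 1..n without gaps")
            old = topo[code]
            topo[code] = ResidueTopology(
                code=code,
                chi=ChiDefinition(code, ordered),
                template=old.template,
                bonds=old.bonds,
            )
        return TopologyRegistry(topo)


def _parse_topology_text(text: str) -> dict:
    topologies = {}
    code = None
    chis: dict = {}
    atoms: list = []
    bonds: list = []

    def flush():
        if code is None:
            return
        quads = tuple(chis[k] for k in sorted(chis))
        topologies[code] = ResidueTopology(
            code=code,
            chi=ChiDefinition(code, quads),
            template=SidechainTemplate(code, tuple(atoms)),
            bonds=tuple(bonds),
        )

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line or line.startswith("FORMAT"):
            continue
        parts = line.split()
        tag = parts[0]
        if tag == "RESIDUE":
            flush()
            code, chis, atoms, bonds = parts[1], {}, [], []
        elif tag == "CHI":
            chis[int(parts[1])] = tuple(parts[2:6])
        elif tag == "ATOM":
            name, el, ggp, gp, p, blen, ang = parts[1:8]
            kind = parts[8]
            if kind == "chi":
                atoms.append(TemplateAtom(name, el, (ggp, gp, p), float(blen),
                                          float(ang), "chi", int(parts[9]),
                                          float(parts[10])))
            else:
                atoms.append(TemplateAtom(name, el, (ggp, gp, p), float(blen),
                                          float(ang), "fixed", 0, float(parts[9])))
        elif tag == "BOND":
            bonds.append((parts[1], parts[2]))
        else:
            raise ValueError(f"unknown record {tag!r} in topology data")
    flush()
    return topologies


def default_registry() -> TopologyRegistry:
    """The built-in registry (20 canonical residues + SEP/TPO/PTR/MLY/CSO)."""
    text = (resources.files("ptmpack") / "data" / "residue_topology.txt").read_text()
    return TopologyRegistry(_parse_topology_text(text))


_DEFAULT = None


def registry() -> TopologyRegistry:
    """Cached module-level default registry."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = default_registry()
    return _DEFAULT
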