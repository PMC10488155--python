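"""Regenerate the embedded residue-topology data file.

Derives side-chain build templates (internal coordinates) and bond graphs for
the 20 canonical residues plus the supported modified residues (SEP, TPO, PTR,
MLY, CSO) from the ideal-geometry chemical component dictionary bundled with
biotite, and writes them to ``src/ptmpack/data/residue_topology.txt``.

Run from the repository root:  python scripts/make_template_data.py
"""

from __future__ import annotations

import sys
from collections import deque
from pathlib import Path

import numpy as np
import biotite.structure.info as info

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from ptmpack.geometry import dihedral, bond_angle, wrap_degrees  # noqa: E402

# Standard chi definitions (IUPAC atom naming); modified residues extend their
# parent residue with the dihedral that carries the modifying group.
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
    # Phosphoserine / phosphothreonine: extra dihedral carries the phosphate.
    "SEP": [("N", "CA", "CB", "OG"), ("CA", "CB", "OG", "P")],
    "TPO": [("N", "CA", "CB", "OG1"), ("CA", "CB", "OG1", "P")],
    # O-phosphotyrosine: tyrosine chis plus the ring-exit phosphate dihedral.
    "PTR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1"),
            ("CE1", "CZ", "OH", "P")],
    # N-dimethyl-lysine: lysine chis plus rotation of the dimethylamino group.
    "MLY": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ"),
            ("CD", "CE", "NZ", "CH1")],
    # S-hydroxycysteine: cysteine chi plus the S-O dihedral.
    "CSO": [("N", "CA", "CB", "SG"), ("CA", "CB", "SG", "OD")],
}

BACKBONE = ("N", "CA", "C", "O")


def derive(code):
    res = info.residue(code)
    names = list(res.atom_name)
    heavy = [
        n
        for n, e in zip(res.atom_name, res.element)
        if e != "H" and n != "OXT"
    ]
    pos = {n: res.coord[names.index(n)] for n in heavy}
    elem = {n: str(res.element[names.index(n)]) for n in heavy}

    adj = {n: set() for n in heavy}
    bonds = []
    arr = res.bonds.as_array()
    for i, j, _ in arr:
        a, b = names[i], names[j]
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
            bonds.append(tuple(sorted((a, b))))
    bonds = sorted(set(bonds))

    chis = CHI_ATOMS[code]

    # BFS tree over the side chain rooted at CA; names sorted so that the
    # lower-numbered ring branch (CD1/CE1) defines the build path.
    pred = {"CA": None}
    order = []
    queue = deque(["CA"])
    seen = {"CA", "N", "C", "O"}
    while queue:
        u = queue.popleft()
        for v in sorted(adj[u]):
            if v not in seen:
                seen.add(v)
                pred[v] = u
                order.append(v)
                queue.append(v)

    records = []
    for atom in order:
        p = pred[atom]
        if atom == "CB":
            ggp, gp = "C", "N"
        else:
            gp = pred[p]
            ggp = "C" if gp == "CA" and pred[gp] is None else pred[gp]
            if gp == "CA":
                ggp = "N"
            if p == "CB":
                ggp, gp = "N", "CA"
        triplet = (ggp, gp, p)
        d = float(dihedral(pos[ggp], pos[gp], pos[p], pos[atom]))
        blen = float(np.linalg.norm(pos[atom] - pos[p]))
        ang = float(bond_angle(pos[gp], pos[p], pos[atom]))
        source = None
        for k, chi in enumerate(chis, start=1):
            if chi == triplet + (atom,):
                source = ("chi", k, 0.0)
                break
            if chi[:3] == triplet:
                off = float(wrap_degrees(d - dihedral(
                    pos[chi[0]], pos[chi[1]], pos[chi[2]], pos[chi[3]])))
                source = ("chi", k, off)
                break
        if source is None:
            source = ("fixed", d)
        records.append((atom, elem[atom], triplet, blen, ang, source))
    return records, bonds, chis


def main():
    out = Path(__file__).resolve().parents[1] / "src" / "ptmpack" / "data" / "residue_topology.txt"
    out.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# residue topology: chi definitions, side-chain build templates, bond graphs",
             "# generated by scripts/make_template_data.py from ideal residue geometry",
             "FORMAT 1"]
    for code in sorted(CHI_ATOMS):
        records, bonds, chis = derive(code)
        lines.append(f"RESIDUE {code}")
        for k, chi in enumerate(chis, start=1):
            lines.append("CHI %d %s" % (k, " ".join(chi)))
        for atom, el, (ggp, gp, p), blen, ang, src in records:
            if src[0] == "chi":
                s = "chi %d %.3f" % (src[1], src[2])
            else:
                s = "fixed %.3f" % src[1]
            lines.append(
                "ATOM %-4s %-2s %-4s %-4s %-4s %7.4f %8.3f %s"
                % (atom, el, ggp, gp, p, blen, ang, s)
            )
        for a, b in bonds:
            lines.append(f"BOND {a} {b}")
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out} ({len(lines)} lines)")


if __name__ == "__main__":
    main()
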