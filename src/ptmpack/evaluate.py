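"""Structure-quality assessment for repacked models.

Implements the strip / restore / repack protocol and the comparison metrics:
superposition-free side-chain RMSD (the backbone never moves, so native and
model share a frame), circular chi mean absolute error per chi index, a
heavy-atom clashscore (serious steric overlaps > 0.4 A per 1000 atoms) and
marginal-residue classification (close contacts and rotamer outliers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .energy import (PackingSystem, ParamTable, _bond_adjacency,
                     _model_atom_table, bonded_exclusions)
from .geometry import wrap_degrees
from .mcmc import MCMCConfig, PackingTask, repack_mcmc
from .ga import GAConfig, evolve
from .rotamers import LibrarySet, nearest_rotamer
from .structure import Residue, Structure, compute_chi, strip_sidechains, rebuild_sidechain
from .topology import BACKBONE_ATOMS, TopologyRegistry, registry as default_registry

__all__ = [
    "EvalReport",
    "MarginalResidue",
    "CLASH_THRESHOLD",
    "load_vdw_radii",
    "sidechain_rmsd",
    "chi_mae",
    "clashscore",
    "rotamer_outlier_pct",
    "classify_marginal",
    "strip_rebuild_protocol",
]

CLASH_THRESHOLD = 0.4  # Angstrom; overlaps strictly greater than this count

# atom-name swaps that relabel chemically equivalent side-chain atoms
_SYMMETRY_SWAPS = {
    "PHE": [(("CD1", "CD2"), ("CE1", "CE2"))],
    "TYR": [(("CD1", "CD2"), ("CE1", "CE2"))],
    "PTR": [(("CD1", "CD2"), ("CE1", "CE2"))],
    "ASP": [(("OD1", "OD2"),)],
    "GLU": [(("OE1", "OE2"),)],
    "ARG": [(("NH1", "NH2"),)],
}


def load_vdw_radii(path=None) -> dict:
    if path is None:
        text = (resources.files("ptmpack") / "data" / "vdw_radii.txt").read_text()
    else:
        text = Path(path).read_text()
    radii = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            el, r = line.split()
            radii[el.upper()] = float(r)
    return radii


@dataclass(frozen=True)
class MarginalResidue:
    residue_id: tuple
    code: str
    reasons: tuple  # subset of ("close_contacts", "rotamer_outlier")

    def __post_init__(self):
        if not self.reasons:
            raise ValueError("a marginal residue needs at least one reason")


@dataclass
class EvalReport:
    per_residue_rmsd: dict  # residue id -> Angstrom
    mean_rmsd: float
    mean_rmsd_repacked: float
    chi_mae: np.ndarray  # degrees, per chi index, all residues
    chi_mae_repacked: np.ndarray  # degrees, per chi index, repacked only
    clashscore: float
    rotamer_outlier_pct: float
    marginal: list
    final_energy: float
    method: str = ""
    site: tuple = ()

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "site": list(self.site),
            "mean_rmsd": self.mean_rmsd,
            "mean_rmsd_repacked": self.mean_rmsd_repacked,
            "chi_mae": [None if np.isnan(x) else float(x) for x in self.chi_mae],
            "chi_mae_repacked": [None if np.isnan(x) else float(x)
                                 for x in self.chi_mae_repacked],
            "clashscore": self.clashscore,
            "rotamer_outlier_pct": self.rotamer_outlier_pct,
            "final_energy": self.final_energy,
            "marginal": [
                {"residue": list(m.residue_id), "code": m.code, "reasons": list(m.reasons)}
                for m in self.marginal
            ],
            "per_residue_rmsd": {
                "/".join(map(str, k)): v for k, v in self.per_residue_rmsd.items()
            },
        }


# ---------------------------------------------------------------------------
# metrics


def _sidechain_map(res: Residue) -> dict:
    return {a.name: a.pos for a in res.atoms
            if a.name not in BACKBONE_ATOMS and a.element != "H"}


def sidechain_rmsd(native_res: Residue, model_res: Residue) -> float:
    """Heavy-atom side-chain RMSD in the common frame (no superposition).

    Chemically equivalent atom pairs (PHE/TYR ring, ASP/GLU carboxylate,
    ARG guanidinium) are matched under the relabelling that minimises the
    RMSD.
    """
    if native_res.code != model_res.code:
        raise ValueError(
            f"residue code mismatch: {native_res.code} vs {model_res.code}")
    nat, mod = _sidechain_map(native_res), _sidechain_map(model_res)
    common = sorted(set(nat) & set(mod))
    if not common:
        return 0.0

    def rmsd(name_map):
        d2 = [np.sum((nat[n] - mod[name_map.get(n, n)]) ** 2) for n in common]
        return float(np.sqrt(np.mean(d2)))

    best = rmsd({})
    for swaps in _SYMMETRY_SWAPS.get(native_res.code, []):
        name_map = {}
        for a, b in swaps:
            name_map[a], name_map[b] = b, a
        if all(v in mod for v in name_map.values()):
            best = min(best, rmsd(name_map))
    return best


def _paired_residues(native: Structure, model: Structure, model_index=0,
                     reg=None):
    reg = reg or default_registry()
    model_by_id = {r.id: r for r in model.models[model_index]}
    for res in native.models[model_index]:
        if not res.is_polymer(reg):
            continue
        other = model_by_id.get(res.id)
        if other is not None and other.code == res.code:
            yield res, other


def chi_mae(native: Structure, model: Structure, reg: TopologyRegistry | None = None,
            residue_ids=None, model_index: int = 0) -> np.ndarray:
    """Circular mean absolute chi error (degrees) per chi index.

    Averages |wrap(chi_native - chi_model)| over residues possessing each chi
    index; restricted to ``residue_ids`` when given.  Entries with no
    comparable residue are NaN.
    """
    reg = reg or default_registry()
    wanted = None if residue_ids is None else {tuple(r) for r in residue_ids}
    sums, counts = {}, {}
    n_pairs = 0
    for nat, mod in _paired_residues(native, model, model_index, reg):
        if wanted is not None and nat.id not in wanted:
            continue
        cn = compute_chi(nat, reg=reg)
        cm = compute_chi(mod, reg=reg)
        n_pairs += 1
        for k in range(cn.size):
            if np.isnan(cn[k]) or np.isnan(cm[k]):
                continue
            dev = abs(float(wrap_degrees(cn[k] - cm[k])))
            dev = min(dev, 360.0 - dev)
            sums[k] = sums.get(k, 0.0) + dev
            counts[k] = counts.get(k, 0) + 1
    if n_pairs == 0:
        raise ValueError("no comparable residues between native and model")
    kmax = max(counts) + 1 if counts else 0
    out = np.full(kmax, np.nan)
    for k in counts:
        out[k] = sums[k] / counts[k]
    return out


def clashscore(structure: Structure, vdw_radii: dict | None = None,
               model_index: int = 0, reg: TopologyRegistry | None = None) -> float:
    """Serious steric overlaps (> 0.4 A beyond summed vdW radii) per 1000 atoms.

    Heavy atoms only; pairs within three covalent bonds are not counted.
    """
    reg = reg or default_registry()
    radii = vdw_radii or load_vdw_radii()
    residues, names, elements, res_idx, coords = _model_atom_table(
        structure, model_index, reg)
    heavy = [i for i, el in enumerate(elements) if el.upper() != "H"]
    if not heavy:
        return 0.0
    adj = _bond_adjacency(residues, names, res_idx, coords, reg)
    excluded = bonded_exclusions(adj)
    r = np.array([radii.get(elements[i].upper(), 1.7) for i in heavy])
    xyz = coords[heavy]
    n = len(heavy)
    count = 0
    # overlap > 0.4 requires d < r_i + r_j - 0.4 <= 3.6 A; a coarse cell grid
    # would be exact here, but n stays small in practice
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    overlap = (r[:, None] + r[None, :]) - d
    iu, ju = np.triu_indices(n, k=1)
    hit = overlap[iu, ju] > CLASH_THRESHOLD
    for i, j in zip(iu[hit], ju[hit]):
        gi, gj = heavy[int(i)], heavy[int(j)]
        if (min(gi, gj), max(gi, gj)) not in excluded:
            count += 1
    return 1000.0 * count / n


def _clashing_residues(structure: Structure, vdw_radii=None, model_index=0, reg=None):
    reg = reg or default_registry()
    radii = vdw_radii or load_vdw_radii()
    residues, names, elements, res_idx, coords = _model_atom_table(
        structure, model_index, reg)
    adj = _bond_adjacency(residues, names, res_idx, coords, reg)
    excluded = bonded_exclusions(adj)
    flagged = set()
    n = len(names)
    r = np.array([radii.get(el.upper(), 1.7) for el in elements])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    overlap = (r[:, None] + r[None, :]) - d
    iu, ju = np.triu_indices(n, k=1)
    hit = overlap[iu, ju] > CLASH_THRESHOLD
    for i, j in zip(iu[hit], ju[hit]):
        i, j = int(i), int(j)
        if (i, j) in excluded:
            continue
        flagged.add(residues[res_idx[i]].id)
        flagged.add(residues[res_idx[j]].id)
    return flagged


def rotamer_outlier_pct(structure: Structure, library_set: LibrarySet,
                        threshold_sigma: float = 3.0, model_index: int = 0,
                        reg: TopologyRegistry | None = None) -> float:
    """Percentage of scored residues farther than ``threshold_sigma`` x sigma
    (on any chi) from their nearest library rotamer."""
    outliers, scored = _rotamer_outliers(structure, library_set, threshold_sigma,
                                         model_index, reg)
    if scored == 0:
        raise ValueError("no residues could be scored against the library set")
    return 100.0 * len(outliers) / scored


def _rotamer_outliers(structure, library_set, threshold_sigma=3.0, model_index=0,
                      reg=None):
    reg = reg or default_registry()
    if not library_set.by_code and not library_set.by_id:
        raise ValueError("empty library set")
    outliers = []
    scored = 0
    for res in structure.models[model_index]:
        if not res.is_polymer(reg) or reg.get(res.code).chi_count == 0:
            continue
        if not library_set.has(res):
            continue
        chi = compute_chi(res, reg=reg)
        if np.any(np.isnan(chi)):
            continue
        lib = library_set.for_residue(res)
        scored += 1
        rot, _ = nearest_rotamer(chi, lib)
        dev = np.abs(wrap_degrees(chi - np.array(rot.chi_mean)))
        if np.any(dev > threshold_sigma * np.array(rot.chi_sigma)):
            outliers.append(res.id)
    return outliers, scored


def classify_marginal(structure: Structure, library_set: LibrarySet,
                      threshold_sigma: float = 3.0, vdw_radii=None,
                      model_index: int = 0,
                      reg: TopologyRegistry | None = None) -> list:
    """Residues flagged for abnormal close contacts or rotamer outliers."""
    reg = reg or default_registry()
    clashing = _clashing_residues(structure, vdw_radii, model_index, reg)
    outliers, _ = _rotamer_outliers(structure, library_set, threshold_sigma,
                                    model_index, reg)
    outlier_set = set(outliers)
    by_id = {r.id: r for r in structure.models[model_index]}
    out = []
    for rid in sorted(clashing | outlier_set):
        reasons = []
        if rid in clashing:
            reasons.append("close_contacts")
        if rid in outlier_set:
            reasons.append("rotamer_outlier")
        res = by_id[rid]
        if not res.is_polymer(reg):
            continue
        out.append(MarginalResidue(rid, res.code, tuple(reasons)))
    return out


# ---------------------------------------------------------------------------
# the full protocol


_METHODS = ("mcmc_rotamer", "mcmc_off", "ga_rotamer", "ga_random")


def strip_rebuild_protocol(structure: Structure, site, method: str,
                           libraries: LibrarySet | None = None,
                           mcmc_config: MCMCConfig | None = None,
                           ga_config: GAConfig | None = None,
                           energy_table: ParamTable | None = None,
                           radius: float = 10.0, seed: int = 0,
                           threshold_sigma: float = 3.0,
                           reg: TopologyRegistry | None = None):
    """Strip all side chains, restore them, repack around ``site``, and score.

    Restoration places every polymer residue's side chain at its library's
    most frequent rotamer mean (uniform random chi for ``ga_random``); the
    movable set within ``radius`` of the site is then repacked with the
    chosen method and the result compared against the original structure.
    Returns (EvalReport, repacked Structure).
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_METHODS}")
    reg = reg or default_registry()
    if libraries is None and method != "ga_random":
        raise ValueError(f"method {method!r} requires rotamer libraries")

    rng = np.random.default_rng(seed)
    stripped = strip_sidechains(structure, reg=reg)

    # restore every polymer residue
    restored = stripped
    for res in restored.models[0]:
        if not res.is_polymer(reg):
            continue
        k = reg.get(res.code).chi_count
        if method == "ga_random" or (libraries is not None and not libraries.has(res)
                                     and k > 0):
            chi = rng.uniform(-180.0, 180.0, size=k)
        elif k > 0:
            lib = libraries.for_residue(res)
            chi = np.array(lib.rotamers[int(np.argmax(lib.frequencies))].chi_mean)
        else:
            chi = np.zeros(0)
        rebuild_sidechain(res, chi, reg=reg)

    task = PackingTask(restored, site, radius=radius)
    if method in ("mcmc_rotamer", "mcmc_off"):
        cfg = mcmc_config or MCMCConfig(seed=seed)
        mode = "rotamer" if method == "mcmc_rotamer" else "off_rotamer"
        if cfg.mode != mode:
            cfg = MCMCConfig(steps=cfg.steps, temperature=cfg.temperature,
                             mode=mode, seed=cfg.seed, anneal_to=cfg.anneal_to)
        result = repack_mcmc(task, cfg, libraries, energy_table, reg)
    else:
        init = "rotamer" if method == "ga_rotamer" else "uniform"
        cfg = ga_config or GAConfig(seed=seed)
        if cfg.init_mode != init:
            cfg = GAConfig(**{**cfg.__dict__, "init_mode": init})
        result = evolve(task, cfg, energy_table,
                        libraries if init == "rotamer" else None, reg)

    repacked = result.structure
    movable_ids = [tuple(m) for m in task.movable]

    per_rmsd = {}
    for nat, mod in _paired_residues(structure, repacked, 0, reg):
        per_rmsd[nat.id] = sidechain_rmsd(nat, mod)
    mae_all = chi_mae(structure, repacked, reg)
    mae_rep = chi_mae(structure, repacked, reg, residue_ids=movable_ids)
    rep_vals = [v for k, v in per_rmsd.items() if k in set(movable_ids)]

    if libraries is not None:
        out_pct = rotamer_outlier_pct(repacked, libraries, threshold_sigma, 0, reg)
        marginal = classify_marginal(repacked, libraries, threshold_sigma, None, 0, reg)
    else:
        out_pct = float("nan")
        marginal = [MarginalResidue(rid, "", ("close_contacts",))
                    for rid in sorted(_clashing_residues(repacked, None, 0, reg))]

    report = EvalReport(
        per_residue_rmsd=per_rmsd,
        mean_rmsd=float(np.mean(list(per_rmsd.values()))) if per_rmsd else 0.0,
        mean_rmsd_repacked=float(np.mean(rep_vals)) if rep_vals else 0.0,
        chi_mae=mae_all,
        chi_mae_repacked=mae_rep,
        clashscore=clashscore(repacked, None, 0, reg),
        rotamer_outlier_pct=out_pct,
        marginal=marginal,
        final_energy=result.best_energy,
        method=method,
        site=structure.find(site).id,
    )
    return report, repacked
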