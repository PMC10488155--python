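"""Metropolis-Hastings side-chain repacking.

Two proposal kernels over the movable region around a mutation/modification
site: ``rotamer`` draws a library rotamer (frequency-weighted) and sets the
side chain to its mean chi values; ``off_rotamer`` additionally perturbs each
chi with a von Mises draw centred on the rotamer mean with concentration
k = 1/sigma^2, letting conformations leave the library grid while the library
still controls the scale of the excursions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import PackingSystem, ParamTable
from .geometry import wrap_degrees
from .rotamers import LibrarySet, sample_rotamer
from .structure import Structure, neighbors_within
from .topology import TopologyRegistry, registry as default_registry

__all__ = [
    "PackingTask",
    "MCMCConfig",
    "VonMisesParams",
    "PackingResult",
    "metropolis_accept",
    "sample_von_mises",
    "propose_rotamer_move",
    "propose_offrotamer_move",
    "repack_mcmc",
]

SIGMA_FLOOR_RAD = math.radians(1.0)


@dataclass
class PackingTask:
    """A repacking problem: the site residue and its movable neighborhood."""

    structure: Structure
    site: tuple  # residue id
    radius: float = 10.0
    movable: list = None  # residue ids; default: neighbors_within(site, radius)
    model_index: int = 0

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.movable is None:
            self.movable = [
                r.id for r in neighbors_within(
                    self.structure, self.site, self.radius, self.model_index)
            ]
        site_id = self.structure.find(self.site, self.model_index).id
        if site_id not in [tuple(m) for m in self.movable]:
            raise ValueError("site must be part of the movable set")


@dataclass(frozen=True)
class MCMCConfig:
    steps: int | None = None  # default 100 x movable residues
    temperature: float = 1.0  # Metropolis scale, score units
    mode: str = "rotamer"  # "rotamer" | "off_rotamer"
    seed: int = 0
    anneal_to: float | None = None  # optional linear temperature ramp target

    def __post_init__(self):
        if self.steps is not None and self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.mode not in ("rotamer", "off_rotamer"):
            raise ValueError(f"unknown MCMC mode {self.mode!r}")


@dataclass(frozen=True)
class VonMisesParams:
    mu: float  # mode, radians
    k: float  # concentration = 1/sigma^2

    def __post_init__(self):
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError("concentration k must be positive and finite")


@dataclass
class PackingResult:
    structure: Structure
    final_energy: float
    best_energy: float
    acceptance_rate: float
    energy_trace: np.ndarray  # accepted-state energy per step
    best_genes: np.ndarray = None  # chi state (degrees) of the best conformation


def metropolis_accept(delta_E: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept downhill moves always; uphill with probability exp(-dE/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_E <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_E / temperature))


def sample_von_mises(params: VonMisesParams, rng: np.random.Generator) -> float:
    """One von Mises(mu, k) draw, in (-pi, pi]."""
    x = rng.vonmises(params.mu, params.k)
    return float(x if x > -math.pi else math.pi)


def _proposable(system: PackingSystem, libraries: LibrarySet):
    """Movable-residue slots with at least one chi; all must carry a library."""
    slots = []
    for r, ri in enumerate(system.movable_ri):
        res = system.residues[ri]
        if system.chi_counts[r] == 0:
            continue  # glycine/alanine: placed once, never proposed
        if not libraries.has(res):
            raise ValueError(
                f"movable residue {res.code} {res.id} has no rotamer library")
        slots.append(r)
    if not slots:
        raise ValueError("no movable residues with chi angles")
    return slots


def propose_rotamer_move(task_or_system, library_set: LibrarySet,
                         rng: np.random.Generator, slots=None):
    """Uniformly pick a movable residue; set chi to a sampled rotamer's means."""
    system = _as_system(task_or_system)
    slots = slots if slots is not None else _proposable(system, library_set)
    r = int(slots[rng.integers(len(slots))])
    res = system.residues[system.movable_ri[r]]
    rot = sample_rotamer(library_set.for_residue(res), rng)
    return r, np.array(rot.chi_mean, dtype=float)


def propose_offrotamer_move(task_or_system, library_set: LibrarySet,
                            rng: np.random.Generator, slots=None):
    """As the rotamer move, then perturb each chi by a von Mises draw with
    concentration 1/sigma^2 (sigma from the library, floored, in radians)."""
    system = _as_system(task_or_system)
    slots = slots if slots is not None else _proposable(system, library_set)
    r = int(slots[rng.integers(len(slots))])
    res = system.residues[system.movable_ri[r]]
    rot = sample_rotamer(library_set.for_residue(res), rng)
    chi = np.empty(len(rot.chi_mean))
    for i, (mu_deg, sig_deg) in enumerate(zip(rot.chi_mean, rot.chi_sigma)):
        sigma = max(math.radians(sig_deg), SIGMA_FLOOR_RAD)
        draw = sample_von_mises(VonMisesParams(math.radians(mu_deg), 1.0 / sigma ** 2), rng)
        chi[i] = math.degrees(draw)
    return r, wrap_degrees(chi)


def _as_system(task_or_system) -> PackingSystem:
    if isinstance(task_or_system, PackingSystem):
        return task_or_system
    t = task_or_system
    return PackingSystem(t.structure, t.movable, model_index=t.model_index)


def repack_mcmc(task: PackingTask, config: MCMCConfig, library_set: LibrarySet,
                energy_table: ParamTable | None = None,
                reg: TopologyRegistry | None = None,
                system: PackingSystem | None = None) -> PackingResult:
    """Metropolis-Hastings repacking of the task's movable region.

    Proposals follow ``config.mode``; energies are incremental over the pairs
    touching the moved residue.  The best-energy conformation seen is
    returned (the input conformation when ``steps = 0`` or nothing better is
    found).  Fully deterministic for a fixed seed.
    """
    reg = reg or default_registry()
    rng = np.random.default_rng(config.seed)
    system = system or PackingSystem(task.structure, task.movable, energy_table,
                                     task.model_index, reg)
    slots = _proposable(system, library_set)
    steps = config.steps if config.steps is not None else 100 * system.n_residues

    # initial state: actual coordinates when complete, else rebuilt from chi
    sc = system.current_sidechain_coords()
    genes = system.initial_chi()
    if sc is None:
        if np.any(np.isnan(genes)):
            raise ValueError(
                "movable side chains are incomplete; restore them before repacking")
        sc = system.rebuild_all(genes)[0]
    genes = np.where(np.isnan(genes), 0.0, genes)

    if config.mode == "rotamer":
        return _repack_discrete(system, config, library_set, slots, sc, genes, steps, rng)

    gene_slices = system.gene_slices()
    propose = propose_offrotamer_move

    energy = system.energy(sc)
    best_energy, best_genes, best_is_initial = energy, genes.copy(), True
    trace = np.empty(steps)
    accepted = 0

    for step in range(steps):
        T = config.temperature
        if config.anneal_to is not None and steps > 1:
            T = config.temperature + (config.anneal_to - config.temperature) * step / (steps - 1)
        r, chi = propose(system, library_set, rng, slots)
        new_coords = system.rebuild_residue(r, chi[None])[0]
        # only pairs touching residue r change
        e_old = system.residue_energy(r, sc[system.res_slices[r]], sc)
        e_new = system.residue_energy(r, new_coords, sc)
        delta = e_new - e_old
        if metropolis_accept(delta, T, rng):
            accepted += 1
            sc[system.res_slices[r]] = new_coords
            genes[gene_slices[r]] = chi
            energy += delta
            if energy < best_energy - 1e-12:
                best_energy, best_genes, best_is_initial = energy, genes.copy(), False
        trace[step] = energy

    if best_is_initial:
        out = system.structure.copy()
    else:
        out = system.apply_to_structure(best_genes)
    return PackingResult(
        structure=out,
        final_energy=best_energy,
        best_energy=best_energy,
        acceptance_rate=accepted / steps if steps else 0.0,
        energy_trace=trace,
        best_genes=best_genes,
    )


def _repack_discrete(system: PackingSystem, config: MCMCConfig, library_set: LibrarySet,
                     slots, sc, genes, steps, rng) -> PackingResult:
    """Rotamer-mode sampler over the finite library grid.

    The proposal space is discrete (library rotamer means), so all candidate
    side-chain coordinates and their context/cross energies are tabulated
    once and each Metropolis step reduces to table lookups.  Results are
    identical to scoring each proposal from scratch.
    """
    R = system.n_residues
    gene_slices = system.gene_slices()
    cand_chi, cand_coords, freqs = [], [], []
    for r in range(R):
        init_coords = sc[system.res_slices[r]][None]
        if r in slots:
            lib = library_set.for_residue(system.residues[system.movable_ri[r]])
            chis = np.vstack([lib.means, genes[gene_slices[r]][None]])
            coords = np.concatenate(
                [system.rebuild_residue(r, lib.means), init_coords], axis=0)
            freqs.append(lib.frequencies)
        else:
            chis = genes[gene_slices[r]][None]
            coords = init_coords
            freqs.append(None)
        cand_chi.append(chis)
        cand_coords.append(coords)

    E_ctx = [system.residue_context_energy(r, cand_coords[r]) for r in range(R)]
    E_cross = {}
    for r in range(R):
        for q in range(r + 1, R):
            E_cross[(r, q)] = system.cross_energy(r, q, cand_coords[r], cand_coords[q])

    def cross(r, q, i, j):
        return E_cross[(r, q)][i, j] if r < q else E_cross[(q, r)][j, i]

    state = [len(c) - 1 for c in cand_coords]  # initial conformation
    energy = sum(E_ctx[r][state[r]] for r in range(R)) + sum(
        cross(r, q, state[r], state[q]) for r in range(R) for q in range(r + 1, R))

    best_energy, best_state, best_is_initial = energy, list(state), True
    trace = np.empty(steps)
    accepted = 0
    slots = list(slots)
    for step in range(steps):
        T = config.temperature
        if config.anneal_to is not None and steps > 1:
            T = config.temperature + (config.anneal_to - config.temperature) * step / (steps - 1)
        r = slots[int(rng.integers(len(slots)))]
        j = int(rng.choice(len(freqs[r]), p=freqs[r]))
        cur = state[r]
        delta = E_ctx[r][j] - E_ctx[r][cur]
        for q in range(R):
            if q != r:
                delta += cross(r, q, j, state[q]) - cross(r, q, cur, state[q])
        if metropolis_accept(delta, T, rng):
            accepted += 1
            state[r] = j
            energy += delta
            if energy < best_energy - 1e-12:
                best_energy, best_state, best_is_initial = energy, list(state), False
        trace[step] = energy

    for r in range(R):
        genes[gene_slices[r]] = cand_chi[r][best_state[r]]
    if best_is_initial:
        out = system.structure.copy()
    else:
        out = system.apply_to_structure(genes)
    return PackingResult(
        structure=out,
        final_energy=float(best_energy),
        best_energy=float(best_energy),
        acceptance_rate=accepted / steps if steps else 0.0,
        energy_trace=trace,
        best_genes=genes.copy(),
    )
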