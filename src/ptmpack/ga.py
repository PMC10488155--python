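"""Real-coded genetic algorithm for side-chain repacking.

Chromosomes concatenate the movable residues' chi angles (radians, clipped to
(-pi, pi]); fitness is the flat-top Lennard-Jones region score (lower is
better).  Selection is k-tournament (k = population/20) with 15% elitism;
mating applies BLX-alpha or simulated binary crossover (SBX) equiprobably
with probability 0.9; mutation (probability 0.15 per individual) draws either
a von Mises perturbation with concentration 1/sigma^2 or Deb's bounded
polynomial operator, again equiprobably.  The population can be initialised
from a rotamer library or from a uniform distribution over (-pi, pi); the
uniform mode needs no library at all, which matters for modified residues
where libraries are thin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import PackingSystem, ParamTable
from .mcmc import PackingResult, PackingTask, SIGMA_FLOOR_RAD
from .rotamers import LibrarySet
from .topology import TopologyRegistry, registry as default_registry

__all__ = [
    "GAConfig",
    "Population",
    "init_population",
    "tournament_select",
    "blx_crossover",
    "sbx_beta",
    "sbx_crossover",
    "mutate_von_mises",
    "mutate_polynomial",
    "evolve",
]

_PI = math.pi
_SIGMA_BOUNDS = (1e-3, _PI)  # sigma genes live on this interval (radians)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 300
    generations: int = 40
    crossover_prob: float = 0.9
    mutation_prob: float = 0.15
    elitism_fraction: float = 0.15
    tournament_fraction: float = 1.0 / 20.0
    blx_alpha: float = 0.5
    sbx_eta: float = 12.0
    polynomial_eta: float = 20.0
    init_mode: str = "rotamer"  # "rotamer" | "uniform"
    sigma_init_upper: float = 0.5  # radians; upper bound of the uniform sigma init
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        for f in (self.elitism_fraction, self.tournament_fraction):
            if not (0 < f <= 1):
                raise ValueError("fractions must be in (0, 1]")
        if self.sbx_eta <= 0 or self.polynomial_eta <= 0:
            raise ValueError("distribution indices must be > 0")
        if self.init_mode not in ("rotamer", "uniform"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    @property
    def tournament_size(self) -> int:
        return max(1, round(self.tournament_fraction * self.population_size))

    @property
    def n_elite(self) -> int:
        return max(1, round(self.elitism_fraction * self.population_size))


@dataclass
class Population:
    genes: np.ndarray  # (P, G) radians in (-pi, pi]
    sigma: np.ndarray  # (P, G) radians, paired spread genes
    fitness: np.ndarray  # (P,), lower is better


def clip_angles(x):
    """Clip to the chromosome domain (-pi, pi]; out-of-range values are set to
    the nearest boundary (with -pi folded onto the equivalent +pi)."""
    x = np.clip(x, -_PI, _PI)
    return np.where(x == -_PI, _PI, x)


def init_population(system_or_task, config: GAConfig,
                    library_set: LibrarySet | None, rng: np.random.Generator) -> Population:
    """Initial population: rotamer-sampled or uniform over (-pi, pi)."""
    system = _as_system(system_or_task)
    P, G = config.population_size, system.gene_count
    if P < 1:
        raise ValueError("population_size must be positive")
    if config.init_mode == "uniform":
        genes = rng.uniform(-_PI, _PI, size=(P, G))
        sigma = rng.uniform(0.0, config.sigma_init_upper, size=(P, G))
        sigma = np.maximum(sigma, _SIGMA_BOUNDS[0])
    else:
        if library_set is None:
            raise ValueError("rotamer initialisation requires a library set")
        genes = np.empty((P, G))
        sigma = np.empty((P, G))
        for r, sl in enumerate(system.gene_slices()):
            res = system.residues[system.movable_ri[r]]
            if sl.stop == sl.start:
                continue
            lib = library_set.for_residue(res)
            idx = rng.choice(len(lib), size=P, p=lib.frequencies)
            genes[:, sl] = np.radians(lib.means[idx])
            sigma[:, sl] = np.maximum(np.radians(lib.sigmas[idx]), _SIGMA_BOUNDS[0])
    return Population(clip_angles(genes), sigma, np.full(P, np.nan))


def tournament_select(population: Population, k: int, rng: np.random.Generator) -> int:
    """Index of the best-fitness member of k distinct uniform draws."""
    P = len(population.fitness)
    if not (1 <= k <= P):
        raise ValueError(f"tournament size {k} out of range 1..{P}")
    contenders = rng.choice(P, size=k, replace=False)
    return int(contenders[np.argmin(population.fitness[contenders])])


def blx_crossover(p1, p2, alpha: float, rng: np.random.Generator,
                  bounds=(-_PI, _PI)):
    """Blend crossover: children uniform on the parent interval widened by
    alpha on each side, then clipped to the nearest boundary."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    p1, p2 = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    lo = np.minimum(p1, p2)
    hi = np.maximum(p1, p2)
    span = hi - lo
    a, b = lo - alpha * span, hi + alpha * span
    c1 = rng.uniform(a, b)
    c2 = rng.uniform(a, b)
    lo_b, hi_b = bounds
    c1 = np.clip(c1, lo_b, hi_b)
    c2 = np.clip(c2, lo_b, hi_b)
    if bounds == (-_PI, _PI):
        c1, c2 = clip_angles(c1), clip_angles(c2)
    return c1, c2


def sbx_beta(mu, eta: float):
    """SBX spread coefficient from a uniform variate.

    beta = (2 mu)^(1/(eta+1)) for mu <= 0.5, else (1 / (2 (1 - mu)))^(1/(eta+1)).
    mu is capped just below 1 to keep beta finite.
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    mu = np.asarray(mu, dtype=float)
    if np.any((mu < 0) | (mu > 1)):
        raise ValueError("mu must be in [0, 1]")
    mu = np.minimum(mu, 1.0 - 1e-6)
    exponent = 1.0 / (eta + 1.0)
    out = np.where(mu <= 0.5,
                   (2.0 * mu) ** exponent,
                   (1.0 / (2.0 * (1.0 - mu))) ** exponent)
    return float(out) if out.ndim == 0 else out


def sbx_crossover(p1, p2, eta: float, rng: np.random.Generator,
                  bounds=(-_PI, _PI), beta=None):
    """Simulated binary crossover; one beta per gene, parents' mean preserved
    before clipping."""
    p1, p2 = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    if beta is None:
        beta = sbx_beta(rng.uniform(0.0, 1.0, size=p1.shape), eta)
    c1 = 0.5 * ((1.0 + beta) * p1 + (1.0 - beta) * p2)
    c2 = 0.5 * ((1.0 - beta) * p1 + (1.0 + beta) * p2)
    lo_b, hi_b = bounds
    c1, c2 = np.clip(c1, lo_b, hi_b), np.clip(c2, lo_b, hi_b)
    if bounds == (-_PI, _PI):
        c1, c2 = clip_angles(c1), clip_angles(c2)
    return c1, c2


def mutate_von_mises(genes, sigma, rng: np.random.Generator, gene_index=None):
    """Resample one gene from von Mises(mu = gene, k = 1/sigma^2)."""
    genes = np.array(genes, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    i = int(rng.integers(genes.size)) if gene_index is None else gene_index
    s = max(float(sigma[i]), SIGMA_FLOOR_RAD)
    genes[i] = rng.vonmises(genes[i], 1.0 / s ** 2)
    return clip_angles(genes)


def mutate_polynomial(genes, eta_m: float, rng: np.random.Generator,
                      gene_index=None, bounds=(-_PI, _PI)):
    """Deb's bounded polynomial mutation of one gene."""
    if eta_m <= 0:
        raise ValueError("eta_m must be > 0")
    genes = np.array(genes, dtype=float)
    i = int(rng.integers(genes.size)) if gene_index is None else gene_index
    lo, hi = bounds
    x = genes[i]
    u = rng.uniform()
    d1 = (x - lo) / (hi - lo)
    d2 = (hi - x) / (hi - lo)
    exp = 1.0 / (eta_m + 1.0)
    if u < 0.5:
        dq = (2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta_m + 1.0)) ** exp - 1.0
    else:
        dq = 1.0 - (2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta_m + 1.0)) ** exp
    genes[i] = x + dq * (hi - lo)
    if bounds == (-_PI, _PI):
        return clip_angles(genes)
    return np.clip(genes, lo, hi)


def _as_system(system_or_task) -> PackingSystem:
    if isinstance(system_or_task, PackingSystem):
        return system_or_task
    t = system_or_task
    return PackingSystem(t.structure, t.movable, model_index=t.model_index)


def evolve(task: PackingTask, config: GAConfig,
           energy_table: ParamTable | None = None,
           library_set: LibrarySet | None = None,
           reg: TopologyRegistry | None = None,
           system: PackingSystem | None = None,
           log: list | None = None) -> PackingResult:
    """Run the genetic algorithm and return the best conformation found.

    ``log``, when given, receives one (generation, best, mean, worst) tuple
    per generation.  Deterministic for a fixed config seed.
    """
    reg = reg or default_registry()
    rng = np.random.default_rng(config.seed)
    system = system or PackingSystem(task.structure, task.movable, energy_table,
                                     task.model_index, reg)
    pop = init_population(system, config, library_set, rng)
    P, G = pop.genes.shape

    def evaluate(stale_mask):
        idx = np.where(stale_mask)[0]
        if idx.size:
            coords = system.rebuild_all(np.degrees(pop.genes[idx]))
            pop.fitness[idx] = system.energy(coords)

    evaluate(np.ones(P, dtype=bool))
    k_t = config.tournament_size
    n_elite = config.n_elite

    for gen in range(config.generations):
        if log is not None:
            log.append((gen, float(np.min(pop.fitness)), float(np.mean(pop.fitness)),
                        float(np.max(pop.fitness))))
        order = np.argsort(pop.fitness, kind="stable")
        elite_idx = order[:n_elite]

        # parent pool the size of the population, each from a k-tournament
        pool = [tournament_select(pop, k_t, rng) for _ in range(P)]

        new_genes = np.empty_like(pop.genes)
        new_sigma = np.empty_like(pop.sigma)
        new_fit = np.full(P, np.nan)
        new_genes[:n_elite] = pop.genes[elite_idx]
        new_sigma[:n_elite] = pop.sigma[elite_idx]
        new_fit[:n_elite] = pop.fitness[elite_idx]

        out = n_elite
        pair_at = 0
        while out < P:
            i1 = pool[pair_at % P]
            i2 = pool[(pair_at + 1) % P]
            pair_at += 2
            g1, g2 = pop.genes[i1].copy(), pop.genes[i2].copy()
            s1, s2 = pop.sigma[i1].copy(), pop.sigma[i2].copy()
            changed = False
            if rng.random() < config.crossover_prob:
                changed = True
                if rng.random() < 0.5:
                    g1, g2 = blx_crossover(g1, g2, config.blx_alpha, rng)
                    s1, s2 = blx_crossover(s1, s2, config.blx_alpha, rng,
                                           bounds=_SIGMA_BOUNDS)
                else:
                    g1, g2 = sbx_crossover(g1, g2, config.sbx_eta, rng)
                    s1, s2 = sbx_crossover(s1, s2, config.sbx_eta, rng,
                                           bounds=_SIGMA_BOUNDS)
            for g, s, src in ((g1, s1, i1), (g2, s2, i2)):
                if out >= P:
                    break
                mutated = False
                if G > 0 and rng.random() < config.mutation_prob:
                    mutated = True
                    gi = int(rng.integers(G))
                    if rng.random() < 0.5:
                        g[:] = mutate_von_mises(g, s, rng, gene_index=gi)
                    else:
                        g[:] = mutate_polynomial(g, config.polynomial_eta, rng,
                                                 gene_index=gi)
                    s[:] = mutate_polynomial(s, config.polynomial_eta, rng,
                                             gene_index=gi, bounds=_SIGMA_BOUNDS)
                new_genes[out] = g
                new_sigma[out] = s
                if not changed and not mutated:
                    new_fit[out] = pop.fitness[src]  # cached: genes unchanged
                out += 1

        pop.genes, pop.sigma, pop.fitness = new_genes, new_sigma, new_fit
        evaluate(np.isnan(pop.fitness))

    if log is not None:
        log.append((config.generations, float(np.min(pop.fitness)),
                    float(np.mean(pop.fitness)), float(np.max(pop.fitness))))
    best = int(np.argmin(pop.fitness))
    best_genes_deg = np.degrees(pop.genes[best])
    structure = system.apply_to_structure(best_genes_deg)
    trace = np.array([row[1] for row in (log or [])]) if log else np.array(
        [float(pop.fitness[best])])
    return PackingResult(
        structure=structure,
        final_energy=float(pop.fitness[best]),
        best_energy=float(pop.fitness[best]),
        acceptance_rate=math.nan,
        energy_trace=trace,
        best_genes=best_genes_deg,
    )
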