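# Methods

## Model overview

`ptmpack` treats side-chain prediction as fixed-backbone packing: the
backbone (N, CA, C, O) never moves, every side chain (CB outward) is a rigid
tree of atoms positioned by its χ dihedral angles with ideal bond lengths
and angles, and the objective is a pairwise steric score over the movable
region. Three assumptions follow:

- **Ideal internal geometry.** Side chains are rebuilt by sequential
  internal-coordinate (natural extension) construction from per-residue
  templates. Template bond lengths, angles and branch dihedral offsets are
  taken from the ideal-coordinate chemical component dictionary and embedded
  as plain-text data (`data/residue_topology.txt`, regenerable with
  `scripts/make_template_data.py`). Rebuilding a residue from its own
  computed χ therefore reproduces experimental coordinates only up to the
  deviation of the real geometry from ideal; on ideal-geometry fixtures the
  round trip is exact to 1e-6°.
- **Heavy atoms only.** Hydrogens are neither built nor scored. The
  clashscore reported here uses the same >0.4 Å overlap threshold as the
  common validation services but, lacking hydrogens, produces systematically
  lower values than a hydrogen-aware analysis; it is an internally consistent
  variant, not a drop-in replacement.
- **One energy term.** The only score is the flat-top Lennard-Jones clash
  function. No electrostatics, solvation, hydrogen bonding or torsional
  statistics enter, so "optimal" always means "least clashing", and the
  native conformation is recovered only insofar as it is sterically
  distinctive.

## Residue topology

Twenty canonical residues plus five common modifications are registered:
phosphoserine (SEP), phosphothreonine (TPO), O-phosphotyrosine (PTR),
N-dimethyl-lysine (MLY) and S-hydroxycysteine (CSO). Modified residues
extend their parent's χ list with the dihedral that carries the modifying
group: SEP/TPO add χ2 = CA-CB-OG(1)-P, PTR adds the ring-exit χ3 =
CE1-CZ-OH-P, CSO adds χ2 = CA-CB-SG-OD, and MLY adds χ5 = CD-CE-NZ-CH1
(the PDB component names the two methyls CH1/CH2; the second methyl rides
at a fixed offset). Phosphate oxygens ride at fixed tetrahedral offsets —
their internal rotation is not a degree of freedom. χ definitions can be
overridden at run time from a flat text file, so unusual conventions or new
residue codes with matching heavy atoms can be accommodated without code
changes.

Dihedral sign convention is the standard one (IUPAC; identical to biotite
and MDAnalysis): the common serine m rotamer is χ1 ≈ −65°.

## Clash energy

With x = d/σᵢⱼ, σᵢⱼ = rᵢ + rⱼ and Eᵢⱼ = √(EᵢEⱼ):

| branch | value |
|---|---|
| x ≤ x₀ | 10 |
| x₀ < x ≤ 1 | 57.273 (1 − x) |
| 1 < x ≤ 10/9 | Eᵢⱼ(10 − 9x) − Eᵢⱼ |
| 10/9 < x ≤ 4/3 | (Eᵢⱼ/4)(9x − 10)² − Eᵢⱼ |
| x > 4/3 | 0 |

The plateau breakpoint is stored as x₀ = 1 − 10/57.273 ≈ 0.825402, the
unique value at which the ramp meets the plateau exactly; quoting it as
0.8254 is a four-decimal rounding, and using the rounded value literally
would introduce a 1.3e-4 jump. The function is continuous everywhere,
bounded in [−Eᵢⱼ, 10], with its minimum −Eᵢⱼ at x = 10/9 — all three
properties are regression-tested over random parameters. Note the units are
deliberately mixed, following common packing practice: the repulsive side is
a dimensionless clash scale while the well depth is kcal/mol; the sum is
treated as one score.

Per-element well depths (param19-derived) and contact radii live in
`data/energy_params.txt` and can be replaced by the user; atoms are typed by
element (C 0.120/1.75, N 0.2384/1.55, O 0.1591/1.45, S 0.043/1.85,
P 0.585/1.85 kcal/mol / Å). Pairs within three covalent bonds (1-2, 1-3,
1-4) are excluded; bonds come from the residue templates plus
geometry-detected peptide C–N links. Region energies sum over every
non-excluded pair touching a movable side-chain atom; waters, ions and
unregistered ligands are never repacked but always count as fixed context.

`PackingSystem` precompiles a movable region — atom tables, pair-parameter
matrices, exclusion masks, and batched rebuild plans — so the GA can score a
whole population per numpy call and the MCMC can evaluate a move from the
pairs touching one residue. Both paths are exact: they equal the brute-force
O(n²) sum, which the tests assert.

## Rotamer libraries

Libraries are backbone-independent. Construction pools complete χ vectors
for the requested code over all structures, chains and models (each model is
an independent observation), then clusters them circularly:

- **wells** (default): each χ is assigned independently to the circularly
  nearest of the canonical sp³ wells (−60°, +60°, 180°, width 120°);
  observations outside every well fall into overflow bins. Deterministic and
  order-invariant.
- **kmeans-circular** (option): Lloyd iterations on the torus, initialised
  from the wells partition, for distributions that straddle well boundaries.

Each surviving cluster (min_count ≥ 3 by default) yields a rotamer with
circular mean, circular σ floored at 1° — the floor keeps the off-rotamer
concentration k = 1/σ² finite — and frequency = cluster size / retained
observations, renormalised to sum to one after pruning. Resolution or
occupancy filtering of the input structures is the caller's responsibility.
An internal-energy column is carried through I/O if present but never used
by the packers.

The native file format is a versioned plain-text table (one rotamer per
line: count, frequency, χ means, χ σs, optional energy). A reader for a
backbone-independent Dunbrack-style dialect (residue, four bin ids, count,
probability, four χ means, four σs per line) is provided; probabilities are
renormalised on load.

## MCMC packers

A packing task fixes a site residue and a movable set (default: every
polymer residue with any atom within 10 Å of the site, the site included).
Residues without χ (Gly/Ala) are placed once from templates and never
proposed. Each step picks a movable residue uniformly, proposes new χ
values, and accepts by the Metropolis criterion at temperature T (default
1.0 in score units — the plateau height 10 then strongly rejects severe
clashes; the paper-level sources leave T open). The default budget is
100 steps × movable residues. The best-energy conformation ever visited is
returned; with steps = 0 the input conformation and its energy are returned
unchanged.

- *Rotamer mode* samples a rotamer by library frequency and applies its mean
  χ. Because the proposal space is the finite library grid, all candidate
  side-chain coordinates and their context/cross energies are tabulated once
  and each step reduces to table lookups — bit-identical to scoring every
  proposal from scratch, which the incremental-equals-full test enforces.
- *Off-rotamer mode* perturbs each χ of the sampled rotamer with a von Mises
  draw centred on the rotamer mean with k = 1/σ² (σ per-χ, converted to
  radians, floored at 1°). Proposals are therefore continuous and almost
  never coincide with a library mean.

With uniform proposal frequencies the chain's stationary distribution on a
two-state system is the Boltzmann weight; this is verified to ±0.02 over
10⁵ steps. (With non-uniform rotamer frequencies the kernel is an
independence-proposal Metropolis without the Hastings correction, matching
the procedure as published.)

## Genetic algorithm

Chromosomes concatenate the movable residues' χ angles in radians, domain
(−π, π]; a parallel vector of σ genes accompanies them (library σ under
rotamer initialisation, U(0, 0.5 rad) under uniform initialisation).
Fitness is the region clash score (lower is better). Per generation:

1. the top 15 % (n ≥ 1) are copied unchanged (elitism — best fitness is
   non-increasing, property-tested);
2. a parent pool the size of the population is drawn by k-tournament,
   k = round(population/20), min 1;
3. consecutive pool pairs produce two children each. With probability 0.9
   the pair undergoes crossover, BLX-α (α = 0.5) or SBX (η = 12) chosen
   equiprobably, applied gene-wise with one β draw per gene (μ capped at
   1 − 10⁻⁶ so β stays finite); σ genes undergo the same operator on their
   own bounds;
4. each child mutates with probability 0.15: one uniformly chosen gene is
   either resampled from von Mises(gene, 1/σ²) or perturbed by Deb's bounded
   polynomial operator (distribution index 20 — separate from the SBX η and
   chosen as common practice), the two types equiprobable; the paired σ gene
   receives a bounded polynomial perturbation.

Out-of-domain offspring are set to the nearest boundary (−π folded onto the
equivalent +π so the half-open domain invariant holds). Individuals
untouched by the operators keep their cached fitness. Granularity choices —
one operator per mating pair, per-gene β, one mutated gene per event — are
this package's interpretation where the published description speaks of
scalar operators; all are configurable through `GAConfig`.

## Evaluation protocol and metrics

`strip_rebuild_protocol` removes every side-chain atom (CB included),
restores each polymer residue at its library's most frequent rotamer mean
(uniform random χ for the library-free ga_random method), repacks the
movable set around the site, and compares against the original:

- **Side-chain RMSD** per residue, heavy atoms, no superposition (the
  backbone is shared, so native and model are already in one frame);
  chemically equivalent atoms (PHE/TYR/PTR ring, ASP/GLU carboxylate, ARG
  guanidinium) are matched under the relabelling that minimises the RMSD.
- **χ-MAE** per χ index: circular |Δχ| averaged over residues, reported both
  over all residues and over the repacked set only.
- **Clashscore**: non-bonded heavy-atom pairs overlapping by strictly more
  than 0.4 Å per 1000 atoms (vdW radii in `data/vdw_radii.txt`).
- **Rotamer outliers / marginal residues**: a residue is an outlier when its
  χ deviates from the nearest library rotamer by more than 3σ (configurable)
  on any index; marginal residues are the union of outliers and residues in
  any >0.4 Å contact, with reasons recorded. A Ramachandran-based criterion
  would need external reference contours and is out of scope.

## Synthetic data

The fixture generators produce exactly what the tests need and no more:

- ideal-geometry chains (helix −57/−47, strand −119/113, extended 180/180)
  with side chains at prescribed χ and the ground truth stored alongside —
  not in — the PDB payload;
- χ ensembles from wrapped-normal mixtures with *exact* component counts
  (largest-remainder rounding, shuffled), so library-recovery tolerances
  measure estimator error rather than binomial noise; at σ ≤ 20° the wrapped
  normal is numerically indistinguishable from a von Mises for this purpose;
- clash fixtures: isolated carbon atoms on an 8 Å grid with exactly the
  requested number of overlapping pairs at the requested depth;
- packing puzzles: short serine chains on the extended backbone (whose grid
  χ values carry zero intrinsic side-chain/backbone strain) with one fixed
  dummy oxygen per penalised rotamer, placed on the CB→OG axis just beyond
  the CB interaction cutoff; placements that would graze another CB are
  skipped. The optimum over the rotamer grid is computed by exhaustive
  enumeration (bounded at 10⁴ states) and serves as the oracle for both
  packers.

What the generators do *not* emulate: crystallographic noise, B-factors,
alternate locations, missing atoms, non-ideal covalent geometry, hydrogens,
and real packing environments. Passing the recovery tests therefore
demonstrates correctness of the machinery (geometry, estimators, samplers,
optimisers) under the stated model, not predictive accuracy on experimental
structures.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale problems chosen as the package's
own defaults: 3-residue × 5-rotamer puzzles (125 states) for oracle
equivalence with 5000-step MCMC runs and population-300/40-generation GA
runs over 100 seeds; a 7-residue, 21-χ helix for the population-size trend
(populations 100–500, 10 repeats each, error measured against the best
energy found across the experiment, since no exhaustive oracle exists at
that dimensionality); 10⁵ draws for the statistical checks of the Metropolis
kernel, the von Mises sampler and the operator application rates.

Angles are degrees at the structure/library layer and radians inside the GA
chromosome; wrapping is to (−180°, 180°] / (−π, π] with −π folded to +π.
Missing χ-defining atoms yield NaN markers, never exceptions, from
`compute_chi`; rebuild refuses residues without N/CA/C. Altloc handling
keeps the highest-occupancy conformer, ties resolved toward blank/'A'.
Every stochastic routine takes a numpy `Generator` or integer seed and is
reproducible bit-for-bit; library building is invariant to input order
(wells clustering is deterministic; circular k-means is seeded from the
wells partition).

## Known limitations

- Single energy term: no electrostatics or hydrogen bonding, so polar
  contacts (e.g. phosphate salt bridges) are invisible to the optimisers.
- Backbone-independent libraries only; backbone-dependent input collapses to
  its marginal on load.
- Clashscore and marginal classification are heavy-atom variants of the
  hydrogen-aware originals.
- Proline is rebuilt as an open chain (χ1/χ2 free); ring closure is not
  enforced, matching the template-based rebuild model.
- The GA and off-rotamer MCMC explore continuous χ space but are still
  scored by sterics alone; on permissive landscapes many conformations tie
  near zero and the reported optimum is then one of several equivalents.
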