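"""Rotamer libraries: construction from coordinate sets, I/O and sampling.

A rotamer is a discrete low-energy side-chain conformation summarised by its
mean chi angles (degrees), per-chi circular standard deviations and an
observation frequency.  Libraries here are backbone-independent.  Libraries
can be built from any set of PDB-format structures for any registered residue
code — including modified residues, for which public libraries are scarce —
with every chain and every model of an input file contributing an independent
observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import circmean, circstd

from .geometry import wrap_degrees
from .structure import Structure, compute_chi
from .topology import TopologyRegistry, registry as default_registry

__all__ = [
    "Rotamer",
    "RotamerLibrary",
    "LibraryBuildConfig",
    "LibrarySet",
    "build_library",
    "collect_chi_observations",
    "save_library",
    "load_library",
    "load_dunbrack_bbind",
    "sample_rotamer",
    "nearest_rotamer",
]

SIGMA_FLOOR_DEG = 1.0  # avoids k = 1/sigma^2 blowing up for tight clusters

# well centers for sp3-like dihedrals; assignment is by nearest circular center
_WELL_CENTERS = (-60.0, 60.0, 180.0)


@dataclass(frozen=True)
class Rotamer:
    chi_mean: tuple  # degrees
    chi_sigma: tuple  # degrees, > 0
    frequency: float  # (0, 1]
    count: int = 0
    internal_energy: float | None = None  # carried through I/O, unused by packers

    def __post_init__(self):
        if len(self.chi_mean) != len(self.chi_sigma):
            raise ValueError("chi_mean and chi_sigma must have equal length")
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"frequency must be in (0, 1], got {self.frequency}")
        if any(s <= 0 for s in self.chi_sigma):
            raise ValueError("chi_sigma must be positive elementwise")

    @property
    def chi_count(self) -> int:
        return len(self.chi_mean)


@dataclass(frozen=True)
class RotamerLibrary:
    residue_code: str
    chi_count: int
    rotamers: tuple
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.rotamers:
            raise ValueError(f"empty rotamer library for {self.residue_code}")
        for r in self.rotamers:
            if r.chi_count != self.chi_count:
                raise ValueError("inconsistent chi counts in library")
        total = sum(r.frequency for r in self.rotamers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {total}")

    def __len__(self) -> int:
        return len(self.rotamers)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([r.frequency for r in self.rotamers])

    @property
    def means(self) -> np.ndarray:
        return np.array([r.chi_mean for r in self.rotamers], dtype=float)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([r.chi_sigma for r in self.rotamers], dtype=float)


@dataclass(frozen=True)
class LibraryBuildConfig:
    cluster_method: str = "wells"  # "wells" | "kmeans-circular"
    well_width: float = 120.0
    min_count: int = 3
    sigma_floor: float = SIGMA_FLOOR_DEG
    n_clusters: int | None = None  # for kmeans-circular
    resolution_cutoff: float | None = None  # caller-side filter, recorded only

    def __post_init__(self):
        if not (0 < self.well_width <= 360):
            raise ValueError("well_width must be in (0, 360]")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.cluster_method not in ("wells", "kmeans-circular"):
            raise ValueError(f"unknown cluster_method {self.cluster_method!r}")


class LibrarySet:
    """Maps residues to libraries, by residue id first, then by residue code."""

    def __init__(self, by_code: dict | None = None, by_id: dict | None = None):
        self.by_code = {k.upper(): v for k, v in (by_code or {}).items()}
        self.by_id = dict(by_id or {})

    def for_residue(self, residue) -> RotamerLibrary:
        lib = self.by_id.get(residue.id)
        if lib is None:
            lib = self.by_code.get(residue.code.upper())
        if lib is None:
            raise KeyError(
                f"no rotamer library for residue {residue.code} {residue.id}"
            )
        return lib

    def has(self, residue) -> bool:
        return residue.id in self.by_id or residue.code.upper() in self.by_code


# ---------------------------------------------------------------------------
# construction


def collect_chi_observations(structures, residue_code: str,
                             chi_definition=None,
                             reg: TopologyRegistry | None = None) -> np.ndarray:
    """Pool complete chi vectors (degrees) for a code over structures/models/chains."""
    reg = reg or default_registry()
    if chi_definition is None:
        chi_definition = reg.get(residue_code).chi
    if isinstance(structures, Structure):
        structures = [structures]
    rows = []
    for st in structures:
        for res in st.residues():  # every model is an independent entry
            if res.code.upper() != residue_code.upper():
                continue
            chi = compute_chi(res, chi_definition)
            if not np.any(np.isnan(chi)):
                rows.append(chi)
    if not rows:
        raise ValueError(f"no complete observations of residue code {residue_code!r}")
    return np.array(rows, dtype=float)


def _well_assignment(chi: np.ndarray, width: float) -> tuple:
    """Assign each chi independently to the circularly nearest well center."""
    keys = []
    for x in chi:
        devs = np.abs(wrap_degrees(x - np.array(_WELL_CENTERS)))
        j = int(np.argmin(devs))
        # angles outside every well of the given width get their own overflow bin
        if devs[j] > width / 2.0:
            keys.append(f"out{int(np.floor(x / width))}")
        else:
            keys.append(j)
    return tuple(keys)


def _circular_stats(obs: np.ndarray, sigma_floor: float):
    mean = wrap_degrees(circmean(obs, high=180.0, low=-180.0, axis=0))
    sigma = np.maximum(circstd(obs, high=180.0, low=-180.0, axis=0), sigma_floor)
    return np.atleast_1d(mean), np.atleast_1d(sigma)


def _cluster_wells(obs: np.ndarray, config: LibraryBuildConfig):
    groups: dict = {}
    for row in obs:
        groups.setdefault(_well_assignment(row, config.well_width), []).append(row)
    return [np.array(v) for v in sorted(groups.values(), key=len, reverse=True)]


def _cluster_kmeans_circular(obs: np.ndarray, config: LibraryBuildConfig):
    """Lloyd iterations on the torus; deterministic init from the wells clusters."""
    k = config.n_clusters or len(_cluster_wells(obs, config))
    k = min(k, len(obs))
    init = _cluster_wells(obs, config)[:k]
    centers = np.array([_circular_stats(g, config.sigma_floor)[0] for g in init])
    while len(centers) < k:
        centers = np.vstack([centers, obs[len(centers) % len(obs)]])
    for _ in range(100):
        dev = wrap_degrees(obs[:, None, :] - centers[None, :, :])
        assign = np.argmin(np.sum(dev ** 2, axis=-1), axis=1)
        new_centers = centers.copy()
        for j in range(len(centers)):
            members = obs[assign == j]
            if len(members):
                new_centers[j] = _circular_stats(members, config.sigma_floor)[0]
        if np.allclose(wrap_degrees(new_centers - centers), 0, atol=1e-10):
            break
        centers = new_centers
    return [obs[assign == j] for j in range(len(centers)) if np.any(assign == j)]


def build_library(structures, residue_code: str, chi_definition=None,
                  config: LibraryBuildConfig | None = None,
                  reg: TopologyRegistry | None = None) -> RotamerLibrary:
    """Build a backbone-independent rotamer library for ``residue_code``.

    Observations are pooled over all structures, chains and models, clustered
    circularly, and summarised per cluster by circular mean, circular sigma
    (floored) and frequency.  Clusters smaller than ``min_count`` are dropped
    and the remaining frequencies renormalised.
    """
    config = config or LibraryBuildConfig()
    reg = reg or default_registry()
    obs = collect_chi_observations(structures, residue_code, chi_definition, reg)
    n_total = len(obs)

    if config.cluster_method == "wells":
        clusters = _cluster_wells(obs, config)
    else:
        clusters = _cluster_kmeans_circular(obs, config)

    kept = [c for c in clusters if len(c) >= config.min_count]
    if not kept:
        kept = [max(clusters, key=len)]  # never return an empty library
    n_kept = sum(len(c) for c in kept)

    rotamers = []
    for c in kept:
        mean, sigma = _circular_stats(c, config.sigma_floor)
        rotamers.append(Rotamer(
            chi_mean=tuple(float(x) for x in mean),
            chi_sigma=tuple(float(s) for s in sigma),
            frequency=len(c) / n_kept,
            count=len(c),
        ))
    rotamers.sort(key=lambda r: (-r.frequency, r.chi_mean))
    # exact renormalisation against floating-point drift
    total = sum(r.frequency for r in rotamers)
    rotamers = [Rotamer(r.chi_mean, r.chi_sigma, r.frequency / total, r.count,
                        r.internal_energy) for r in rotamers]

    return RotamerLibrary(
        residue_code=residue_code.upper(),
        chi_count=obs.shape[1],
        rotamers=tuple(rotamers),
        provenance={
            "n_observations": n_total,
            "n_used": n_kept,
            "cluster_method": config.cluster_method,
            "min_count": config.min_count,
        },
    )


# ---------------------------------------------------------------------------
# I/O — native format


_FORMAT_VERSION = 1


def save_library(library: RotamerLibrary, path) -> None:
    lines = [f"# ptmpack rotamer library", f"VERSION {_FORMAT_VERSION}",
             f"RESIDUE {library.residue_code} {library.chi_count}"]
    for r in library.rotamers:
        fields = [str(int(r.count)), repr(float(r.frequency))]
        fields += [repr(float(x)) for x in r.chi_mean]
        fields += [repr(float(s)) for s in r.chi_sigma]
        if r.internal_energy is not None:
            fields += ["E", repr(float(r.internal_energy))]
        lines.append("ROT " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def load_library(path) -> RotamerLibrary:
    lines = [ln.split("#", 1)[0].strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines or not lines[0].startswith("VERSION"):
        raise ValueError(f"{path}: not a ptmpack rotamer library (missing VERSION)")
    version = int(lines[0].split()[1])
    if version != _FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported library format version {version}")
    if len(lines) < 2 or not lines[1].startswith("RESIDUE"):
        raise ValueError(f"{path}: truncated library (missing RESIDUE header)")
    _, code, k = lines[1].split()
    k = int(k)
    rotamers = []
    for ln in lines[2:]:
        parts = ln.split()
        if parts[0] != "ROT":
            raise ValueError(f"{path}: unexpected record {parts[0]!r}")
        body = parts[1:]
        if len(body) < 2 + 2 * k:
            raise ValueError(f"{path}: truncated rotamer record")
        energy = None
        if "E" in body:
            e_at = body.index("E")
            energy = float(body[e_at + 1])
            body = body[:e_at]
        count = int(body[0])
        freq = float(body[1])
        means = tuple(float(x) for x in body[2:2 + k])
        sigmas = tuple(float(x) for x in body[2 + k:2 + 2 * k])
        rotamers.append(Rotamer(means, sigmas, freq, count, energy))
    if not rotamers:
        raise ValueError(f"{path}: library holds no rotamers")
    return RotamerLibrary(code, k, tuple(rotamers))


def load_dunbrack_bbind(path, residue_code: str | None = None,
                        reg: TopologyRegistry | None = None) -> RotamerLibrary:
    """Read a backbone-independent Dunbrack-style text table.

    Expected whitespace columns per rotamer line::

        RES r1 r2 r3 r4 count probability chi1 chi2 chi3 chi4 sig1 sig2 sig3 sig4

    Probabilities may be percentages or fractions; they are renormalised.
    Unused trailing chi/sigma columns (beyond the residue's chi count) are
    ignored; lines for other residue codes are skipped when ``residue_code``
    is given, otherwise the first code encountered is used.
    """
    reg = reg or default_registry()
    rotamers = []
    code = residue_code.upper() if residue_code else None
    k = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        this_code = parts[0].upper()
        if code is None:
            code = this_code
        if this_code != code:
            continue
        if k is None:
            k = reg.get(code).chi_count if code in reg else 4
        vals = parts[5:]
        if len(vals) < 2 + 2 * 4:
            raise ValueError(f"{path}:{ln}: expected count, probability and 4+4 chi columns")
        count = int(float(vals[0]))
        prob = float(vals[1])
        means = tuple(float(x) for x in vals[2:2 + k])
        sigmas = tuple(max(float(x), SIGMA_FLOOR_DEG) for x in vals[6:6 + k])
        rotamers.append((count, prob, means, sigmas))
    if not rotamers:
        raise ValueError(f"{path}: no rotamer lines for residue code {code!r}")
    total = sum(p for _, p, _, _ in rotamers)
    rots = tuple(
        Rotamer(m, s, p / total, c) for c, p, m, s in rotamers
    )
    return RotamerLibrary(code, len(rots[0].chi_mean), rots,
                          provenance={"source": "dunbrack-bbind"})


# ---------------------------------------------------------------------------
# queries


def sample_rotamer(library: RotamerLibrary, rng: np.random.Generator) -> Rotamer:
    """Draw a rotamer with probability equal to its frequency."""
    idx = rng.choice(len(library.rotamers), p=library.frequencies)
    return library.rotamers[int(idx)]


def nearest_rotamer(chi_vector, library: RotamerLibrary):
    """Rotamer minimising the max circular deviation over chi indices.

    Returns ``(rotamer, max_abs_circular_deviation_degrees)``.
    """
    chi = np.atleast_1d(np.asarray(chi_vector, dtype=float))
    if chi.size != library.chi_count:
        raise ValueError(
            f"chi vector length {chi.size} != library chi_count {library.chi_count}"
        )
    devs = np.abs(wrap_degrees(chi[None, :] - library.means))
    worst = devs.max(axis=1)
    best = int(np.argmin(worst))
    return library.rotamers[best], float(worst[best])
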