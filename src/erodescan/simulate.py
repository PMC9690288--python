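"""Synthetic diploid cohorts with planted IBD tracts and a truth ledger.

The generator emulates the data the pipeline is built for: multi-scaffold
diploid genotype matrices in which each individual carries planted runs of
homozygosity of known coalescence-age class, a background per-site
heterozygosity theta_bg, impact-annotated deleterious sites whose genotype
frequencies follow an inbreeding coefficient F, and per-site read profiles
with Poisson depth and per-read error epsilon.  Every artifact is
reproducible from one seed, and a :class:`SimTruth` ledger records exactly
what was planted so downstream stages have recovery oracles.

Tract lengths for a bin of representative age ``g`` follow the standard
coalescent expectation for IBD tracts: Exponential with mean 100/(2 r g) Mb,
truncated to the bin's length range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .matrix import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, SampleMetadata
from .roh import AgeModel, length_of_age

__all__ = [
    "PopulationSim",
    "SimConfig",
    "SimTruth",
    "Tract",
    "draw_tract_lengths",
    "plant_roh",
    "simulate_population",
    "simulate_read_profiles",
]

IMPACT_CATEGORIES = ("LOW", "MODERATE", "HIGH")
_NUCS = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Raised when simulation targets are infeasible on the given layout."""


@dataclass(frozen=True)
class Tract:
    """One planted IBD tract (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    bin_label: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PopulationSim:
    """Per-population simulation settings.

    ``froh_targets`` are the fractions of the analyzable genome to plant as
    IBD tracts in each age bin (historical, intermediate, recent).
    ``f_load`` is the inbreeding coefficient governing genotype frequencies
    at deleterious sites: P(hom alt) = p^2 + F p q, P(het) = 2 p q (1 - F).
    """

    name: str
    n: int
    theta_bg: float = 0.25
    froh_targets: tuple[float, float, float] = (0.0, 0.0, 0.0)
    f_load: float = 0.0
    depth_mean: float = 25.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if not 0 <= self.theta_bg < 1:
            raise ConfigurationError("theta_bg must be in [0, 1)")
        if sum(self.froh_targets) > 1:
            raise ConfigurationError("per-bin F targets must sum to <= 1")
        if not 0 <= self.f_load <= 1:
            raise ConfigurationError("f_load must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigurationError("error_rate must be in [0, 0.5)")


@dataclass
class SimConfig:
    """Cohort-level simulation settings shared across populations.

    ``bin_ages`` are representative coalescence ages (generations) for the
    historical / intermediate / recent bins; tract lengths are Exponential
    with mean 100/(2 r g) Mb truncated to the bin's length range.  Default
    ages sit inside each bin's age range rather than at its edges.
    ``deleterious`` maps impact category to (site count, alt allele
    frequency).  ``n_structure_sites`` background sites receive
    Hardy–Weinberg genotypes from population-specific allele frequencies
    drawn by a Balding–Nichols model with divergence ``structure_fst``,
    planting detectable population structure for PCA.
    """

    layout: GenomeLayout
    populations: list[PopulationSim]
    age_model: AgeModel = field(default_factory=AgeModel)
    bin_ages: tuple[float, float, float] = (150.0, 25.0, 10.0)
    snp_spacing_bp: float = 1000.0
    deleterious: dict[str, tuple[int, float]] = field(default_factory=dict)
    n_structure_sites: int = 0
    structure_fst: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snp_spacing_bp < 1:
            raise ConfigurationError("snp_spacing_bp must be >= 1")
        for cat, (m, p) in self.deleterious.items():
            if cat not in IMPACT_CATEGORIES:
                raise ConfigurationError(f"unknown impact category {cat!r}")
            if m < 0 or not 0 < p < 1:
                raise ConfigurationError("deleterious counts/frequencies invalid")
        if not 0 < self.structure_fst < 1 and self.n_structure_sites:
            raise ConfigurationError("structure_fst must be in (0, 1)")


@dataclass
class SimTruth:
    """Ledger of everything planted — the recovery-test oracle."""

    samples: list[str]
    population: dict[str, str]
    tracts: dict[str, list[Tract]]
    froh: dict[str, dict[str, float]]
    theta_bg: dict[str, float]
    error_rate: dict[str, float]
    f_load: dict[str, float]
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "samples": self.samples,
            "population": self.population,
            "theta_bg": self.theta_bg,
            "error_rate": self.error_rate,
            "f_load": self.f_load,
            "froh": self.froh,
            "tracts": {
                s: [[t.scaffold, t.start, t.end, t.bin_label] for t in ts]
                for s, ts in self.tracts.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        tracts = {s: [Tract(*t[:3], bin_label=t[3]) for t in ts]
                  for s, ts in d["tracts"].items()}
        return cls(samples=d["samples"], population=d["population"],
                   tracts=tracts, froh=d["froh"], theta_bg=d["theta_bg"],
                   error_rate=d["error_rate"], f_load=d["f_load"], seed=d["seed"])


def draw_tract_lengths(
    g: float,
    r: float,
    n: int,
    rng: np.random.Generator,
    bounds_mb: tuple[float, float] | None = None,
) -> np.ndarray:
    """Draw IBD tract lengths (Mb): Exponential with mean 100/(2 r g),
    truncated to ``bounds_mb`` via the inverse CDF when given."""
    mean = length_of_age(g, r)
    if bounds_mb is None:
        return rng.exponential(mean, size=n)
    lo, hi = bounds_mb
    u = rng.random(n)
    c_lo = np.exp(-lo / mean)
    c_hi = 0.0 if np.isinf(hi) else np.exp(-hi / mean)
    return -mean * np.log(c_lo - u * (c_lo - c_hi))


def _draw_bin_lengths_to_target(
    target_bp: float, g: float, r: float, bounds_mb: tuple[float, float],
    rng: np.random.Generator, tol: float = 0.10,
) -> list[int]:
    """Tract lengths (bp) for one bin whose sum lies within ±tol of target."""
    lo_bp, hi_bp = target_bp * (1 - tol), target_bp * (1 + tol)
    for _ in range(500):
        lengths: list[int] = []
        total = 0.0
        for _ in range(200):
            if total >= lo_bp:
                break
            cand = float(draw_tract_lengths(g, r, 1, rng, bounds_mb)[0]) * 1e6
            if total + cand <= hi_bp:
                lengths.append(int(round(cand)))
                total += cand
        if lo_bp <= total <= hi_bp:
            return lengths
    raise ConfigurationError(
        f"could not assemble tract lengths summing to {target_bp:.0f} bp "
        f"within ±{tol:.0%} for bin age g={g}")


def plant_roh(
    layout: GenomeLayout,
    targets: tuple[float, float, float],
    ages: tuple[float, float, float],
    r: float,
    rng: np.random.Generator,
    age_model: AgeModel = AgeModel(),
    tol: float = 0.10,
    edge_margin_mb: float = 0.05,
    min_separation_bp: int = 100_000,
) -> list[Tract]:
    """Plant non-overlapping tracts on the unmasked genome.

    ``targets`` are per-bin fractions of the analyzable length; the planted
    per-bin fraction lands within ±tol relative of each non-zero target.
    Lengths are drawn ``edge_margin_mb`` inside the bin's range so every
    planted tract has an unambiguous age class even after caller boundary
    error, and tracts are separated by at least ``min_separation_bp`` so
    distinct planted tracts cannot fuse into one called segment.
    """
    analyzable = layout.analyzable_length
    if analyzable <= 0:
        raise ConfigurationError("layout has no analyzable sequence")
    if sum(targets) > 0.9:
        raise ConfigurationError("total planted fraction must be <= 0.9")

    # draw lengths per bin, then place longest-first on free intervals
    drawn: list[tuple[int, int]] = []  # (length_bp, bin index)
    for b, (target, g) in enumerate(zip(targets, ages)):
        if target <= 0:
            continue
        lo, hi = age_model.bin_edges_mb[b], age_model.bin_edges_mb[b + 1]
        lo += edge_margin_mb
        if np.isfinite(hi):
            hi -= edge_margin_mb
        for L in _draw_bin_lengths_to_target(target * analyzable, g, r,
                                             (lo, hi), rng, tol):
            drawn.append((L, b))
    drawn.sort(reverse=True)

    free: list[tuple[str, int, int]] = []
    for name, _ in layout.analyzable_scaffolds():
        for s, e in layout.analyzable_intervals(name):
            free.append((name, int(s), int(e)))

    tracts: list[Tract] = []
    for length, b in drawn:
        spans = np.array([max(0, e - s - length + 1) for _, s, e in free])
        if spans.sum() == 0:
            raise ConfigurationError(
                f"no free interval can hold a {length} bp tract")
        k = rng.choice(len(free), p=spans / spans.sum())
        name, s, e = free.pop(k)
        start = int(s + rng.integers(0, e - s - length + 1))
        tracts.append(Tract(name, start, start + length,
                            age_model.bin_labels[b]))
        if start - min_separation_bp > s:
            free.append((name, s, start - min_separation_bp))
        if start + length + min_separation_bp < e:
            free.append((name, start + length + min_separation_bp, e))
    tracts.sort(key=lambda t: (t.scaffold, t.start))
    return tracts


def _site_positions(layout: GenomeLayout, spacing: float,
                    rng: np.random.Generator) -> list[tuple[str, np.ndarray]]:
    """Geometric inter-site gaps with the configured mean, per scaffold."""
    out = []
    p = min(1.0, 1.0 / spacing)
    for name, length in layout.analyzable_scaffolds():
        est = int(length / spacing * 1.3) + 100
        gaps = rng.geometric(p, size=est)
        pos = np.cumsum(gaps)
        while pos[-1] < length:  # rare shortfall: extend
            extra = rng.geometric(p, size=est)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        pos = pos[pos <= length]
        out.append((name, pos.astype(np.int64)))  # 1-based
    return out


def simulate_population(config: SimConfig):
    """Generate a cohort: (GenotypeMatrix, impact table, SimTruth).

    Outside planted tracts each site is HET with probability theta_bg (else
    HOM_REF); inside tracts sites are homozygous, HOM_ALT with probability
    1/2.  Deleterious and structure sites follow their own genotype models
    (independent of tracts).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    analyzable = layout.analyzable_length

    per_scaffold = _site_positions(layout, config.snp_spacing_bp, rng)
    scaff_names = np.concatenate([np.repeat(n, len(p)) for n, p in per_scaffold]) \
        if per_scaffold else np.array([], dtype=object)
    positions = np.concatenate([p for _, p in per_scaffold]) \
        if per_scaffold else np.array([], dtype=np.int64)
    n_sites = positions.size

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame({
        "scaffold": scaff_names, "pos": positions,
        "ref": _NUCS[ref_idx], "alt": _NUCS[alt_idx],
        "qual": np.full(n_sites, 60.0),
    })

    # special-site designation: deleterious categories, then structure sites
    category = np.full(n_sites, "", dtype=object)
    n_special = sum(m for m, _ in config.deleterious.values()) + config.n_structure_sites
    if n_special > n_sites:
        raise ConfigurationError("more special sites requested than sites simulated")
    special = rng.choice(n_sites, size=n_special, replace=False)
    offset = 0
    del_freq: dict[str, float] = {}
    for cat in IMPACT_CATEGORIES:
        if cat not in config.deleterious:
            continue
        m, p = config.deleterious[cat]
        category[special[offset:offset + m]] = cat
        del_freq[cat] = p
        offset += m
    structure_idx = special[offset:]
    is_deleterious = category != ""

    # population-specific allele frequencies at structure sites (Balding–Nichols)
    anc = rng.uniform(0.1, 0.9, size=structure_idx.size)
    fst = config.structure_fst
    pop_freq = {}
    for pop in config.populations:
        if structure_idx.size and fst > 0:
            a = anc * (1 - fst) / fst
            b = (1 - anc) * (1 - fst) / fst
            pop_freq[pop.name] = rng.beta(a, b)
        else:
            pop_freq[pop.name] = anc

    samples: list[str] = []
    pop_of: dict[str, str] = {}
    calls_rows, depth_rows = [], []
    tracts_by: dict[str, list[Tract]] = {}
    froh_by: dict[str, dict[str, float]] = {}
    theta_by, eps_by, fload_by = {}, {}, {}
    meta_rows = []

    pos_by_scaffold = {n: p for n, p in per_scaffold}
    site_offset = {}
    off = 0
    for n, p in per_scaffold:
        site_offset[n] = off
        off += len(p)

    for pop in config.populations:
        q = pop_freq[pop.name]
        for i in range(pop.n):
            sample = f"{pop.name}_{i:02d}"
            samples.append(sample)
            pop_of[sample] = pop.name
            theta_by[sample] = pop.theta_bg
            eps_by[sample] = pop.error_rate
            fload_by[sample] = pop.f_load
            meta_rows.append({"sample": sample, "population": pop.name,
                              "year": 2019, "mean_coverage": pop.depth_mean})

            tracts = plant_roh(layout, pop.froh_targets, config.bin_ages,
                               config.age_model.r, rng, config.age_model) \
                if any(t > 0 for t in pop.froh_targets) else []
            tracts_by[sample] = tracts
            fr_bp = {label: 0 for label in config.age_model.bin_labels}
            for t in tracts:
                fr_bp[t.bin_label] += t.length
            froh_by[sample] = {k: v / analyzable for k, v in fr_bp.items()}

            calls = np.full(n_sites, HOM_REF, dtype=np.int8)
            if pop.theta_bg > 0:
                calls[rng.random(n_sites) < pop.theta_bg] = HET
            # planted tracts: perfectly homozygous, allele label 50:50
            in_tract = np.zeros(n_sites, dtype=bool)
            for t in tracts:
                p_arr = pos_by_scaffold[t.scaffold]
                a = np.searchsorted(p_arr, t.start + 1, side="left")
                b = np.searchsorted(p_arr, t.end, side="right")
                in_tract[site_offset[t.scaffold] + a:
                         site_offset[t.scaffold] + b] = True
            n_in = int(in_tract.sum())
            hom = np.where(rng.random(n_in) < 0.5, HOM_ALT, HOM_REF).astype(np.int8)
            calls[in_tract] = hom
            # deleterious sites: genotype frequencies under F_load
            for cat, p in del_freq.items():
                idx = np.flatnonzero(category == cat)
                pq = p * (1 - p)
                p_hom = p * p + pop.f_load * pq
                p_het = 2 * pq * (1 - pop.f_load)
                u = rng.random(idx.size)
                g = np.full(idx.size, HOM_REF, dtype=np.int8)
                g[u < p_hom + p_het] = HET
                g[u < p_hom] = HOM_ALT
                calls[idx] = g
            # structure sites: Hardy–Weinberg from population frequency
            if structure_idx.size:
                dosage = rng.binomial(2, q)
                calls[structure_idx] = np.array(
                    [HOM_REF, HET, HOM_ALT], dtype=np.int8)[dosage]
            calls_rows.append(calls)
            depth_rows.append(rng.poisson(pop.depth_mean, size=n_sites)
                              .astype(np.int32))

    matrix = GenotypeMatrix(
        sites=sites,
        calls=np.stack(calls_rows) if calls_rows else np.empty((0, n_sites), np.int8),
        depth=np.stack(depth_rows) if depth_rows else np.empty((0, n_sites), np.int32),
        samples=samples,
    )
    impact = sites.loc[is_deleterious, ["scaffold", "pos", "ref", "alt"]].copy()
    impact["category"] = category[is_deleterious]
    impact = impact.reset_index(drop=True)
    truth = SimTruth(samples=samples, population=pop_of, tracts=tracts_by,
                     froh=froh_by, theta_bg=theta_by, error_rate=eps_by,
                     f_load=fload_by, seed=config.seed)
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    return matrix, impact, truth, metadata


def simulate_read_profiles(
    calls: np.ndarray,
    depth_mean: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-site (ref, alt) read counts for one individual's genotype vector.

    Depth is Poisson(depth_mean).  Homozygous sites report the true allele
    with probability 1 - error_rate per read; at heterozygous sites each
    read picks one allele 50:50 and then errs with probability error_rate
    (net alt probability exactly 1/2).  Missing genotypes get depth 0.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    calls = np.asarray(calls)
    n = calls.size
    depth = rng.poisson(depth_mean, size=n)
    depth[calls == MISSING] = 0
    p_alt = np.full(n, error_rate)
    p_alt[calls == HET] = 0.5
    p_alt[calls == HOM_ALT] = 1 - error_rate
    alt = rng.binomial(depth, p_alt)
    return np.stack([depth - alt, alt], axis=1)
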