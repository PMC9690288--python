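"""Runs of homozygosity: sliding-window detection, F_ROH and ROH-length dating.

The caller reproduces the PLINK-style ``--homozyg`` procedure: windows of a
fixed number of consecutive SNPs are classified homozygous when they contain
at most a few heterozygous (and missing) calls; a SNP is inside a homozygous
segment when at least a threshold fraction of the windows covering it are
homozygous; maximal runs of such SNPs become ROH after segment-level SNP
count, physical length, density and gap rules.

A ROH of length L Mb is dated to g = 100 / (2 r L) generations back to the
common ancestor of the two haplotypes, with r the recombination rate in
cM/Mb.  F_ROH is the fraction of the analyzable genome covered by ROH, and
is decomposed by tract length into coalescence-age bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .matrix import HET, MISSING, GenotypeMatrix

__all__ = [
    "ROHParams",
    "ROHSegment",
    "AgeModel",
    "FrohResult",
    "window_hit_fractions",
    "call_roh",
    "call_roh_matrix",
    "age_of_length",
    "length_of_age",
    "froh",
    "segments_to_frame",
]


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window and segment rules (PLINK ``--homozyg`` vocabulary)."""

    window_snp: int = 200           # SNPs per sliding window
    window_het_max: int = 3         # max HET calls for a homozygous window
    window_missing_max: int = 5     # max MISSING calls for a homozygous window
    hit_threshold: float = 0.05     # min fraction of homozygous windows per SNP
    seg_min_snp: int = 100          # min SNPs per segment
    seg_min_kb: float = 100.0       # min physical segment length
    density_kb_per_snp: float = 50.0  # max kb per SNP inside a segment
    gap_max_kb: float = 1000.0      # max gap between neighbouring segment SNPs

    def __post_init__(self) -> None:
        if min(self.window_snp, self.seg_min_snp) <= 0:
            raise ValueError("SNP counts must be positive")
        if not 0 < self.hit_threshold <= 1:
            raise ValueError("hit_threshold must be in (0, 1]")
        if min(self.window_het_max, self.window_missing_max) < 0:
            raise ValueError("window tolerances must be >= 0")


@dataclass(frozen=True)
class ROHSegment:
    """One called run of homozygosity (0-based half-open extent)."""

    individual: str
    scaffold: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return self.length / 1e6


@dataclass(frozen=True)
class AgeModel:
    """Maps ROH length to generations since coalescence.

    Default bins (Mb): (0.1, 2] historical, (2, 8] intermediate, (8, inf)
    recent, matching ~850 / ~45 / ~10 generations at r = 0.6 cM/Mb.
    """

    r: float = 0.6                      # recombination rate, cM per Mb
    generation_time: float = 2.0        # years per generation
    bin_edges_mb: tuple[float, ...] = (0.1, 2.0, 8.0, float("inf"))
    bin_labels: tuple[str, ...] = ("historical", "intermediate", "recent")

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("recombination rate must be positive")
        edges = np.asarray(self.bin_edges_mb)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.bin_labels) != len(self.bin_edges_mb) - 1:
            raise ValueError("need one label per bin")

    @property
    def n_bins(self) -> int:
        return len(self.bin_labels)

    def bin_of_length(self, length_mb: float) -> int:
        """Index of the left-open bin (e_i, e_{i+1}] containing a length;
        -1 for lengths at or below the first edge."""
        edges = self.bin_edges_mb
        for i in range(self.n_bins):
            if edges[i] < length_mb <= edges[i + 1]:
                return i
        return -1

    def bin_age_range(self, i: int) -> tuple[float, float]:
        """(youngest, oldest) generations for bin i."""
        lo, hi = self.bin_edges_mb[i], self.bin_edges_mb[i + 1]
        young = 0.0 if np.isinf(hi) else age_of_length(hi, self.r)
        return young, age_of_length(lo, self.r)


def age_of_length(length_mb: float, r: float = 0.6) -> float:
    """Expected generations to the common ancestor of a ROH: g = 100/(2 r L)."""
    if length_mb <= 0 or r <= 0:
        raise ValueError("length and recombination rate must be positive")
    return 100.0 / (2.0 * r * length_mb)


def length_of_age(g: float, r: float = 0.6) -> float:
    """Expected ROH length (Mb) for coalescence g generations back: 100/(2 r g)."""
    if g <= 0 or r <= 0:
        raise ValueError("age and recombination rate must be positive")
    return 100.0 / (2.0 * r * g)


def window_hit_fractions(calls: np.ndarray, params: ROHParams = ROHParams()) -> np.ndarray:
    """Per-SNP fraction of covering windows classified as homozygous.

    Windows are runs of ``window_snp`` consecutive SNPs fully inside the
    scaffold's SNP list.  A scaffold with fewer SNPs than one window is
    evaluated against a single truncated window covering all its SNPs.
    """
    calls = np.asarray(calls)
    n = calls.size
    if n == 0:
        return np.zeros(0)
    het = (calls == HET).astype(np.int64)
    miss = (calls == MISSING).astype(np.int64)
    w = params.window_snp
    if n < w:
        ok = het.sum() <= params.window_het_max and miss.sum() <= params.window_missing_max
        return np.full(n, 1.0 if ok else 0.0)

    csum_het = np.concatenate([[0], np.cumsum(het)])
    csum_miss = np.concatenate([[0], np.cumsum(miss)])
    win_het = csum_het[w:] - csum_het[:-w]          # window starting at i
    win_miss = csum_miss[w:] - csum_miss[:-w]
    hom = ((win_het <= params.window_het_max)
           & (win_miss <= params.window_missing_max)).astype(np.int64)
    n_win = hom.size  # == n - w + 1

    csum_hom = np.concatenate([[0], np.cumsum(hom)])
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    count = csum_hom[hi + 1] - csum_hom[lo]
    denom = hi - lo + 1
    return count / denom


def call_roh(
    calls: np.ndarray,
    positions: np.ndarray,
    scaffold: str,
    individual: str = "",
    params: ROHParams = ROHParams(),
) -> list[ROHSegment]:
    """Call ROH on one individual's genotypes along one scaffold.

    ``positions`` are 1-based and strictly increasing.  Returns sorted,
    non-overlapping segments whose extent is first to last member SNP.
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=np.int64)
    if calls.size != positions.size:
        raise ValueError("calls and positions must align")
    frac = window_hit_fractions(calls, params)
    in_run = frac >= params.hit_threshold
    if not in_run.any():
        return []

    # maximal runs of consecutive qualifying SNPs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], in_run.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]  # half-open index runs

    gap_bp = params.gap_max_kb * 1000.0
    segments: list[ROHSegment] = []
    for a, b in zip(starts, ends):
        # split at inter-SNP gaps wider than gap_max
        idx = np.arange(a, b)
        gaps = np.diff(positions[idx])
        cut = np.flatnonzero(gaps > gap_bp)
        pieces = np.split(idx, cut + 1)
        for piece in pieces:
            n_snps = piece.size
            p_first, p_last = positions[piece[0]], positions[piece[-1]]
            start, end = int(p_first - 1), int(p_last)  # 0-based half-open
            length = end - start
            if n_snps < params.seg_min_snp:
                continue
            if length < params.seg_min_kb * 1000.0:
                continue
            if n_snps * params.density_kb_per_snp * 1000.0 < length:
                continue
            segments.append(ROHSegment(individual, scaffold, start, end, int(n_snps)))
    return segments


def call_roh_matrix(
    matrix: GenotypeMatrix,
    layout: GenomeLayout,
    params: ROHParams = ROHParams(),
) -> dict[str, list[ROHSegment]]:
    """Call ROH for every individual across all analyzable scaffolds."""
    out: dict[str, list[ROHSegment]] = {s: [] for s in matrix.samples}
    for scaffold, idx in matrix.scaffold_slices():
        if not layout.is_analyzable(scaffold):
            continue
        positions = matrix.sites["pos"].to_numpy()[idx]
        for i, sample in enumerate(matrix.samples):
            out[sample].extend(
                call_roh(matrix.calls[i, idx], positions, scaffold, sample, params)
            )
    return out


@dataclass
class FrohResult:
    """Per-individual genomic inbreeding coefficient, decomposed by age bin."""

    individual: str
    total: float
    per_bin: dict[str, float]
    denominator_bp: int

    def as_row(self) -> dict:
        row = {"individual": self.individual, "froh_total": self.total,
               "denominator_bp": self.denominator_bp}
        row.update({f"froh_{k}": v for k, v in self.per_bin.items()})
        return row


def froh(
    segments: list[ROHSegment],
    layout: GenomeLayout,
    age_model: AgeModel = AgeModel(),
    individual: str | None = None,
) -> FrohResult:
    """F_ROH = summed ROH length / analyzable genome length, split by length bin.

    The per-bin values partition the total exactly: segments are assigned to
    left-open length bins (0.1–2], (2–8], (8–inf) Mb by default.
    """
    denom = layout.analyzable_length
    if denom <= 0:
        raise ValueError("layout has zero analyzable length")
    bins = {label: 0 for label in age_model.bin_labels}
    for seg in segments:
        i = age_model.bin_of_length(seg.length_mb)
        if i >= 0:
            bins[age_model.bin_labels[i]] += seg.length
    per_bin = {k: v / denom for k, v in bins.items()}
    name = individual if individual is not None else (
        segments[0].individual if segments else "")
    return FrohResult(individual=name, total=sum(per_bin.values()),
                      per_bin=per_bin, denominator_bp=denom)


def segments_to_frame(
    segments_by_individual: dict[str, list[ROHSegment]],
    age_model: AgeModel = AgeModel(),
) -> pd.DataFrame:
    """Flatten called segments into a table with age annotations."""
    rows = []
    for sample, segs in segments_by_individual.items():
        for s in segs:
            i = age_model.bin_of_length(s.length_mb)
            rows.append({
                "individual": sample, "scaffold": s.scaffold,
                "start": s.start, "end": s.end, "n_snps": s.n_snps,
                "length_kb": s.length / 1000.0,
                "age_bin": age_model.bin_labels[i] if i >= 0 else "sub_threshold",
                "g_estimate": age_of_length(s.length_mb, age_model.r),
            })
    return pd.DataFrame(rows, columns=[
        "individual", "scaffold", "start", "end", "n_snps",
        "length_kb", "age_bin", "g_estimate"])
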