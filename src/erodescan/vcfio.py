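"""Readers/writers for the formats the pipeline consumes and emits.

VCF is read through cyvcf2; writing uses a plain-text emitter restricted to
the GT:DP dialect the pipeline needs.  BED is 3-column, 0-based half-open.
The 1-based/0-based shift between VCF and internal coordinates happens here
and nowhere else.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .layout import GenomeLayout, merge_intervals
from .matrix import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, SampleMetadata

log = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_layout",
    "read_metadata",
    "read_impact_table",
]

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
# cyvcf2 gt_types with gts012=True: 0 HOM_REF, 1 HET, 2 HOM_ALT, 3 unknown
_FROM_CYVCF2 = np.array([HOM_REF, HET, HOM_ALT, MISSING], dtype=np.int8)


def read_vcf(path, layout: GenomeLayout) -> GenotypeMatrix:
    """Parse a VCF v4.2 into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained as sites.  Indel positions are
    registered separately (they drive proximity filtering); multiallelic
    SNPs are dropped and counted.  Records on scaffolds absent from
    ``layout`` are dropped and counted.
    """
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    known = set(layout.scaffold_lengths)
    samples = list(vcf.samples)
    rows, call_cols, depth_cols, indel_rows = [], [], [], []
    n_off_layout = n_multiallelic = 0

    for var in vcf:
        if var.CHROM not in known:
            n_off_layout += 1
            continue
        if var.is_indel or len(var.REF) != 1 or any(len(a) != 1 for a in var.ALT):
            indel_rows.append((var.CHROM, var.POS))
            continue
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0],
                     0.0 if var.QUAL is None else float(var.QUAL)))
        call_cols.append(_FROM_CYVCF2[np.asarray(var.gt_types, dtype=np.int64)])
        dp = var.format("DP")
        if dp is None:
            depth_cols.append(np.zeros(len(samples), dtype=np.int32))
        else:
            dp = np.asarray(dp, dtype=np.int64).reshape(-1)
            dp[dp < 0] = 0  # cyvcf2 encodes missing DP as a large negative int
            depth_cols.append(dp.astype(np.int32))
    vcf.close()

    if n_off_layout:
        log.info("read_vcf: dropped %d records on scaffolds absent from layout",
                 n_off_layout)
    if n_multiallelic:
        log.info("read_vcf: dropped %d multiallelic SNP records", n_multiallelic)

    sites = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt", "qual"])
    n = len(samples)
    calls = (np.stack(call_cols, axis=1) if call_cols
             else np.empty((n, 0), dtype=np.int8))
    depth = (np.stack(depth_cols, axis=1) if depth_cols
             else np.empty((n, 0), dtype=np.int32))
    indels = pd.DataFrame(indel_rows, columns=["scaffold", "pos"])
    return GenotypeMatrix(sites=sites, calls=calls, depth=depth,
                          samples=samples, indels=indels)


def write_vcf(matrix: GenotypeMatrix, path, layout: GenomeLayout | None = None) -> None:
    """Write a GT:DP VCF v4.2; ``read_vcf(write_vcf(m))`` is the identity on
    calls, depths and site fields."""
    scaffolds = (layout.scaffolds if layout is not None
                 else [(s, int(matrix.sites.loc[matrix.sites.scaffold == s, "pos"].max()))
                       for s in matrix.sites["scaffold"].unique()])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=erodescan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for name, length in scaffolds:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        sites = matrix.sites
        for j in range(matrix.n_sites):
            row = sites.iloc[j]
            geno = "\t".join(
                f"{_GT_STR[int(matrix.calls[i, j])]}:{int(matrix.depth[i, j])}"
                for i in range(matrix.n_samples)
            )
            fh.write(f"{row.scaffold}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t"
                     f"{row.qual:g}\t.\t.\tGT:DP\t{geno}\n")


def read_bed(path) -> dict[str, np.ndarray]:
    """Read a 3-column BED into merged 0-based half-open intervals per scaffold."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 BED columns")
            scaffold, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: BED end {end} <= start {start}")
            out.setdefault(scaffold, []).append((start, end))
    return {s: merge_intervals(np.asarray(iv)) for s, iv in out.items()}


def write_bed(intervals: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for scaffold, ivals in intervals.items():
            for s, e in np.asarray(ivals).reshape(-1, 2):
                fh.write(f"{scaffold}\t{int(s)}\t{int(e)}\n")


def read_layout(genome_path, mask_path=None, min_scaffold_bp: int = 25_000) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from a two-column ``scaffold<TAB>length``
    genome file plus an optional BED mask."""
    scaffolds = []
    with open(genome_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{genome_path}:{ln}: expected scaffold<TAB>length")
            scaffolds.append((parts[0], int(parts[1])))
    masked = read_bed(mask_path) if mask_path else {}
    masked = {s: iv for s, iv in masked.items() if s in dict(scaffolds)}
    return GenomeLayout(scaffolds=tuple(scaffolds), masked=masked,
                        min_scaffold_bp=min_scaffold_bp)


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))


def read_impact_table(path) -> pd.DataFrame:
    """TSV ``scaffold, pos, ref, alt, category`` with category in
    {LOW, MODERATE, HIGH} — a flattened snpEff/VEP-style export."""
    df = pd.read_csv(path, sep="\t")
    required = {"scaffold", "pos", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"impact table needs columns {sorted(required)}")
    bad = set(df["category"].unique()) - {"LOW", "MODERATE", "HIGH"}
    if bad:
        raise ValueError(f"unknown impact categories: {sorted(bad)}")
    return df
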