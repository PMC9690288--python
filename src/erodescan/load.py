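"""Mutational-load proportions stratified by zygosity and impact category.

Variants annotated LOW (synonymous), MODERATE (missense) or HIGH (loss of
function) are intersected with the genotype matrix; for each individual the
number of homozygous-alt and heterozygous genotypes in each category is
divided by one shared denominator, twice the number of annotated sites
genotyped in that individual (all categories pooled).  The pooled
denominator keeps proportions comparable across categories and individuals;
it is recorded on every output row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import HET, HOM_ALT, MISSING, GenotypeMatrix

__all__ = ["load_proportions"]

CATEGORIES = ("LOW", "MODERATE", "HIGH")


def load_proportions(matrix: GenotypeMatrix, impact: pd.DataFrame) -> pd.DataFrame:
    """Per-individual, per-category zygosity proportions of annotated variants.

    Returns a table with columns ``individual, category, n_hom, n_het,
    denominator, hom_prop, het_prop``.  The alt allele is taken as the
    deleterious allele (annotations are alt-specific).
    """
    key = pd.MultiIndex.from_frame(matrix.sites[["scaffold", "pos"]])
    ann = impact.set_index(["scaffold", "pos"])
    hit = key.isin(ann.index)
    if not hit.any():
        raise ValueError("no annotated site overlaps the genotype matrix")
    idx = np.flatnonzero(hit)
    cats = ann.loc[key[idx], "category"].to_numpy()

    rows = []
    for i, sample in enumerate(matrix.samples):
        calls = matrix.calls[i, idx]
        genotyped = calls != MISSING
        denominator = 2 * int(genotyped.sum())
        for cat in CATEGORIES:
            sel = (cats == cat) & genotyped
            n_hom = int((calls[sel] == HOM_ALT).sum())
            n_het = int((calls[sel] == HET).sum())
            rows.append({
                "individual": sample, "category": cat,
                "n_hom": n_hom, "n_het": n_het, "denominator": denominator,
                "hom_prop": n_hom / denominator if denominator else 0.0,
                "het_prop": n_het / denominator if denominator else 0.0,
            })
    return pd.DataFrame(rows)
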