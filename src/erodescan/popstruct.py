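"""Population structure (variance-standardized GRM + PCA) and rank tests.

The genomic relationship matrix standardizes alt-allele dosages per site to
(d - 2p)/sqrt(2p(1-p)) with p the sample allele frequency, and averages the
outer products over sites; its eigendecomposition yields the principal
components of population stratification.  Group comparisons use the
tie-corrected Kruskal–Wallis H test with Dunn's rank-sum post hoc z tests
and Holm (default) or Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

__all__ = [
    "PCAResult",
    "GroupTestResult",
    "dosage_matrix",
    "standardized_grm",
    "pca",
    "kruskal_wallis",
    "dunn_posthoc",
]


def dosage_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Alt-allele dosages in {0, 1, 2}; requires a complete (filtered) matrix."""
    if np.any(matrix.calls == MISSING):
        raise ValueError("dosage matrix requires complete genotyping; filter first")
    lut = np.zeros(3, dtype=np.float64)
    lut[HOM_REF], lut[HET], lut[HOM_ALT] = 0.0, 1.0, 2.0
    return lut[matrix.calls]


def standardized_grm(dosage: np.ndarray, drop_monomorphic: bool = True) -> np.ndarray:
    """Variance-standardized genomic relationship matrix from an
    ``(n_samples, n_sites)`` dosage array."""
    d = np.asarray(dosage, dtype=np.float64)
    p = d.mean(axis=0) / 2.0
    if drop_monomorphic:
        keep = (p > 0) & (p < 1)
        d, p = d[:, keep], p[keep]
    if np.any((p <= 0) | (p >= 1)):
        raise AssertionError("monomorphic site reached standardization")
    if d.shape[1] == 0:
        raise ValueError("no polymorphic sites for the relationship matrix")
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (z @ z.T) / d.shape[1]


@dataclass
class PCAResult:
    coordinates: pd.DataFrame      # samples x PC1..PCk, scaled by sqrt(eigenvalue)
    variance_fraction: np.ndarray  # per returned axis, of all positive eigenvalues
    n_snps: int


def pca(grm: np.ndarray, k: int = 10, samples: list[str] | None = None,
        n_snps: int = 0) -> PCAResult:
    """Top-k eigenpairs of a (symmetric) relationship matrix."""
    g = np.asarray(grm, dtype=np.float64)
    if not np.allclose(g, g.T, atol=1e-8):
        raise ValueError("relationship matrix must be symmetric")
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    positive = vals > 1e-12
    n_pos = int(positive.sum())
    if k > n_pos:
        import warnings
        warnings.warn(f"requested {k} axes but only {n_pos} positive eigenvalues;"
                      " truncating", stacklevel=2)
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    frac = vals[:k] / vals[positive].sum()
    idx = samples if samples is not None else list(range(g.shape[0]))
    df = pd.DataFrame(coords, index=idx,
                      columns=[f"PC{i+1}" for i in range(k)])
    return PCAResult(coordinates=df, variance_fraction=frac, n_snps=n_snps)


@dataclass
class GroupTestResult:
    grouping: str
    h_statistic: float
    df: int
    p_value: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    adjustment: str = "holm"


def kruskal_wallis(groups: list[np.ndarray], grouping: str = "") -> GroupTestResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square p value (df = k - 1)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(grouping, 0.0, len(arrays) - 1, 1.0)
    h, p = stats.kruskal(*arrays)
    return GroupTestResult(grouping, float(h), len(arrays) - 1, float(p))


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def dunn_posthoc(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    adjustment: str = "holm",
) -> pd.DataFrame:
    """Dunn's post hoc z tests on pooled mid-ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)] with
    tie term T = sum(t^3 - t) / (12(N - 1)).  Two-sided normal p values,
    adjusted by Holm (default) or Bonferroni.
    """
    if adjustment not in ("holm", "bonferroni"):
        raise ValueError("adjustment must be 'holm' or 'bonferroni'")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if labels is None:
        labels = [f"group{i+1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # mid-ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12.0 * (n_total - 1))) \
        if n_total > 1 else 0.0

    mean_rank, sizes = [], []
    start = 0
    for a in arrays:
        mean_rank.append(ranks[start:start + a.size].mean())
        sizes.append(a.size)
        start += a.size

    var_core = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        se2 = var_core * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0:
            z = 0.0
        else:
            z = (mean_rank[i] - mean_rank[j]) / np.sqrt(se2)
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": labels[i], "group2": labels[j],
                     "z": float(z), "p": float(min(p, 1.0))})
    df = pd.DataFrame(rows)
    raw = df["p"].to_numpy()
    if adjustment == "holm":
        df["p_adj"] = _holm(raw)
    else:
        df["p_adj"] = np.minimum(1.0, raw * raw.size)
    df["adjustment"] = adjustment
    return df
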