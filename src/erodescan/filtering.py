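"""Site and genotype quality filters applied before any analysis.

Retained sites must: lie on analyzable scaffolds outside the mask, have
site quality >= QV 30, sit more than 5 bp from the nearest indel, satisfy
per-sample depth bounds of one third to twice that sample's mean coverage,
and (by default) carry a call in every individual.  A site failing several
rules is attributed to the first failing rule, in the fixed order
scaffold/mask -> quality -> indel proximity -> depth -> completeness, so
report counts always sum to the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .matrix import MISSING, GenotypeMatrix, SampleMetadata

__all__ = ["FilterParams", "FilterReport", "depth_thresholds", "filter_sites"]

RULES = ("scaffold_or_mask", "quality", "indel_proximity", "depth", "incomplete")


@dataclass(frozen=True)
class FilterParams:
    min_qv: float = 30.0
    indel_exclusion_radius: int = 5
    depth_min_factor: float = 1.0 / 3.0   # of a sample's mean coverage
    depth_max_factor: float = 2.0         # times a sample's mean coverage
    min_scaffold_bp: int = 25_000
    require_complete_genotyping: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.depth_min_factor < self.depth_max_factor:
            raise ValueError("need 0 < depth_min_factor < depth_max_factor")
        if self.indel_exclusion_radius < 0:
            raise ValueError("indel radius must be >= 0")


@dataclass
class FilterReport:
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULES})
    retained: int = 0

    @property
    def input_sites(self) -> int:
        return self.retained + sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": n} for r, n in self.removed.items()]
        rows.append({"rule": "retained", "removed": self.retained})
        return pd.DataFrame(rows)


def depth_thresholds(mean_coverage: float,
                     params: FilterParams = FilterParams()) -> tuple[float, float]:
    """Per-sample depth bounds: (mean/3, 2*mean) at the defaults."""
    if mean_coverage <= 0:
        raise ValueError("mean coverage must be positive")
    return (params.depth_min_factor * mean_coverage,
            params.depth_max_factor * mean_coverage)


def _nearest_indel_distance(sites: pd.DataFrame, indels: pd.DataFrame) -> np.ndarray:
    """Distance from each SNP to the nearest indel anchor on its scaffold."""
    dist = np.full(len(sites), np.inf)
    if indels.empty:
        return dist
    by_scaffold = {s: np.sort(g["pos"].to_numpy())
                   for s, g in indels.groupby("scaffold")}
    for scaffold, grp in sites.groupby("scaffold", sort=False):
        anchors = by_scaffold.get(scaffold)
        if anchors is None:
            continue
        pos = grp["pos"].to_numpy()
        k = np.searchsorted(anchors, pos)
        left = np.where(k > 0, np.abs(pos - anchors[np.maximum(k - 1, 0)]), np.inf)
        right = np.where(k < len(anchors),
                         np.abs(anchors[np.minimum(k, len(anchors) - 1)] - pos), np.inf)
        dist[grp.index.to_numpy()] = np.minimum(left, right)
    return dist


def filter_sites(
    matrix: GenotypeMatrix,
    layout: GenomeLayout,
    metadata: SampleMetadata,
    params: FilterParams = FilterParams(),
    indels: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply all site filters; returns the filtered matrix and a report.

    ``indels`` defaults to the indel positions registered on the matrix.
    Depth bounds use each sample's own mean coverage from ``metadata``.
    """
    metadata.check_samples(matrix.samples)
    if indels is None:
        indels = matrix.indels
    sites = matrix.sites
    n = len(sites)

    # rule 1: analyzable scaffold, outside mask
    ok_scaffold = sites["scaffold"].map(layout.is_analyzable).to_numpy(dtype=bool)
    masked = np.zeros(n, dtype=bool)
    for scaffold, grp in sites.groupby("scaffold", sort=False):
        idx = grp.index.to_numpy()
        masked[idx] = layout.is_masked(scaffold, grp["pos"].to_numpy() - 1)
    fail1 = ~ok_scaffold | masked

    # rule 2: site quality
    fail2 = sites["qual"].to_numpy() < params.min_qv

    # rule 3: proximity to indels (distance <= radius removes the SNP)
    dist = _nearest_indel_distance(sites, indels)
    fail3 = dist <= params.indel_exclusion_radius

    # rule 4: per-sample depth bounds
    lo = np.array([depth_thresholds(metadata.mean_coverage(s), params)[0]
                   for s in matrix.samples])
    hi = np.array([depth_thresholds(metadata.mean_coverage(s), params)[1]
                   for s in matrix.samples])
    depth = matrix.depth
    fail4 = ((depth < lo[:, None]) | (depth > hi[:, None])).any(axis=0)

    # rule 5: complete genotyping
    fail5 = ((matrix.calls == MISSING).any(axis=0)
             if params.require_complete_genotyping
             else np.zeros(n, dtype=bool))

    report = FilterReport()
    remaining = np.ones(n, dtype=bool)
    for rule, fail in zip(RULES, (fail1, fail2, fail3, fail4, fail5)):
        hit = remaining & fail
        report.removed[rule] = int(hit.sum())
        remaining &= ~fail
    report.retained = int(remaining.sum())
    return matrix.subset_sites(remaining), report
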