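"""In-memory genotype container shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HOM_REF", "HET", "HOM_ALT", "MISSING", "GenotypeMatrix", "SampleMetadata"]

# diploid call codes (int8); MISSING must stay negative
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

SITE_COLUMNS = ["scaffold", "pos", "ref", "alt", "qual"]


@dataclass
class GenotypeMatrix:
    """Per-individual, per-site diploid genotype calls.

    Attributes
    ----------
    sites
        DataFrame with columns ``scaffold, pos (1-based), ref, alt, qual``,
        ordered with positions strictly increasing within scaffold.
    calls
        ``(n_samples, n_sites)`` int8 array of call codes.
    depth
        ``(n_samples, n_sites)`` int32 array of per-genotype read depths.
    samples
        Ordered individual identifiers.
    indels
        DataFrame ``scaffold, pos`` of indel anchor positions observed in the
        source VCF; retained only to drive indel-proximity filtering.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray
    samples: list[str]
    indels: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["scaffold", "pos"])
    )

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        self.validate()

    def validate(self) -> None:
        n_samples, n_sites = len(self.samples), len(self.sites)
        if self.calls.shape != (n_samples, n_sites):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n_samples}, {n_sites})"
            )
        if self.depth.shape != self.calls.shape:
            raise ValueError("every call needs a depth entry")
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")
        if len(self.sites) and np.any(self.sites["qual"].to_numpy() < 0):
            raise ValueError("site quality must be >= 0")
        for scaffold, grp in self.sites.groupby("scaffold", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on scaffold {scaffold!r}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to a boolean/index site selection."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sites=self.sites.iloc[keep],
            calls=self.calls[:, keep],
            depth=self.depth[:, keep],
            samples=list(self.samples),
            indels=self.indels.copy(),
        )

    def scaffold_slices(self):
        """Yield ``(scaffold, index array)`` in site order."""
        for scaffold, grp in self.sites.groupby("scaffold", sort=False):
            yield scaffold, grp.index.to_numpy()


@dataclass
class SampleMetadata:
    """Sample-to-population table: id, population label, year, mean coverage."""

    table: pd.DataFrame

    REQUIRED = ("sample", "population", "mean_coverage")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        if (self.table["mean_coverage"] <= 0).any():
            raise ValueError("mean coverage must be > 0")
        self.table = self.table.reset_index(drop=True)

    def check_samples(self, samples: list[str]) -> None:
        """Every matrix sample must have exactly one metadata row."""
        known = set(self.table["sample"])
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise KeyError(f"samples without metadata: {unknown}")

    def mean_coverage(self, sample: str) -> float:
        rows = self.table.loc[self.table["sample"] == sample, "mean_coverage"]
        if rows.empty:
            raise KeyError(f"no metadata row for sample {sample!r}")
        return float(rows.iloc[0])

    def population(self, sample: str) -> str:
        rows = self.table.loc[self.table["sample"] == sample, "population"]
        if rows.empty:
            raise KeyError(f"no metadata row for sample {sample!r}")
        return str(rows.iloc[0])
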