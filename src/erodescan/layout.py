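"""Genome coordinate frame: scaffolds, lengths and masked intervals.

All internal intervals are 0-based half-open ``[start, end)``.  VCF positions
are 1-based and converted exactly once, at the I/O boundary (:mod:`.vcfio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeLayout",
    "merge_intervals",
    "intersect_intervals",
    "total_length",
]


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge half-open intervals given as an ``(n, 2)`` array.

    Touching intervals (``end == start``) are coalesced.
    """
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.shape[0] == 0:
        return arr
    if np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("interval end must be greater than start")
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged half-open interval sets."""
    a = np.asarray(a, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b, dtype=np.int64).reshape(-1, 2)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def total_length(intervals: np.ndarray) -> int:
    """Total number of bases covered by a merged interval set."""
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.shape[0] == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered scaffolds with lengths plus masked regions.

    Parameters
    ----------
    scaffolds
        Ordered ``(name, length_bp)`` pairs.
    masked
        Mapping scaffold -> ``(n, 2)`` array of 0-based half-open masked
        intervals (repeat mask, sex-linked scaffolds, mitogenome, ...).
    min_scaffold_bp
        Scaffolds shorter than this are excluded from every analysis
        (default 25 kb).
    """

    scaffolds: tuple[tuple[str, int], ...]
    masked: dict[str, np.ndarray] = field(default_factory=dict)
    min_scaffold_bp: int = 25_000

    def __post_init__(self) -> None:
        names = [n for n, _ in self.scaffolds]
        if len(set(names)) != len(names):
            raise ValueError("scaffold names must be unique")
        lengths = dict(self.scaffolds)
        merged = {}
        for name, ivals in self.masked.items():
            if name not in lengths:
                raise ValueError(f"masked interval on unknown scaffold {name!r}")
            m = merge_intervals(ivals)
            if len(m) and (m[0, 0] < 0 or m[-1, 1] > lengths[name]):
                raise ValueError(f"masked interval outside scaffold {name!r}")
            merged[name] = m
        object.__setattr__(self, "masked", merged)

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return dict(self.scaffolds)

    def is_analyzable(self, scaffold: str) -> bool:
        length = self.scaffold_lengths.get(scaffold)
        return length is not None and length >= self.min_scaffold_bp

    def analyzable_scaffolds(self) -> list[tuple[str, int]]:
        return [(n, l) for n, l in self.scaffolds if l >= self.min_scaffold_bp]

    def masked_for(self, scaffold: str) -> np.ndarray:
        return self.masked.get(scaffold, np.empty((0, 2), dtype=np.int64))

    def analyzable_intervals(self, scaffold: str) -> np.ndarray:
        """Unmasked intervals of an analyzable scaffold (empty if not analyzable)."""
        if not self.is_analyzable(scaffold):
            return np.empty((0, 2), dtype=np.int64)
        length = self.scaffold_lengths[scaffold]
        mask = self.masked_for(scaffold)
        out = []
        prev = 0
        for s, e in mask:
            if s > prev:
                out.append((prev, s))
            prev = max(prev, e)
        if prev < length:
            out.append((prev, length))
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    @property
    def analyzable_length(self) -> int:
        """Total unmasked bases on scaffolds >= ``min_scaffold_bp``."""
        return sum(
            total_length(self.analyzable_intervals(n))
            for n, _ in self.analyzable_scaffolds()
        )

    def is_masked(self, scaffold: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized mask lookup for 0-based positions on one scaffold."""
        pos = np.asarray(positions, dtype=np.int64)
        mask = self.masked_for(scaffold)
        if mask.shape[0] == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(mask[:, 0], pos, side="right") - 1
        inside = idx >= 0
        inside[inside] = pos[inside] < mask[idx[inside], 1]
        return inside
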