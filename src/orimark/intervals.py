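"""Genomic interval types and set algebra on sorted, merged region sets.

Regions are 0-based half-open. A *merged* :class:`RegionSet` is sorted by
(chromosome, start) and pairwise non-overlapping and non-abutting: abutting
intervals (``end == next start``) are coalesced on merge, i.e. contiguous
regions are treated as one feature region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np


@dataclass(frozen=True)
class TagAlignment:
    """One aligned sequencing read (nascent-strand, genomic control, or ChIP)."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid alignment interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Region:
    """One called peak / feature region, optionally scored."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid region [{self.start}, {self.end}) on {self.chrom}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _sort_key(r: Region) -> tuple[str, int, int]:
    return (r.chrom, r.start, r.end)


class RegionSet:
    """A list of regions, sorted by (chromosome, start); optionally merged.

    When ``merged`` is true the regions are pairwise non-overlapping and
    non-abutting, which the set-algebra operations below rely on.
    """

    __slots__ = ("_regions", "_merged")

    def __init__(self, regions: Iterable[Region] = (), merged: bool = False):
        regs = sorted(regions, key=_sort_key)
        if merged:
            for a, b in zip(regs, regs[1:]):
                if a.chrom == b.chrom and b.start <= a.end:
                    raise ValueError(
                        "RegionSet flagged merged but contains overlapping/abutting regions"
                    )
        self._regions = tuple(regs)
        self._merged = bool(merged)

    @property
    def regions(self) -> tuple[Region, ...]:
        return self._regions

    @property
    def is_merged(self) -> bool:
        return self._merged

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self._regions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return [(r.chrom, r.start, r.end, r.score) for r in self] == [
            (r.chrom, r.start, r.end, r.score) for r in other
        ]

    def __repr__(self) -> str:
        return f"RegionSet(n={len(self)}, merged={self._merged})"

    @property
    def chroms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self._regions:
            seen.setdefault(r.chrom, None)
        return tuple(seen)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome ``(n, 2)`` int arrays of (start, end), sorted."""
        out: dict[str, list[tuple[int, int]]] = {}
        for r in self._regions:
            out.setdefault(r.chrom, []).append((r.start, r.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    @property
    def covered_bp(self) -> int:
        """Total bp covered; counts multiplicity if the set is unmerged."""
        if self._merged:
            return sum(r.length for r in self._regions)
        return merge(self).covered_bp

    def lengths(self) -> np.ndarray:
        return np.asarray([r.length for r in self._regions], dtype=np.int64)


def merge(regions: Iterable[Region] | RegionSet, gap: int = 0) -> RegionSet:
    """Coalesce overlapping or near regions into one feature region each.

    Regions separated by at most ``gap`` bp are joined; with the default
    ``gap=0`` abutting regions (``end == next start``) merge while regions
    with any positive gap do not. Scores are dropped. Total covered bp is
    conserved for ``gap=0``.
    """
    regs = sorted(regions, key=_sort_key)
    out: list[Region] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for r in regs:
        if r.chrom != cur_chrom or r.start > cur_end + gap:
            if cur_chrom is not None:
                out.append(Region(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = r.chrom, r.start, r.end
        else:
            cur_end = max(cur_end, r.end)
    if cur_chrom is not None:
        out.append(Region(cur_chrom, cur_start, cur_end))
    return RegionSet(out, merged=(gap == 0))


def union(a: RegionSet, b: RegionSet) -> RegionSet:
    return merge(list(a) + list(b))


def _require_merged(*sets: RegionSet) -> None:
    for s in sets:
        if not s.is_merged:
            raise ValueError("operation requires merged RegionSets; call merge() first")


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    """Maximal intervals covered by both sets, abutting results joined."""
    _require_merged(a, b)
    av, bv = a.by_chrom(), b.by_chrom()
    out: list[Region] = []
    for chrom in av:
        if chrom not in bv:
            continue
        A, B = av[chrom], bv[chrom]
        i = j = 0
        while i < len(A) and j < len(B):
            s = max(A[i, 0], B[j, 0])
            e = min(A[i, 1], B[j, 1])
            if s < e:
                out.append(Region(chrom, int(s), int(e)))
            if A[i, 1] < B[j, 1]:
                i += 1
            else:
                j += 1
    return merge(out)


def subtract(a: RegionSet, b: RegionSet) -> RegionSet:
    """bp-level set difference ``a \\ b`` of merged sets."""
    _require_merged(a, b)
    bv = b.by_chrom()
    out: list[Region] = []
    for r in a:
        cuts = bv.get(r.chrom)
        if cuts is None:
            out.append(Region(r.chrom, r.start, r.end))
            continue
        pos = r.start
        for s, e in cuts:
            if e <= pos:
                continue
            if s >= r.end:
                break
            if s > pos:
                out.append(Region(r.chrom, pos, int(s)))
            pos = max(pos, int(e))
            if pos >= r.end:
                break
        if pos < r.end:
            out.append(Region(r.chrom, pos, r.end))
    return RegionSet(out, merged=True)
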