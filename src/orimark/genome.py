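"""Genome reference frame: ordered chromosomes and fixed-width bin grids.

All coordinates in this package are 0-based, half-open (BED-native).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in bp."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lengths", tuple(int(x) for x in self.lengths))
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(self.names) == 0:
            raise ValueError("empty genome layout")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(self.names, self.lengths):
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes.keys()), tuple(sizes.values()))

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    @property
    def total_bp(self) -> int:
        return sum(self.lengths)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise KeyError(f"chromosome {name!r} not in layout") from None


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width binning of a genome layout.

    Bin ``i`` of a chromosome spans ``[i*width, min((i+1)*width, length))``;
    the final bin of each chromosome may be shorter than ``width``.
    """

    layout: GenomeLayout
    width: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "width", int(self.width))
        if self.width < 1:
            raise ValueError(f"bin width must be >= 1, got {self.width}")

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.layout.length_of(chrom) / self.width)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.layout.names)

    def bin_lengths(self, chrom: str) -> np.ndarray:
        """Actual bp length of each bin (the last bin may be short)."""
        length = self.layout.length_of(chrom)
        n = self.n_bins(chrom)
        out = np.full(n, self.width, dtype=np.int64)
        out[-1] = length - (n - 1) * self.width
        return out

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.width

    def bin_ends(self, chrom: str) -> np.ndarray:
        ends = self.bin_starts(chrom) + self.width
        ends[-1] = self.layout.length_of(chrom)
        return ends
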