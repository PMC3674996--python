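"""Readers/writers: UCSC chrom.sizes, BED3/BED6 tag alignments and regions,
and bedGraph signal tracks. All formats are tab-delimited text, 0-based
half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator

import numpy as np

from .genome import BinGrid, GenomeLayout
from .intervals import Region, RegionSet, TagAlignment, merge

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed record in a text genomic file; message names the line."""


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Parse a two-column chrom.sizes file, preserving file order."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer chromosome length {fields[1]!r}"
                ) from None
            if name in names:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length < 1:
                raise ParseError(f"{path}:{lineno}: non-positive length {length}")
            names.append(name)
            lengths.append(length)
    if not names:
        raise ParseError(f"{path}: empty chrom.sizes file")
    return GenomeLayout(tuple(names), tuple(lengths))


def _parse_bed_line(path, lineno: int, line: str) -> tuple[str, int, int, str | None]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
    if start < 0:
        raise ParseError(f"{path}:{lineno}: negative start {start}")
    if start >= end:
        raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
    strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else None
    return chrom, start, end, strand


def iter_alignments(path: str | Path, layout: GenomeLayout) -> Iterator[TagAlignment]:
    """Yield tag alignments in file order; logs the count of records skipped
    because their chromosome is absent from the layout."""
    alignments, skipped = load_alignments(path, layout)
    if skipped:
        logger.info("%s: skipped %d alignments on chromosomes absent from layout", path, skipped)
    yield from alignments


def load_alignments(
    path: str | Path, layout: GenomeLayout
) -> tuple[list[TagAlignment], int]:
    """Read a BED3+ alignment file.

    Returns ``(alignments, n_skipped)`` where skipped records are those on
    chromosomes absent from the layout. Coordinate violations (negative start,
    start >= end, end beyond the chromosome) raise :class:`ParseError`.
    """
    out: list[TagAlignment] = []
    skipped = 0
    sizes = layout.sizes
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, strand = _parse_bed_line(path, lineno, line)
            if chrom not in sizes:
                skipped += 1
                continue
            if end > sizes[chrom]:
                raise ParseError(
                    f"{path}:{lineno}: end {end} beyond {chrom} length {sizes[chrom]}"
                )
            out.append(TagAlignment(chrom, start, end, strand))
    return out, skipped


def read_regions(
    path: str | Path,
    layout: GenomeLayout | None = None,
    merge_regions: bool = True,
) -> RegionSet:
    """Read a BED3+ region file into a sorted (and by default merged) set.

    Records on chromosomes absent from ``layout`` (when given) are skipped
    with a logged count. A numeric 5th column is kept as the region score
    (dropped if the set is merged).
    """
    regions: list[Region] = []
    skipped = 0
    sizes = layout.sizes if layout is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, _ = _parse_bed_line(path, lineno, line)
            if sizes is not None and chrom not in sizes:
                skipped += 1
                continue
            score = None
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            regions.append(Region(chrom, start, end, score))
    if skipped:
        logger.info("%s: skipped %d regions on chromosomes absent from layout", path, skipped)
    if merge_regions:
        return merge(regions)
    return RegionSet(regions, merged=False)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    """Write BED3 (or BED5 when scores are present)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            if r.score is None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i}\t{r.score:.6g}\n")


def write_signal_track(
    track,
    path: str | Path,
    merge_runs: bool = False,
    decimals: int = 6,
) -> None:
    """Write a bin-aligned track as 4-column bedGraph.

    One line per bin by default; with ``merge_runs`` adjacent equal-valued
    bins (after decimal formatting) are run-length merged.
    """
    grid: BinGrid = track.grid
    with open(path, "w") as fh:
        for chrom in grid.layout.names:
            values = track.data[chrom]
            starts = grid.bin_starts(chrom)
            ends = grid.bin_ends(chrom)
            formatted = [f"{v:.{decimals}f}" for v in values]
            i = 0
            n = len(values)
            while i < n:
                j = i + 1
                if merge_runs:
                    while j < n and formatted[j] == formatted[i]:
                        j += 1
                fh.write(f"{chrom}\t{starts[i]}\t{ends[j - 1]}\t{formatted[i]}\n")
                i = j


def read_signal_track(path: str | Path, grid: BinGrid, label: str = "",
                      total_reads: int | None = None):
    """Read a bin-aligned bedGraph (possibly run-length merged) back into a
    :class:`~orimark.tracks.SignalTrack` on ``grid``."""
    from .tracks import SignalTrack

    data = {c: np.zeros(grid.n_bins(c)) for c in grid.layout.names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in data:
                raise ParseError(f"{path}:{lineno}: chromosome {chrom!r} not in grid layout")
            if start % grid.width != 0:
                raise ParseError(f"{path}:{lineno}: interval not aligned to {grid.width}-bp bins")
            b0 = start // grid.width
            b1 = (end + grid.width - 1) // grid.width
            data[chrom][b0:b1] = value
    return SignalTrack(grid=grid, data=data, total_reads=total_reads, label=label)
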