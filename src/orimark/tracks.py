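"""Binned signal tracks: read counting, RPKM normalization, Gaussian
smoothing, and nascent-strand/control enrichment-ratio tracks.

The coverage model is deliberately simple: each aligned read is assigned to
the fixed-width bin containing its midpoint (so read number is conserved
exactly), per-bin counts are converted to reads per kilobase per million
mapped reads using each bin's true length, and a truncated, renormalized
Gaussian kernel smooths the bin values. The replication initiation signal is
the per-bin ratio of nascent-strand RPKM to genomic-control RPKM, which
cancels sequencing bias and copy-number variation shared by the two samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .genome import BinGrid
from .intervals import TagAlignment


@dataclass
class SignalTrack:
    """Per-chromosome bin values (read counts or RPKM, all >= 0)."""

    grid: BinGrid
    data: dict[str, np.ndarray]
    total_reads: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        for chrom in self.grid.layout.names:
            if chrom not in self.data:
                raise ValueError(f"track missing data for chromosome {chrom!r}")
            v = np.asarray(self.data[chrom], dtype=float)
            if len(v) != self.grid.n_bins(chrom):
                raise ValueError(
                    f"{chrom}: {len(v)} values for {self.grid.n_bins(chrom)} bins"
                )
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{chrom}: track values must be finite and >= 0")
            self.data[chrom] = v

    @classmethod
    def zeros(cls, grid: BinGrid, total_reads: int | None = None, label: str = "") -> "SignalTrack":
        return cls(grid, {c: np.zeros(grid.n_bins(c)) for c in grid.layout.names},
                   total_reads, label)

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.grid.layout.names])


@dataclass
class RatioTrack:
    """Per-bin enrichment ratio (e.g. nascent RPKM / control RPKM)."""

    grid: BinGrid
    data: dict[str, np.ndarray]
    pseudocount: float = 0.0
    numerator: str = ""
    denominator: str = ""

    def __post_init__(self) -> None:
        for chrom in self.grid.layout.names:
            v = np.asarray(self.data[chrom], dtype=float)
            if len(v) != self.grid.n_bins(chrom):
                raise ValueError(
                    f"{chrom}: {len(v)} values for {self.grid.n_bins(chrom)} bins"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{chrom}: ratio values must be finite")
            self.data[chrom] = v

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.grid.layout.names])


def count_reads_per_bin(
    alignments: Iterable[TagAlignment],
    grid: BinGrid,
    assignment_rule: str = "midpoint",
) -> SignalTrack:
    """Count reads into grid bins.

    ``midpoint`` (default): each read counted once, in the bin containing its
    midpoint — the total over all bins equals the number of reads assigned.
    ``overlap``: each read distributes one unit across the bins it spans,
    proportionally to bp overlap.
    """
    if assignment_rule not in ("midpoint", "overlap"):
        raise ValueError(f"unknown assignment rule {assignment_rule!r}")
    counts = {c: np.zeros(grid.n_bins(c)) for c in grid.layout.names}
    w = grid.width
    n_reads = 0
    if assignment_rule == "midpoint":
        mids: dict[str, list[int]] = {c: [] for c in grid.layout.names}
        for a in alignments:
            mids[a.chrom].append(a.midpoint)
            n_reads += 1
        for chrom, m in mids.items():
            if m:
                idx = np.asarray(m, dtype=np.int64) // w
                counts[chrom] = np.bincount(idx, minlength=grid.n_bins(chrom)).astype(float)
    else:
        for a in alignments:
            n_reads += 1
            b0, b1 = a.start // w, (a.end - 1) // w
            length = a.end - a.start
            arr = counts[a.chrom]
            for b in range(b0, b1 + 1):
                lo = max(a.start, b * w)
                hi = min(a.end, (b + 1) * w)
                arr[b] += (hi - lo) / length
    if n_reads == 0:
        warnings.warn("no alignments provided; returning an all-zero track", stacklevel=2)
    return SignalTrack(grid=grid, data=counts, total_reads=n_reads, label="counts")


def compute_rpkm(count_track: SignalTrack) -> SignalTrack:
    """RPKM per bin: ``c_i / ((L_i/1000) * (N/1e6))`` with ``L_i`` the bin's
    actual bp length (edge bins may be short) and ``N`` the track's total
    mapped reads."""
    n = count_track.total_reads
    if not n:
        raise ValueError("total mapped reads must be > 0 to compute RPKM")
    data = {}
    for chrom in count_track.grid.layout.names:
        lengths = count_track.grid.bin_lengths(chrom).astype(float)
        data[chrom] = count_track.data[chrom] / ((lengths / 1000.0) * (n / 1e6))
    return SignalTrack(grid=count_track.grid, data=data, total_reads=n,
                       label=count_track.label or "rpkm")


def gaussian_kernel(sigma_bins: float, truncation_radius: float = 4.0) -> np.ndarray:
    """Discrete Gaussian kernel truncated at ±radius·sigma, normalized to sum 1."""
    if sigma_bins < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma_bins}")
    r = int(np.ceil(truncation_radius * sigma_bins))
    if sigma_bins == 0 or r == 0:
        return np.array([1.0])
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_bins) ** 2)
    return k / k.sum()


def smooth_values(values: np.ndarray, sigma_bins: float,
                  truncation_radius: float = 4.0) -> np.ndarray:
    """Convolve one chromosome's bin values with a truncated Gaussian kernel.

    Chromosome ends are handled by renormalizing the kernel over in-bounds
    bins, so a constant track stays constant everywhere.
    """
    kernel = gaussian_kernel(sigma_bins, truncation_radius)
    if len(kernel) == 1:
        return values.astype(float, copy=True)
    # centered slice of the full convolution (np.convolve's "same" mode pads
    # to max(len(values), len(kernel)), wrong for short chromosomes)
    n, k = len(values), len(kernel)
    lo = (k - 1) // 2
    num = np.convolve(values, kernel, mode="full")[lo : lo + n]
    den = np.convolve(np.ones(n), kernel, mode="full")[lo : lo + n]
    return num / den


def gaussian_smooth(track, sigma_bins: float = 2.0, truncation_radius: float = 4.0):
    """Gaussian-smooth every chromosome of a SignalTrack or RatioTrack."""
    if sigma_bins < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma_bins}")
    data = {
        chrom: smooth_values(np.asarray(v, dtype=float), sigma_bins, truncation_radius)
        for chrom, v in track.data.items()
    }
    return replace(track, data=data)


def enrichment_ratio(
    nascent_rpkm: SignalTrack,
    control_rpkm: SignalTrack,
    pseudocount: float = 0.5,
) -> RatioTrack:
    """Per-bin enrichment ratio ``(nascent_i + eps) / (control_i + eps)``.

    The symmetric pseudocount keeps the ratio finite at zero-control bins and
    leaves its null centered at 1.
    """
    if nascent_rpkm.grid != control_rpkm.grid:
        raise ValueError("numerator and denominator tracks are on different grids")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    data = {}
    for chrom in nascent_rpkm.grid.layout.names:
        num = nascent_rpkm.data[chrom] + pseudocount
        den = control_rpkm.data[chrom] + pseudocount
        if pseudocount == 0 and np.any(den == 0):
            raise ValueError(
                f"{chrom}: control has zero-RPKM bins; use a positive pseudocount"
            )
        data[chrom] = num / den
    return RatioTrack(
        grid=nascent_rpkm.grid,
        data=data,
        pseudocount=pseudocount,
        numerator=nascent_rpkm.label,
        denominator=control_rpkm.label,
    )
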