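"""Enriched-region ("peak") calling from binned tracks at a target empirical
FDR, and bin-association counting.

The caller smooths the input bin values with a truncated Gaussian kernel and
keeps bins whose smoothed value exceeds a threshold chosen from an empirical
null. The null rearranges the *raw* bin values (destroying their spatial
clustering) and passes them through the same smoothing: genuine contiguous
signal survives smoothing while rearranged signal is diluted, so for each
candidate threshold t the expected number of null bins exceeding t estimates
the false-discovery count among the observed exceedances:

    FDR(t) = mean_runs #{null smoothed bins >= t} / max(#{observed smoothed bins >= t}, 1)

The table is made monotone non-increasing in t by a running minimum, and the
calling threshold is the smallest t whose regularized FDR is at or below the
configured level. Surviving bins are joined across gaps up to ``merge_gap``
bp and regions narrower than ``min_width`` bp are dropped.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid
from .intervals import Region, RegionSet, merge
from .tracks import smooth_values


@dataclass(frozen=True)
class PeakCallConfig:
    fdr: float = 0.15
    n_randomizations: int = 20
    min_width: int = 200
    merge_gap: int = 200
    seed: int = 0
    sigma_bins: float = 2.0
    truncation_radius: float = 4.0
    null_mode: str = "permute"  # "permute" or "shift"
    n_thresholds: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError(f"FDR must be in (0, 1), got {self.fdr}")
        if self.n_randomizations < 1:
            raise ValueError("need at least one randomization")
        if self.null_mode not in ("permute", "shift"):
            raise ValueError(f"unknown null mode {self.null_mode!r}")


@dataclass
class PeakCallResult:
    peaks: RegionSet
    threshold: float
    estimated_fdr: float
    fdr_table: pd.DataFrame = field(repr=False)


def _chrom_rng(seed: int, run: int, chrom: str) -> np.random.Generator:
    # keyed by chromosome *name* so results are invariant to layout order
    digest = hashlib.blake2s(chrom.encode(), digest_size=4).digest()
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(seed, run, int.from_bytes(digest, "little")))
    )


def _null_values(values: np.ndarray, rng: np.random.Generator, mode: str) -> np.ndarray:
    if mode == "permute":
        return rng.permutation(values)
    offset = int(rng.integers(0, len(values)))
    return np.roll(values, offset)


def empirical_null_thresholds(track, config: PeakCallConfig) -> pd.DataFrame:
    """Threshold-vs-FDR table from a rearrangement null.

    Returns a DataFrame with ascending ``threshold``, the observed and mean
    null exceeding-bin counts, the raw FDR ratio and its monotone
    (non-increasing) regularization ``fdr``.
    """
    chroms = list(track.grid.layout.names)
    raw = {c: np.asarray(track.data[c], dtype=float) for c in chroms}
    pooled_raw = np.concatenate([raw[c] for c in chroms])
    if np.ptp(pooled_raw) == 0:
        raise ValueError("all-constant track: the rearrangement null is degenerate")

    smoothed = np.concatenate(
        [smooth_values(raw[c], config.sigma_bins, config.truncation_radius) for c in chroms]
    )
    qs = np.linspace(0.0, 1.0, config.n_thresholds + 1)[1:]
    thresholds = np.unique(np.quantile(smoothed, qs))

    smoothed_sorted = np.sort(smoothed)
    n = len(smoothed_sorted)
    observed = n - np.searchsorted(smoothed_sorted, thresholds, side="left")

    null_total = np.zeros(len(thresholds))
    for run in range(config.n_randomizations):
        parts = []
        for chrom in chroms:
            rng = _chrom_rng(config.seed, run, chrom)
            parts.append(
                smooth_values(
                    _null_values(raw[chrom], rng, config.null_mode),
                    config.sigma_bins,
                    config.truncation_radius,
                )
            )
        null_sorted = np.sort(np.concatenate(parts))
        null_total += n - np.searchsorted(null_sorted, thresholds, side="left")
    null_mean = null_total / config.n_randomizations

    fdr_raw = null_mean / np.maximum(observed, 1)
    fdr = np.minimum.accumulate(np.minimum(fdr_raw, 1.0))
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "observed_exceed": observed,
            "null_exceed_mean": null_mean,
            "fdr_raw": fdr_raw,
            "fdr": fdr,
        }
    )


def call_enriched_regions(track, config: PeakCallConfig) -> PeakCallResult:
    """Call enriched regions on a binned track at the configured FDR.

    Deterministic given the config seed, and invariant to the order in which
    chromosomes appear in the layout.
    """
    table = empirical_null_thresholds(track, config)
    eligible = table[table["fdr"] <= config.fdr]
    grid: BinGrid = track.grid
    if eligible.empty:
        warnings.warn(
            f"no threshold reaches FDR <= {config.fdr}; returning an empty region set",
            stacklevel=2,
        )
        return PeakCallResult(RegionSet(merged=True), float("nan"), float("nan"), table)
    row = eligible.iloc[0]  # smallest qualifying threshold -> most inclusive call
    threshold = float(row["threshold"])
    est_fdr = float(row["fdr"])

    regions: list[Region] = []
    w = grid.width
    for chrom in grid.layout.names:
        values = smooth_values(
            np.asarray(track.data[chrom], dtype=float),
            config.sigma_bins,
            config.truncation_radius,
        )
        kept = np.flatnonzero(values >= threshold)
        if len(kept) == 0:
            continue
        chrom_len = grid.layout.length_of(chrom)
        bins = [
            Region(chrom, int(b) * w, min((int(b) + 1) * w, chrom_len)) for b in kept
        ]
        for r in merge(bins, gap=config.merge_gap):
            if r.length >= config.min_width:
                b0, b1 = r.start // w, (r.end + w - 1) // w
                score = float(values[b0:b1].mean())
                regions.append(Region(chrom, r.start, r.end, score))
    peaks = RegionSet(regions, merged=True)
    return PeakCallResult(peaks, threshold, est_fdr, table)


def count_associated_bins(peaks: RegionSet, grid: BinGrid) -> int:
    """Number of grid bins whose span intersects any peak."""
    total = 0
    for chrom, arr in peaks.by_chrom().items():
        mask = np.zeros(grid.n_bins(chrom), dtype=bool)
        w = grid.width
        for s, e in arr:
            mask[s // w : (e + w - 1) // w] = True
        total += int(mask.sum())
    return total
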