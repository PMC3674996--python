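"""Proximity colocalization statistics with a size-matched randomized null,
distance-to-feature enrichment profiles, and double-feature intersection
(additivity) analysis.

Distance semantics are edge-to-edge: the distance between two intervals is 0
when they overlap (or abut) and otherwise the end-to-start gap in bp. A
feature "within w bp" of a target therefore means gap <= w. The null for the
colocalization test preserves each feature's length and chromosome while
drawing its start uniformly, independently per feature (overlaps permitted);
the observed proximity fraction is compared to the mean over R such
randomized feature sets, with an add-one empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .intervals import Region, RegionSet, intersect
from .tracks import RatioTrack

DEFAULT_DISTANCE_EDGES = (0.0, 500.0, 1000.0, 2000.0, 5000.0, 10000.0, np.inf)


@dataclass(frozen=True)
class ColocConfig:
    window: int = 2000
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.n_runs < 1:
            raise ValueError("need at least one null run")


@dataclass
class ColocResult:
    observed: float
    null_fractions: np.ndarray = field(repr=False)
    null_mean: float = 0.0
    null_sd: float = 0.0
    fold: float = 0.0
    p_empirical: float = 1.0
    n_features: int = 0
    window: int = 2000

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold": self.fold,
            "p_empirical": self.p_empirical,
            "n_features": self.n_features,
            "window": self.window,
            "n_runs": int(len(self.null_fractions)),
        }


def _gap_distances(
    f_starts: np.ndarray, f_ends: np.ndarray, t_starts: np.ndarray, t_ends: np.ndarray
) -> np.ndarray:
    """Edge-to-edge distances from each feature interval to the nearest of a
    sorted, merged target list on the same chromosome."""
    m = len(t_starts)
    if m == 0:
        return np.full(len(f_starts), np.inf)
    idx_r = np.searchsorted(t_starts, f_ends, side="left")
    right = np.where(idx_r < m, t_starts[np.minimum(idx_r, m - 1)] - f_ends, np.inf)
    idx_l = np.searchsorted(t_ends, f_starts, side="right") - 1
    left = np.where(idx_l >= 0, f_starts - t_ends[np.maximum(idx_l, 0)], np.inf)
    d = np.minimum(right, left).astype(float)
    # overlap: the last target starting before the feature end reaches past its start
    idx_o = idx_r - 1
    has = idx_o >= 0
    overlap = has & (t_ends[np.maximum(idx_o, 0)] > f_starts)
    d[overlap] = 0.0
    return np.maximum(d, 0.0)


def nearest_distances(features, targets: RegionSet) -> np.ndarray:
    """Distance from every feature region to its nearest target, in feature
    sort order. +inf where the feature's chromosome has no targets."""
    if not targets.is_merged:
        raise ValueError("targets must be a merged RegionSet")
    tv = targets.by_chrom()
    feats = sorted(features, key=lambda r: (r.chrom, r.start, r.end))
    out = np.empty(len(feats))
    pos = 0
    i = 0
    while i < len(feats):
        chrom = feats[i].chrom
        j = i
        while j < len(feats) and feats[j].chrom == chrom:
            j += 1
        fs = np.asarray([f.start for f in feats[i:j]], dtype=np.int64)
        fe = np.asarray([f.end for f in feats[i:j]], dtype=np.int64)
        if chrom in tv:
            arr = tv[chrom]
            out[pos : pos + (j - i)] = _gap_distances(fs, fe, arr[:, 0], arr[:, 1])
        else:
            out[pos : pos + (j - i)] = np.inf
        pos += j - i
        i = j
    return out


def nearest_distance(region: Region, targets: RegionSet) -> float:
    """Distance from one region to the nearest target (0 on overlap)."""
    return float(nearest_distances([region], targets)[0])


def proximity_fraction(features, targets: RegionSet, window: int) -> float:
    """Fraction of feature regions within ``window`` bp of any target."""
    feats = list(features)
    if not feats:
        raise ValueError("proximity fraction is undefined for an empty feature set")
    d = nearest_distances(feats, targets)
    return float(np.mean(d <= window))


def randomize_size_matched(
    features, layout: GenomeLayout, seed_or_rng
) -> RegionSet:
    """One uniformly-placed random region per feature, same length, same
    chromosome; placements independent (overlaps permitted)."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = []
    for f in sorted(features, key=lambda r: (r.chrom, r.start, r.end)):
        chrom_len = layout.length_of(f.chrom)
        if f.length > chrom_len:
            raise ValueError(
                f"feature of length {f.length} exceeds {f.chrom} length {chrom_len}"
            )
        start = int(rng.integers(0, chrom_len - f.length + 1))
        out.append(Region(f.chrom, start, start + f.length))
    return RegionSet(out, merged=False)


def coloc_test(
    features, targets: RegionSet, layout: GenomeLayout, config: ColocConfig
) -> ColocResult:
    """Observed proximity fraction vs. R size-matched randomized feature sets.

    Reports the null mean/SD, fold enrichment (observed / null mean) and the
    add-one empirical p-value ``(1 + #{null >= observed}) / (R + 1)``.
    """
    feats = list(features)
    observed = proximity_fraction(feats, targets, config.window)
    rng = np.random.default_rng(config.seed)
    null = np.empty(config.n_runs)
    for r in range(config.n_runs):
        rand = randomize_size_matched(feats, layout, rng)
        null[r] = proximity_fraction(rand, targets, config.window)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if config.n_runs > 1 else 0.0
    fold = float(observed / null_mean) if null_mean > 0 else float("inf")
    p = float((1 + np.sum(null >= observed)) / (config.n_runs + 1))
    return ColocResult(
        observed=observed,
        null_fractions=null,
        null_mean=null_mean,
        null_sd=null_sd,
        fold=fold,
        p_empirical=p,
        n_features=len(feats),
        window=config.window,
    )


def floor_to_one(values: np.ndarray) -> np.ndarray:
    """Box-plot convention for ratio summaries: values below 1 become 1."""
    return np.maximum(np.asarray(values, dtype=float), 1.0)


def distance_profile(
    ratio_track: RatioTrack,
    features: RegionSet,
    distance_bin_edges=DEFAULT_DISTANCE_EDGES,
) -> pd.DataFrame:
    """Box statistics of the floored enrichment ratio as a function of each
    genomic bin's distance to the nearest feature region.

    Every grid bin is assigned the edge-to-edge distance from its span to the
    nearest feature; ratio values are floored at 1; per distance bin the
    median, quartiles, 95th-percentile whisker, mean and n are reported.
    """
    if len(features) == 0:
        raise ValueError("distance profile requires a non-empty feature set")
    if not features.is_merged:
        raise ValueError("features must be a merged RegionSet")
    edges = np.asarray(distance_bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("distance bin edges must be strictly increasing")
    grid = ratio_track.grid
    fv = features.by_chrom()
    dist_parts, val_parts = [], []
    for chrom in grid.layout.names:
        starts = grid.bin_starts(chrom)
        ends = grid.bin_ends(chrom)
        if chrom in fv:
            arr = fv[chrom]
            d = _gap_distances(starts, ends, arr[:, 0], arr[:, 1])
        else:
            d = np.full(len(starts), np.inf)
        dist_parts.append(d)
        val_parts.append(floor_to_one(ratio_track.data[chrom]))
    dist = np.concatenate(dist_parts)
    vals = np.concatenate(val_parts)

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        # an unbounded final bin also collects bins on chromosomes with no
        # features at all (infinite distance)
        sel = (dist >= lo) & ((dist < hi) | (np.isinf(hi) & np.isinf(dist)))
        v = vals[sel]
        rows.append(
            {
                "dist_lo": lo,
                "dist_hi": hi,
                "n": int(sel.sum()),
                "mean": float(v.mean()) if len(v) else np.nan,
                "median": float(np.median(v)) if len(v) else np.nan,
                "q1": float(np.quantile(v, 0.25)) if len(v) else np.nan,
                "q3": float(np.quantile(v, 0.75)) if len(v) else np.nan,
                "p95": float(np.quantile(v, 0.95)) if len(v) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def intersect_tracks(a: RegionSet, b: RegionSet) -> RegionSet:
    """Double-feature track: maximal intervals covered by both feature sets,
    with contiguous (abutting) results treated as one feature region."""
    return intersect(a, b)


def _mean_floored_ratio(ratio_track: RatioTrack, regions: RegionSet) -> float:
    grid = ratio_track.grid
    total, n = 0.0, 0
    w = grid.width
    for chrom, arr in regions.by_chrom().items():
        mask = np.zeros(grid.n_bins(chrom), dtype=bool)
        for s, e in arr:
            mask[s // w : (e + w - 1) // w] = True
        v = floor_to_one(ratio_track.data[chrom][mask])
        total += float(v.sum())
        n += len(v)
    return total / n if n else float("nan")


def additivity_compare(ratio_track: RatioTrack, a: RegionSet, b: RegionSet) -> dict:
    """Mean floored ratio over bins in A, in B, and in the double-feature
    track A∩B, with pairwise differences (descriptive, no significance test)."""
    inter = intersect_tracks(a, b)
    mean_a = _mean_floored_ratio(ratio_track, a)
    mean_b = _mean_floored_ratio(ratio_track, b)
    empty = len(inter) == 0
    mean_i = float("nan") if empty else _mean_floored_ratio(ratio_track, inter)
    return {
        "mean_a": mean_a,
        "mean_b": mean_b,
        "mean_intersection": mean_i,
        "intersection_empty": empty,
        "diff_intersection_minus_a": mean_i - mean_a if not empty else float("nan"),
        "diff_intersection_minus_b": mean_i - mean_b if not empty else float("nan"),
        "intersection_bp": inter.covered_bp,
    }
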