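"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity with the most literal possible algorithm
(per-read loops, per-bp bitmaps, exhaustive scans, textbook formulas) so it
stays independent of the vectorized implementation paths it checks.
"""

import numpy as np


def brute_count_midpoint(alignments, grid):
    """Per-read loop assigning each read to the bin holding its midpoint."""
    counts = {c: np.zeros(grid.n_bins(c)) for c in grid.layout.names}
    for a in alignments:
        mid = (a.start + a.end) // 2
        counts[a.chrom][mid // grid.width] += 1
    return counts


def brute_gaussian_smooth(values, sigma, radius):
    """Direct discrete convolution with a truncated, renormalized kernel;
    chromosome ends renormalize over in-bounds bins."""
    n = len(values)
    r = int(np.ceil(radius * sigma))
    if sigma == 0 or r == 0:
        return np.asarray(values, dtype=float).copy()
    weights = np.array([np.exp(-0.5 * (k / sigma) ** 2) for k in range(-r, r + 1)])
    weights = weights / weights.sum()
    out = np.zeros(n)
    for i in range(n):
        acc = wsum = 0.0
        for k in range(-r, r + 1):
            j = i + k
            if 0 <= j < n:
                acc += weights[k + r] * values[j]
                wsum += weights[k + r]
        out[i] = acc / wsum
    return out


def coverage_bitmap(regions, layout):
    """Per-bp boolean coverage arrays (the bitmap oracle for set algebra)."""
    bits = {c: np.zeros(layout.length_of(c), dtype=bool) for c in layout.names}
    for r in regions:
        bits[r.chrom][r.start : r.end] = True
    return bits


def bitmap_to_intervals(bits):
    """Maximal runs of True per chromosome as (chrom, start, end) tuples."""
    out = []
    for chrom, b in bits.items():
        padded = np.concatenate([[False], b, [False]])
        d = np.diff(padded.astype(int))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return sorted(out)


def brute_nearest_distance(region, targets):
    """Exhaustive pairwise scan; edge-to-edge gap, 0 on overlap."""
    best = np.inf
    for t in targets:
        if t.chrom != region.chrom:
            continue
        if t.start < region.end and t.end > region.start:
            return 0.0
        gap = max(t.start - region.end, region.start - t.end)
        best = min(best, gap)
    return float(best)


def brute_chi_square(table):
    """Textbook Pearson chi-square of homogeneity, summed term by term."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df


def brute_fdr_table(track, config):
    """Same-definition resampling estimate of the threshold-vs-FDR table,
    written as plain loops. Uses the same named random substreams as the
    implementation so the two must agree bin for bin."""
    from orimark.peaks import _chrom_rng, _null_values
    from orimark.tracks import smooth_values

    chroms = list(track.grid.layout.names)
    raw = {c: np.asarray(track.data[c], dtype=float) for c in chroms}
    smoothed = np.concatenate(
        [smooth_values(raw[c], config.sigma_bins, config.truncation_radius) for c in chroms]
    )
    qs = np.linspace(0.0, 1.0, config.n_thresholds + 1)[1:]
    thresholds = np.unique(np.quantile(smoothed, qs))
    observed = np.array([(smoothed >= t).sum() for t in thresholds], dtype=float)
    null_mean = np.zeros(len(thresholds))
    for run in range(config.n_randomizations):
        parts = []
        for chrom in chroms:
            rng = _chrom_rng(config.seed, run, chrom)
            parts.append(
                smooth_values(_null_values(raw[chrom], rng, config.null_mode),
                              config.sigma_bins, config.truncation_radius)
            )
        pooled = np.concatenate(parts)
        for i, t in enumerate(thresholds):
            null_mean[i] += (pooled >= t).sum()
    null_mean /= config.n_randomizations
    fdr_raw = null_mean / np.maximum(observed, 1.0)
    fdr = np.minimum.accumulate(np.minimum(fdr_raw, 1.0))
    return thresholds, observed, null_mean, fdr
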