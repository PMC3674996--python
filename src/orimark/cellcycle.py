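"""Cell-cycle phase-resolved analysis of chromatin-mark region sets.

Phase sets (G1, S, G2) for one mark are compared at bp level: the "S-only"
set is everything covered by the mark in S-phase but in neither G1 nor G2
(region boundaries shift between phases, so identity is defined by coverage,
not by whole-region matching). Per-phase bin-association counts feed a
marks-by-phases contingency table whose homogeneity is assessed with a
Pearson chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ColocConfig, ColocResult, coloc_test
from .genome import BinGrid, GenomeLayout
from .intervals import Region, RegionSet, subtract, union
from .peaks import count_associated_bins

PHASES = ("G1", "S", "G2")


def phase_only_set(
    sets: dict[str, RegionSet], phase: str, min_width: int = 100
) -> RegionSet:
    """bp-level set difference: coverage present in ``phase`` but in neither
    of the other two phases; fragments narrower than ``min_width`` bp are
    dropped to avoid jitter slivers."""
    for p in PHASES:
        if p not in sets:
            raise ValueError(f"missing phase {p!r}")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    others = [p for p in PHASES if p != phase]
    diff = subtract(sets[phase], union(sets[others[0]], sets[others[1]]))
    kept = [r for r in diff if r.length >= min_width]
    return RegionSet(kept, merged=True)


def build_phase_count_table(
    peak_sets: dict[str, dict[str, RegionSet]], grid: BinGrid
) -> pd.DataFrame:
    """Marks-by-phases table of bin-association counts.

    ``peak_sets`` maps mark name -> phase -> merged RegionSet; the entry for
    (mark, phase) is the number of grid bins intersecting that phase's peaks.
    """
    rows = {}
    for mark, phases in peak_sets.items():
        row = {}
        for phase in PHASES:
            if phase not in phases:
                raise ValueError(f"mark {mark!r} missing phase {phase!r}")
            row[phase] = count_associated_bins(phases[phase], grid)
        rows[mark] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(PHASES))


def chi_square_phase_homogeneity(table) -> tuple[float, int, float]:
    """Pearson chi-square of homogeneity on a 2-marks-by-phases count table.

    Returns ``(statistic, df, p)`` with the upper-tail p-value; no continuity
    correction is applied.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError("expected a 2 x k table of counts (k >= 2)")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero row/column marginal: chi-square is undefined")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def phase_coloc(
    sets: dict[str, RegionSet],
    targets: RegionSet,
    layout: GenomeLayout,
    config: ColocConfig,
    s_only_min_width: int = 100,
) -> dict[str, ColocResult]:
    """Colocalization test per phase set plus the derived S-only set.

    All rows share one fixed target set and the same configured seed, so
    identical inputs give identical results.
    """
    results = {}
    for phase in PHASES:
        results[phase] = coloc_test(sets[phase], targets, layout, config)
    s_only = phase_only_set(sets, "S", min_width=s_only_min_width)
    if len(s_only):
        results["S-only"] = coloc_test(s_only, targets, layout, config)
    return results
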