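"""Proximity colocalization, randomized nulls, distance profiles,
and double-feature intersection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from orimark import (
    BinGrid,
    ColocConfig,
    GenomeLayout,
    RatioTrack,
    Region,
    RegionSet,
    additivity_compare,
    coloc_test,
    distance_profile,
    intersect_tracks,
    merge,
    nearest_distance,
    nearest_distances,
    proximity_fraction,
    randomize_size_matched,
)


# ---------------------------------------------------------------------------
# nearest distance


def test_nearest_distance_overlap_and_gap():
    targets = merge([Region("chr1", 150, 300)])
    assert nearest_distance(Region("chr1", 100, 200), targets) == 0
    assert nearest_distance(Region("chr1", 100, 140), targets) == 10
    targets2 = merge([Region("chr1", 250, 300)])
    assert nearest_distance(Region("chr1", 100, 200), targets2) == 50


def test_nearest_distance_infinite_without_targets_on_chromosome():
    targets = merge([Region("chr2", 0, 10)])
    assert nearest_distance(Region("chr1", 0, 10), targets) == np.inf


@given(st.integers(0, 2**31 - 1))
def test_nearest_distances_match_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    chroms = ("chr1", "chr2")
    feats = [
        Region(chroms[int(rng.integers(2))], s := int(rng.integers(0, 9_900)), s + int(rng.integers(1, 100)))
        for _ in range(40)
    ]
    targets = merge(
        Region(chroms[int(rng.integers(2))], s := int(rng.integers(0, 9_900)), s + int(rng.integers(1, 100)))
        for _ in range(25)
    )
    got = nearest_distances(feats, targets)
    feats_sorted = sorted(feats, key=lambda r: (r.chrom, r.start, r.end))
    expected = [oracles.brute_nearest_distance(f, targets) for f in feats_sorted]
    np.testing.assert_allclose(got, expected)


# ---------------------------------------------------------------------------
# proximity fraction


def test_proximity_fraction_extremes(layout_small):
    targets = merge([Region("chr1", 1000, 2000), Region("chr1", 50_000, 51_000)])
    assert proximity_fraction(list(targets), targets, 2000) == 1.0
    far = [Region("chr1", 10_000, 10_100)]
    assert proximity_fraction(far, targets, 2000) == 0.0
    with pytest.raises(ValueError, match="empty"):
        proximity_fraction([], targets, 2000)


def test_proximity_fraction_monotone_in_window(rng):
    targets = merge(
        Region("chr1", s := int(rng.integers(0, 90_000)), s + 500) for _ in range(10)
    )
    feats = [Region("chr1", s := int(rng.integers(0, 99_000)), s + 300) for _ in range(50)]
    fracs = [proximity_fraction(feats, targets, w) for w in (0, 100, 500, 2000, 10_000)]
    assert fracs == sorted(fracs)


# ---------------------------------------------------------------------------
# size-matched randomization


def test_randomization_preserves_length_multiset_per_chromosome(layout_small, rng):
    feats = [
        Region(c, s := int(rng.integers(0, 40_000)), s + int(rng.integers(100, 5000)))
        for c in ("chr1", "chr2")
        for _ in range(20)
    ]
    rand = randomize_size_matched(feats, layout_small, 123)
    for chrom in ("chr1", "chr2"):
        got = sorted(r.length for r in rand if r.chrom == chrom)
        want = sorted(f.length for f in feats if f.chrom == chrom)
        assert got == want


def test_randomization_seed_determinism(layout_small):
    feats = [Region("chr1", 0, 1000), Region("chr2", 100, 400)]
    a = randomize_size_matched(feats, layout_small, 7)
    b = randomize_size_matched(feats, layout_small, 7)
    c = randomize_size_matched(feats, layout_small, 8)
    assert a == b
    assert a != c


def test_feature_longer_than_chromosome_is_error(layout_small):
    with pytest.raises(ValueError, match="exceeds"):
        randomize_size_matched([Region("chr2", 0, 60_000)], layout_small, 0)


def test_random_placement_matches_closed_form_geometry():
    """For one target of length T on a G-bp chromosome, a random L-bp feature
    lies within w of it with probability ~ (T + 2w + L) / (G - L + 1)."""
    G, T, w, L = 1_000_000, 10_000, 2000, 1000
    layout = GenomeLayout(("chr1",), (G,))
    targets = merge([Region("chr1", 400_000, 400_000 + T)])
    feats = [Region("chr1", 0, L)]
    runs = 10_000
    rng = np.random.default_rng(99)
    hits = 0
    for _ in range(runs):
        rand = randomize_size_matched(feats, layout, rng)
        hits += nearest_distances(list(rand), targets)[0] <= w
    expected = (T + 2 * w + L) / (G - L + 1)  # ~ 0.01502
    se = np.sqrt(expected * (1 - expected) / runs)
    assert abs(hits / runs - expected) <= 3 * se


# ---------------------------------------------------------------------------
# coloc test


def test_coloc_identical_sets_gives_extreme_result(layout_small, rng):
    feats = merge(
        Region("chr1", s := int(rng.integers(0, 90_000)), s + 500) for _ in range(12)
    )
    cfg = ColocConfig(window=2000, n_runs=99, seed=5)
    res = coloc_test(feats, feats, layout_small, cfg)
    assert res.observed == 1.0
    assert res.p_empirical == pytest.approx(1 / 100)
    assert res.fold > 1
    assert res.fold == pytest.approx(1 / res.null_mean)


def test_coloc_p_value_range_and_reproducibility(layout_small, rng):
    feats = [Region("chr1", s := int(rng.integers(0, 99_000)), s + 200) for _ in range(15)]
    targets = merge([Region("chr1", 30_000, 35_000)])
    cfg = ColocConfig(window=1000, n_runs=50, seed=42)
    r1 = coloc_test(feats, targets, layout_small, cfg)
    r2 = coloc_test(feats, targets, layout_small, cfg)
    assert np.array_equal(r1.null_fractions, r2.null_fractions)
    assert 1 / 51 <= r1.p_empirical <= 1.0


# ---------------------------------------------------------------------------
# distance profile


def _ratio_track(grid, value=1.0):
    return RatioTrack(
        grid, {c: np.full(grid.n_bins(c), float(value)) for c in grid.layout.names}
    )


def test_profile_of_constant_track_is_flat(grid_small):
    feats = merge([Region("chr1", 10_000, 12_000)])
    prof = distance_profile(_ratio_track(grid_small, 1.0), feats)
    filled = prof[prof["n"] > 0]
    assert (filled["median"] == 1.0).all()
    assert (filled["mean"] == 1.0).all()
    assert prof["n"].sum() == grid_small.total_bins


def test_profile_floors_values_below_one(grid_small):
    track = _ratio_track(grid_small, 0.4)
    feats = merge([Region("chr1", 0, 1000)])
    prof = distance_profile(track, feats)
    assert (prof[prof["n"] > 0]["mean"] == 1.0).all()


def test_profile_elevated_near_features(grid_small):
    track = _ratio_track(grid_small, 1.0)
    feats = merge([Region("chr1", 50_000, 52_000)])
    # elevate the ratio only within 500 bp of the feature
    track.data["chr1"][495:525] = 5.0
    prof = distance_profile(track, feats).set_index("dist_lo")
    near = prof.loc[0.0, "mean"]
    far = prof.loc[5000.0, "mean"]
    assert near > far


def test_profile_with_feature_everywhere_has_single_distance_bin(grid_small):
    feats = merge(
        [Region(c, 0, grid_small.layout.length_of(c)) for c in grid_small.layout.names]
    )
    prof = distance_profile(_ratio_track(grid_small), feats)
    assert prof.loc[0, "n"] == grid_small.total_bins
    assert (prof["n"][1:] == 0).all()


def test_profile_rejects_empty_features(grid_small):
    with pytest.raises(ValueError, match="empty"):
        distance_profile(_ratio_track(grid_small), RegionSet(merged=True))


# ---------------------------------------------------------------------------
# double-feature intersection & additivity


def test_intersect_tracks_examples():
    a = merge([Region("chr1", 0, 100)])
    b = merge([Region("chr1", 50, 150)])
    assert [(r.start, r.end) for r in intersect_tracks(a, b)] == [(50, 100)]
    disjoint = merge([Region("chr1", 500, 600)])
    assert len(intersect_tracks(a, disjoint)) == 0


@given(st.integers(0, 2**31 - 1))
def test_intersect_commutative_associative_idempotent(seed):
    rng = np.random.default_rng(seed)
    layout = GenomeLayout(("chr1",), (100_000,))

    def rand_set():
        return merge(
            Region("chr1", s := int(rng.integers(0, 95_000)), s + int(rng.integers(1, 4000)))
            for _ in range(int(rng.integers(0, 12)))
        )

    a, b, c = rand_set(), rand_set(), rand_set()
    assert intersect_tracks(a, b) == intersect_tracks(b, a)
    assert intersect_tracks(intersect_tracks(a, b), c) == intersect_tracks(
        a, intersect_tracks(b, c)
    )
    assert intersect_tracks(a, a) == a
    inter = intersect_tracks(a, b)
    assert inter.covered_bp <= min(a.covered_bp, b.covered_bp)
    bits_a = oracles.coverage_bitmap(a, layout)["chr1"]
    bits_b = oracles.coverage_bitmap(b, layout)["chr1"]
    assert [(r.chrom, r.start, r.end) for r in inter] == oracles.bitmap_to_intervals(
        {"chr1": bits_a & bits_b}
    )


def test_additivity_identity_and_constant(grid_small):
    a = merge([Region("chr1", 10_000, 15_000), Region("chr2", 0, 3000)])
    rec = additivity_compare(_ratio_track(grid_small, 1.0), a, a)
    assert rec["mean_a"] == rec["mean_b"] == rec["mean_intersection"] == 1.0
    assert rec["diff_intersection_minus_a"] == 0.0


def test_additivity_flags_empty_intersection(grid_small):
    a = merge([Region("chr1", 0, 1000)])
    b = merge([Region("chr1", 5000, 6000)])
    rec = additivity_compare(_ratio_track(grid_small), a, b)
    assert rec["intersection_empty"]
    assert np.isnan(rec["mean_intersection"])


def test_independent_coincident_features_are_additive_not_synergistic(grid_small):
    """Two marks that independently coincide with elevated-ratio sites: the
    double-feature mean matches the single-feature means (no synergy)."""
    track = _ratio_track(grid_small, 1.0)
    rng = np.random.default_rng(3)
    sites = [int(s) for s in rng.integers(50, 950, 30) * 100]
    for s in sites:
        track.data["chr1"][s // 100 - 2 : s // 100 + 2] = 6.0
    a = merge(Region("chr1", s - 300, s + 300) for s in sites[:20])
    b = merge(Region("chr1", s - 250, s + 350) for s in sites[10:])
    rec = additivity_compare(track, a, b)
    assert rec["mean_intersection"] <= 1.15 * max(rec["mean_a"], rec["mean_b"])
    assert rec["mean_intersection"] >= 0.85 * max(rec["mean_a"], rec["mean_b"])
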