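"""Read counting, RPKM normalization, smoothing, and enrichment ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from orimark import (
    BinGrid,
    GenomeLayout,
    SignalTrack,
    TagAlignment,
    compute_rpkm,
    count_reads_per_bin,
    enrichment_ratio,
    gaussian_smooth,
)
from orimark.tracks import smooth_values


def track_of(grid, chrom_values, total_reads=None):
    return SignalTrack(grid, {c: np.asarray(v, float) for c, v in chrom_values.items()},
                       total_reads=total_reads)


# ---------------------------------------------------------------------------
# count_reads_per_bin


def test_midpoint_assignment_single_read(grid_small):
    track = count_reads_per_bin([TagAlignment("chr1", 120, 156)], grid_small)
    assert track.data["chr1"][1] == 1  # midpoint 138 -> bin 1
    assert track.pooled().sum() == 1


def test_counts_are_additive(grid_small):
    reads = [TagAlignment("chr1", 500, 536)] * 10
    track = count_reads_per_bin(reads, grid_small)
    assert track.data["chr1"][5] == 10


def test_empty_alignment_stream_warns_and_is_zero(grid_small):
    with pytest.warns(UserWarning, match="no alignments"):
        track = count_reads_per_bin([], grid_small)
    assert track.pooled().sum() == 0


@given(st.integers(0, 2**31 - 1))
def test_midpoint_counting_matches_per_read_oracle_and_conserves(seed):
    layout = GenomeLayout(("chr1", "chr2"), (10_000, 3_000))
    grid = BinGrid(layout, 100)
    rng = np.random.default_rng(seed)
    reads = []
    for _ in range(int(rng.integers(1, 400))):
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        start = int(rng.integers(0, layout.length_of(chrom) - 36))
        reads.append(TagAlignment(chrom, start, start + 36))
    track = count_reads_per_bin(reads, grid)
    expected = oracles.brute_count_midpoint(reads, grid)
    for c in layout.names:
        np.testing.assert_array_equal(track.data[c], expected[c])
    assert track.pooled().sum() == len(reads)  # conservation


def test_overlap_rule_distributes_fraction_of_read(grid_small):
    track = count_reads_per_bin(
        [TagAlignment("chr1", 90, 126)], grid_small, assignment_rule="overlap"
    )
    np.testing.assert_allclose(track.data["chr1"][0], 10 / 36)
    np.testing.assert_allclose(track.data["chr1"][1], 26 / 36)
    np.testing.assert_allclose(track.pooled().sum(), 1.0)


# ---------------------------------------------------------------------------
# RPKM


def test_rpkm_direct_formula(grid_small):
    counts = SignalTrack.zeros(grid_small, total_reads=1_000_000)
    counts.data["chr1"][3] = 10
    rpkm = compute_rpkm(counts)
    assert rpkm.data["chr1"][3] == pytest.approx(100.0)  # 10 / (0.1 kb * 1 M reads)
    assert rpkm.data["chr1"][0] == 0.0


def test_rpkm_uses_true_length_of_short_edge_bin():
    layout = GenomeLayout(("chr1",), (250,))
    grid = BinGrid(layout, 100)
    counts = SignalTrack(grid, {"chr1": np.array([0.0, 0.0, 5.0])}, total_reads=1_000_000)
    rpkm = compute_rpkm(counts)
    assert rpkm.data["chr1"][2] == pytest.approx(5 / (0.050 * 1.0))


def test_rpkm_scale_invariance(grid_small, rng):
    data = {c: rng.integers(0, 20, grid_small.n_bins(c)).astype(float)
            for c in grid_small.layout.names}
    a = compute_rpkm(track_of(grid_small, data, total_reads=50_000))
    doubled = {c: 2 * v for c, v in data.items()}
    b = compute_rpkm(track_of(grid_small, doubled, total_reads=100_000))
    for c in grid_small.layout.names:
        np.testing.assert_allclose(a.data[c], b.data[c])


def test_rpkm_requires_positive_total(grid_small):
    with pytest.raises(ValueError, match="total mapped reads"):
        compute_rpkm(SignalTrack.zeros(grid_small, total_reads=0))


# ---------------------------------------------------------------------------
# Gaussian smoothing


def test_smoothing_preserves_constant_track(grid_small):
    track = track_of(grid_small, {c: np.full(grid_small.n_bins(c), 3.5)
                                  for c in grid_small.layout.names})
    for sigma in (0.5, 2.0, 7.0):
        sm = gaussian_smooth(track, sigma)
        for c in grid_small.layout.names:
            np.testing.assert_allclose(sm.data[c], 3.5, rtol=1e-12)


def test_sigma_zero_is_identity(grid_small, rng):
    data = {c: rng.random(grid_small.n_bins(c)) for c in grid_small.layout.names}
    track = track_of(grid_small, data)
    sm = gaussian_smooth(track, 0.0)
    for c in grid_small.layout.names:
        np.testing.assert_array_equal(sm.data[c], track.data[c])


def test_negative_sigma_is_error(grid_small):
    with pytest.raises(ValueError, match="sigma"):
        gaussian_smooth(SignalTrack.zeros(grid_small), -1.0)


def test_delta_response_matches_convolution_oracle():
    values = np.zeros(200)
    values[80] = 1.0
    got = smooth_values(values, 2.0, 4.0)
    expected = oracles.brute_gaussian_smooth(values, 2.0, 4.0)
    np.testing.assert_allclose(got, expected, atol=1e-12)
    # peak equals the renormalized kernel's center weight
    from orimark.tracks import gaussian_kernel

    assert got[80] == pytest.approx(gaussian_kernel(2.0, 4.0).max())


@given(st.integers(0, 2**31 - 1), st.sampled_from([0.7, 2.0, 5.0]))
def test_smoothing_matches_oracle_on_random_tracks(seed, sigma):
    rng = np.random.default_rng(seed)
    values = rng.random(int(rng.integers(3, 300))) * 10
    got = smooth_values(values, sigma, 4.0)
    expected = oracles.brute_gaussian_smooth(values, sigma, 4.0)
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_interior_signal_is_conserved():
    values = np.zeros(500)
    values[240:260] = 7.0
    got = smooth_values(values, 2.0, 4.0)
    assert got.sum() == pytest.approx(values.sum(), rel=1e-9)


# ---------------------------------------------------------------------------
# enrichment ratio


def test_ratio_of_identical_positive_tracks_is_one(grid_small, rng):
    data = {c: rng.random(grid_small.n_bins(c)) + 0.1 for c in grid_small.layout.names}
    t = track_of(grid_small, data)
    ratio = enrichment_ratio(t, t, pseudocount=0.0)
    for c in grid_small.layout.names:
        np.testing.assert_allclose(ratio.data[c], 1.0)


def test_ratio_pseudocount_policy(grid_small):
    nascent = SignalTrack.zeros(grid_small)
    control = SignalTrack.zeros(grid_small)
    nascent.data["chr1"][0] = 2.0
    ratio = enrichment_ratio(nascent, control, pseudocount=0.5)
    assert ratio.data["chr1"][0] == pytest.approx(5.0)  # 2.5 / 0.5
    assert ratio.data["chr1"][1] == pytest.approx(1.0)


def test_ratio_zero_control_without_pseudocount_is_error(grid_small):
    nascent = SignalTrack.zeros(grid_small)
    control = SignalTrack.zeros(grid_small)
    with pytest.raises(ValueError, match="pseudocount"):
        enrichment_ratio(nascent, control, pseudocount=0.0)


def test_ratio_grid_mismatch_is_error(layout_small):
    a = SignalTrack.zeros(BinGrid(layout_small, 100))
    b = SignalTrack.zeros(BinGrid(layout_small, 200))
    with pytest.raises(ValueError, match="grid"):
        enrichment_ratio(a, b)
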