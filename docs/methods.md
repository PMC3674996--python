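# Methods

## Coordinate model

All coordinates are 0-based, half-open (BED-native) in every reader, writer
and internal structure; 1-based coordinates never appear outside log text.
Strand is parsed but ignored: every statistic here operates on strandless
coverage. Region sets are kept sorted by (chromosome, start); a *merged* set
is additionally non-overlapping and non-abutting — abutting intervals
(`end == next start`) are coalesced, i.e. contiguous regions count as one
feature region. Set algebra (merge, union, intersection, bp-level
difference) runs on sorted per-chromosome arrays and is property-tested
against per-bp boolean bitmap oracles.

## Signal tracks

**Binning.** Each chromosome is divided into fixed-width bins (default
100 bp; the terminal bin may be short). A read is assigned to the bin
containing its midpoint, so the total count equals the number of reads — a
conservation law the tests exploit. A bp-overlap weighting rule is available
(`assignment_rule="overlap"`), under which each read distributes one unit
across the bins it spans. Duplicate reads are not collapsed.

**RPKM.** `rpkm_i = c_i / ((L_i/1000) · (N/10^6))` with `L_i` the bin's true
length, so short terminal bins are not deflated, and `N` the track's total
assigned reads. RPKM is linear in counts and inversely linear in `N`.

**Smoothing.** A Gaussian kernel with σ expressed in bins (default 2 bins =
200 bp), truncated at ±4σ and renormalized to sum 1. Chromosome ends are
handled by renormalizing the kernel over in-bounds bins, so a constant track
is exactly preserved everywhere and interior signal is conserved. σ = 0 is
the identity. The defaults smooth at the scale of nucleosomal noise without
erasing 1–2 kb features; any result sensitive to σ should be reported with
it. Smoothing is implemented as an explicit truncated-kernel convolution
(rather than a library filter with fixed boundary modes) because the edge
renormalization is part of the contract; it is tested against a direct
convolution-loop oracle at 1e-9.

**Enrichment ratio.** `ratio_i = (nascent_i + ε)/(control_i + ε)` with a
symmetric pseudocount ε (default 0.5 RPKM) that keeps the null centered at 1
and the ratio finite where the control is empty. At realistic sequencing
depths a raw 100-bp control bin is frequently zero while ε is small relative
to per-read RPKM increments, which makes the raw-ratio distribution heavily
right-tailed; the pipeline therefore forms the ratio **between smoothed RPKM
tracks**, which removes the zero-control instability. ε = 0 is permitted
only when every control bin is positive.

## Enriched-region calling

The caller takes a binned track, smooths it internally (same kernel as
above), and keeps bins at or above a threshold chosen from an empirical
null:

* Null construction: the **raw** bin values of each chromosome are randomly
  permuted, then passed through the same smoothing. Any rearrangement of
  bins preserves the multiset of raw values, so the informative contrast is
  spatial: genuine signal is contiguous and survives smoothing, while
  permuted signal is diluted toward the mean. (A circular-shift mode is
  provided for completeness but shifts also preserve contiguity, so that
  null is nearly degenerate — its FDR is ≈ 1 at every threshold; the
  permutation null is the default for exactly this reason.)
* Candidate thresholds are quantiles of the smoothed observed values
  (scale-free across datasets). For each threshold `t`,
  `FDR(t) = mean over randomizations of #{null bins ≥ t} / max(#{observed bins ≥ t}, 1)`,
  capped at 1 and made monotone non-increasing in `t` by a running minimum.
* The calling threshold is the smallest `t` with regularized FDR at or below
  the target (most inclusive call satisfying the level); kept bins are
  joined across gaps up to `merge_gap` (default 200 bp) and regions narrower
  than `min_width` (default 200 bp) are dropped. Each region is scored by
  its mean smoothed signal.
* Per-chromosome random streams are keyed by chromosome *name*, so calls are
  bit-reproducible for a fixed seed and invariant to chromosome order. An
  all-constant track raises a degenerate-null error; a track where no
  threshold reaches the target returns an empty set with a warning.
* Raising the FDR target can only lower the threshold, so the kept-bin set
  and total called coverage grow monotonically; the *number* of regions need
  not (newly kept bins can bridge two regions into one), which is why the
  monotonicity property is asserted on coverage.

Replication initiation peaks are called on the ratio track at FDR 0.15;
chromatin-mark domains are called on ChIP RPKM tracks by the same machinery
(default FDR 0.15). The number of randomizations defaults to 20.

## Colocalization statistics

**Distance.** Edge-to-edge: 0 for overlapping or abutting intervals,
otherwise the end-to-start gap; "within w" means gap ≤ w (equivalent to
overlap after dilating targets by w). The proximity window defaults to
w = 2000 bp. Distances are computed by a sorted binary-search sweep and
verified against an exhaustive pairwise scan.

**Null.** Each feature is redrawn uniformly on its own chromosome with its
length preserved (start uniform on `[0, chromLen − len]`); placements are
independent and may overlap each other or the targets, and no
gap/blacklist exclusion is applied. For a single target of length T on a
G-bp chromosome and a feature of length L, the per-draw hit probability is
`(T + 2w + L)/(G − L + 1)` up to edge effects, which the implementation
matches within 3 standard errors over 10⁴ draws — the analytic anchor of
the whole statistic.

**Test.** Observed fraction vs. R = 100 null fractions: null mean and SD,
fold = observed/null mean, and the add-one empirical p
`(1 + #{null ≥ obs})/(R + 1)`, so p ∈ [1/(R+1), 1]. Analytic p-values are
deliberately not produced; at R = 100 the smallest reportable p is ~0.0099.

**Distance profile.** Every genomic bin gets the distance from its span to
the nearest feature region; ratio values are floored at 1 (the box-plot
convention for ratio summaries — applied only inside profile/additivity
summaries, never to stored tracks); per distance bin (defaults
[0,500), [500,1000), [1000,2000), [2000,5000), [5000,10⁴), [10⁴,∞)) the
median, quartiles, 95th-percentile whisker, mean and n are reported. Bins on
chromosomes with no features fall in the unbounded final bin.

**Double-feature additivity.** The intersection of two merged feature tracks
(abutting results joined) is compared descriptively: mean floored ratio over
bins in A, in B, and in A∩B, with differences — no significance test. Note
that if the single tracks are diluted by feature regions unrelated to the
targets, the intersection is less diluted and its mean rises for purely
compositional reasons; the synthetic demonstration therefore restricts both
tracks to their target-coincident regions before comparing.

## Cell-cycle analysis

Phase sets are compared at bp level because called-region boundaries shift
between phases. "S-only" = coverage in S minus the union of G1 and G2
coverage, re-merged, with fragments below a minimum width dropped. For exact
region sets the minimum is one bin (100 bp); **for called peaks the pipeline
uses 500 bp**, the scale of call-boundary uncertainty under the default
smoothing — per-phase read resampling jitters call edges by a few bins, and
at one bin the S-only set is dominated by these origin-adjacent slivers
rather than genuinely S-specific domains (on synthetic data, ≥500-bp
fragments are ~99% genuinely S-specific versus ~33% at 100 bp).

The marks-by-phases table counts, per (mark, phase), the grid bins whose
span intersects any called domain. Phase homogeneity of two marks is tested
with Pearson's chi-square (`scipy.stats.chi2_contingency`, no continuity
correction; df = 2 for three phases), cross-checked in the tests against a
term-by-term Σ(O−E)²/E sum. Colocalization rows for G1/S/S-only/G2 all use
one fixed replication-target set and a shared seed.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
these defaults chosen as the validation conditions: a 10-Mb genome in two
chromosomes (6 + 4 Mb), 100 origins (uniform placement; a fixed-grid mode
exists), 200 mark regions with lengths uniform on 500–3000 bp, association
probability ρ = 0.8, and 2×10⁵ reads of 36 bp per sample (the short
single-end regime of the platform era being emulated).

* **Origins and piles.** Nascent reads are a mixture: with probability
  `p_sig` a read is drawn from a symmetric triangular pile of half-width
  500 bp around a random origin, otherwise uniformly.
  `p_sig = (f−1)A/(G + (f−1)A)` (A = total pile bp, G = genome bp) makes the
  expected in-pile/background coverage ratio equal the configured fold
  f = 10. The control sample is uniform; ChIP samples use the same mixture
  with positions bp-uniform within that phase's mark regions. The 500-bp
  half-width puts the detectable ratio enrichment at the sub-kb scale the
  distance profiles probe.
* **Marks.** An origin-associated mark has its midpoint placed within
  w_assoc = 1000 bp of a random origin center — deliberately distinct from
  the 2000-bp analysis window, so parameter recovery is not tautological.
  Unassociated marks are uniform.
* **Phases.** G1 is the base set; G2 jitters each boundary by ≤50 bp
  (emulating call variation between biologically identical samples); S is
  the base set plus `round((s_expansion − 1)·M)` extra uniformly-placed,
  origin-unassociated marks whose widths are multiplied by the expansion
  factor (default 1.5). The expansion is attached to the extra marks rather
  than to the shared ones so that the added S coverage carries no origin
  signal — the construction whose consequences the phase analysis is
  supposed to detect (wider S distribution; S-only regions at chance
  association). An optional second "stable" mark with no expansion serves as
  the homogeneity control.
* **Reproducibility.** All randomness flows from one master seed through
  named substreams (origins, marks, jitter, one per read sample), so any
  component can be regenerated independently and emission is
  checksum-identical for a fixed seed. `truth.json` round-trips the planted
  truth exactly.

What the generator does **not** model: GC or mappability bias, fragment-size
effects, copy-number variation (the ratio corrects for it; the simulator
simply doesn't introduce it), chromatin-state autocorrelation beyond the
planted regions, or duplicate-read artifacts. Passing tests therefore show
that the statistics recover planted structure under idealized noise, not
that any specific biological dataset will reproduce published values.

## Pipeline

`run_full_analysis` composes the stages from one config: read loading →
RPKM → smoothing → ratio → replication peaks → per-phase mark domains →
colocalization table (overall + G1/S/S-only/G2) → bin-count table and
chi-square → distance profile. Every output is stamped with a content hash
of the config (excluding the output directory) and the seeds; a stage
failure aborts with the stage name while partial outputs are preserved; and
re-running an identical config reproduces the report byte for byte. Results
are written as one JSON report plus per-table TSVs for diffing.

## Sizes and determinism of the validation runs

The tests and the acceptance script run entirely on generated data: the
study-scale configuration above (~10⁵ bins, 5–8 read samples) for
end-to-end checks, 10⁴ draws for the analytic null, and ≤10⁵-bp layouts for
the oracle-equivalence properties. Every stochastic check is seeded;
hypothesis runs derandomized.

## Known limitations

* The empirical-FDR caller is scale-free but its permutation null assumes
  exchangeable background bins; strong background autocorrelation (real
  chromatin) makes the FDR estimate optimistic.
* Fold enrichment is undefined (reported as infinite) when the null mean is
  exactly 0; with 100 runs this occurs only for pathologically small target
  sets.
* The colocalization null preserves lengths and chromosome assignment but
  not local genomic context (no masking of gaps or blacklisted regions; a
  configurable exclusion mask is out of scope here).
* Bin-count tables depend on the calling FDR; comparisons across marks are
  meaningful only at matched calling parameters.
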