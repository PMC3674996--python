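# orimark

Analysis pipeline for asking whether a chromatin mark colocalizes with DNA
replication initiation sites, genome-wide and across the cell cycle.

Replication initiation sites are mapped by nascent-strand sequencing
(NS-Seq): short, RNA-primed nascent DNA is sequenced, and read pileups over a
matched genomic-control library mark origins of replication. Chromatin-mark
locations come from ChIP-Seq, optionally fractionated into G1, S and G2
populations. The question the statistics answer: do the mark's domains sit
near initiation sites more often than size-matched random regions would, and
does that association change through the cell cycle?

## What it computes

* **Binned RPKM tracks.** Aligned reads (BED) are counted into fixed 100-bp
  bins (midpoint rule) and normalized to reads per kilobase per million
  mapped reads: `RPKM_i = c_i / ((L_i/1000) · (N/10^6))`. A truncated,
  renormalized Gaussian kernel (σ = 2 bins) smooths the bin values.
* **Replication initiation ratio.** Per bin,
  `r_i = (NS_i + ε) / (control_i + ε)` on the smoothed RPKM tracks
  (pseudocount ε = 0.5); the ratio cancels sequencing bias and copy-number
  variation shared by the two libraries, so `r_i > 1` indicates initiation
  activity.
* **Enriched-region calling at an empirical FDR.** Bins whose smoothed value
  exceeds a threshold are kept, where the threshold is chosen so that
  `FDR(t) = E[null bins ≥ t] / #{observed bins ≥ t}` is at or below the
  target (15% for replication peaks). The null rearranges the raw bin values
  per chromosome and re-smooths them, destroying spatial clustering while
  preserving the value distribution.
* **Proximity colocalization.** The observed fraction of feature regions
  within w = 2000 bp (edge-to-edge) of a target peak is compared with the
  mean fraction over R = 100 *size-matched randomized* feature sets — each
  feature redrawn uniformly on its own chromosome with its length preserved.
  Reported: observed and null fractions, fold enrichment, and the add-one
  empirical p-value `(1 + #{null ≥ obs}) / (R + 1)`.
* **Distance profiles and double-feature additivity.** Box statistics of the
  initiation ratio (floored at 1) as a function of each bin's distance to
  the nearest feature; and mean floored ratio over the intersection of two
  feature tracks versus each single track.
* **Cell-cycle set algebra.** bp-level "S-only" regions (covered by the mark
  in S but in neither G1 nor G2), marks-by-phases bin-count tables, and a
  Pearson chi-square test of phase homogeneity between two marks.
* **Synthetic data with planted truth.** A generator produces a small genome
  with planted origins, nascent/control/ChIP read sets and phase-resolved
  mark regions at a controlled mark–origin association probability ρ, so the
  whole pipeline is testable without any external data and parameter
  recovery can be verified.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (large intermediates go to `scratch/`, tables to `results/`):

```bash
cd analysis
python 01_simulate.py && python 02_tracks.py && python 03_call_peaks.py
python 04_colocalization.py && python 05_cellcycle.py
```

On the default configuration (10-Mb genome, 100 origins, 200 mark regions
with planted association probability ρ = 0.8, 2×10⁵ reads/sample, seed 17)
this prints:

```
replication peaks: 100, origin recall 100.0%
      regions  observed_pct  null_mean_pct  null_sd_pct  fold  p_empirical  n_features
planted_marks         79.00           6.29         1.65 12.56     0.009901         200
    called_G1         65.74           6.81         2.70  9.66     0.009901         108
     called_S         37.86           7.17         1.64  5.28     0.009901         206
    called_G2         65.14           6.45         2.11 10.10     0.009901         109
called_S_only         13.59           7.35         2.67  1.85     0.029703         103
```

Reading this: 79% of the planted mark regions lie within 2 kb of a called
replication peak versus 6.3% expected by chance (fold 12.6, the smallest
achievable empirical p at 100 runs) — the pipeline recovers the planted
ρ = 0.8 plus chance hits. Phase-resolved, the G1 and G2 domains are strongly
origin-associated while the regions marked *only* in S-phase are not
(13.6% vs. a 7.4% null), and the bin-count table shows the mark covering
2.5× more bins in S than in G1 (5000 vs 1998), a phase redistribution the
chi-square test calls significant (χ² = 714.5, df = 2, p ≈ 7×10⁻¹⁵⁶).

The same operations are available as a CLI for real data
(`orimark simulate|bin|ratio|callpeaks|coloc|distprofile|run`), e.g.

```bash
orimark callpeaks --track ratio.bedgraph --genome g.sizes --fdr 0.15 --seed 17 --out peaks.bed
orimark coloc --features marks.bed --targets peaks.bed --genome g.sizes \
    --window 2000 --runs 100 --seed 17 --out coloc.json
```

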