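# Methods

`chromcompare` implements the comparative analysis of two transcription
factors' genome-wide binding landscapes measured by ChIP-seq — the setting
is a ubiquitous factor (B, e.g. CTCF) and a paralog with a near-identical
consensus (A, e.g. the testis-specific CTCFL/BORIS) — together with a
synthetic-data generator that plants every structure the analysis is meant
to detect.

## Coordinate conventions

All coordinates are 0-based, half-open (BED). The TSS of a minus-strand
gene is `end − 1`. A peak's *center* is its summit when recorded, otherwise
`floor((start + end) / 2)`. Adapters to/from 1-based closed coordinates are
provided and round-trip exactly.

## Site classification

Two peak sets A and B are partitioned into A-only / B-only / shared. A
peak of A is shared iff some peak of B overlaps it by at least
`min_overlap` bases (default 1 bp — the most permissive criterion and the
common convention for two-set Venn diagrams; the underlying study does not
define its intersection rule, so the threshold is exposed). Counting is
site-level: one A peak overlapping several B peaks is one shared site, and
the B-side shared count is reported separately so that both conservation
identities hold exactly:

    |A| = |A-only| + |shared_A|        |B| = |B-only| + |shared_B|

Peaks overlapping *within* one set are merged first (warning emitted);
without this the identities are ill-defined.

## Signal tracks, matrices and profiles

Reads are accepted as BED6 5′-position records. Each read is extended to a
fixed fragment length (default 200 bp; configurable — the fragment model of
the original analysis is unstated) from its 5′ end in its strand direction
and piled into base-resolution coverage; RPM normalization scales by
10⁶ / library size.

Signal around sites is summarized as a sites × bins matrix: 4-kb windows
centered on peak centers, 50-bp bins (80 columns), each cell the *mean*
per-base coverage in the bin so values are invariant to bin size. Sites
whose window leaves the chromosome are dropped, not zero-padded, to avoid
artificial edge depression in averages. Column means give the cumulative
profile; heatmap order is decreasing row mean with (chrom, start)
tie-break, so output is deterministic.

## Motif model and scanning

PWMs are built from equal-length aligned site sequences with a
background-proportional pseudocount (default weight 1):
`p_i(b) = (count + w·bg_b)/(n_valid + w)`; N bases are excluded from
counts. Scanning scores each window by natural-log odds
`Σ ln(p_i(w_i)/bg(w_i))` on both strands (reverse-strand windows scored on
the reverse complement, reported at forward coordinates); windows
containing N are skipped; all windows at or above the threshold are
reported with no overlap masking, since occurrence heatmaps count raw
predictions. The default threshold is 60% of the maximal achievable score:
with the generator's 20-bp motif and 5% per-position mutation rate this
admits up to 3 mismatches, giving ≈98% expected recovery of planted
instances while background hits on random sequence are rare (the analytic
false-hit probability per window, obtainable by exact convolution of the
per-position score distribution, is ~10⁻⁸). De novo motif discovery is out
of scope; PWMs come from user-provided aligned sites or JASPAR-style count
files.

## Gene-relative annotation

The signed distance from a site center to the nearest TSS is oriented by
the gene's strand (negative = upstream); nearest is by absolute distance
with ties broken toward the lexicographically smaller gene name. Distance
profiles are binned frequencies over ±40 kb; out-of-window sites are
excluded from numerator and denominator and reported. Genomic context is a
single category per site center with precedence
TSS > TES > exon > intron > intergenic; TSS/TES windows default to ±1 kb
(the original figure does not state its windows; configurable).

A gene is *bound* when some site center lies within −2 kb … +1 kb of its
TSS in gene orientation, both bounds inclusive. Expression comparisons use
the two-sided Mann–Whitney U test: exact by full enumeration of group
assignments when n₁+n₂ ≤ 12 (tie-safe), otherwise the normal approximation
with tie and continuity corrections. The rank-based choice reflects the
skewed, unit-free nature of log expression summaries; it is invariant
under monotone transforms.

## Competition analysis

For shared sites, the B factor's RPM signal is quantified as the mean
coverage over a 300-bp window around the peak center (a typical point-factor
footprint; configurable) in two conditions. Fold changes use a
pseudo-signal ε = 0.5 RPM to stabilize low-coverage ratios:
`log2fc = log2((s₂+ε)/(s₁+ε))`; sites are *up* above the 1.5× threshold,
*down* below 1/1.5, else unchanged. No variance model is fitted because
the emulated design has no replicates; the >1.5-fold rule is the entire
operationalization of "changed".

## Synthetic data generator

The generator's defaults are the package's study conditions: 2 chromosomes,
500 genes, 500 A sites, 2,000 B sites of width 300 bp, 300 shared, motifs
planted at 70% of sites (so motif-free sites exist, as observed in real
data) with 5% per-position mutation, H3-like reads at 200 per site plus
100k background, ChIP reads at Poisson(200) per site with N(0, 80 bp)
positional scatter, 100 shared sites planted 2-fold down and 20 planted
2-fold up in condition 2, and a +1.0 log2 expression shift for A-bound
genes. Chromosomes are 8 Mb each with a 4-kb minimum spacing between site
centers: with the ±2-kb analysis windows this keeps neighbouring sites'
planted chromatin shapes from bleeding into each other's windows, which a
denser layout would destroy. A-only sites are preferentially (70%)
retargeted into a random gene's strand-oriented promoter window, subject to
the exact minimum-spacing constraint.

Chromatin classes are sampled from per-class fragment-center densities over
±2 kb: A-only sites get a flat 4-fold depletion over ±600 bp (loosely
assembled promoter nucleosomes); B-only sites get a sharp central trough
flanked by Gaussian nucleosomes (σ = 20 bp) spaced at the 185-bp repeat;
shared sites an intermediate mixture. Reads are emitted so that rebuilding
coverage with the configured fragment extension reconstructs the sampled
fragments exactly.

All randomness flows from one `numpy` Generator seeded explicitly; the same
config and seed give byte-identical output files.

### What the generator does not emulate

Mappability and repeat structure, GC bias, sequencing errors, diploid
genomes, replicate variability, and peak-caller artifacts. Passing tests
therefore demonstrate correctness of the analysis operations and
recoverability of planted structure under idealized noise — not robustness
to every failure mode of real libraries.

## Numerical choices and known limitations

* Matrix/profile arithmetic is double precision; tests compare at 1e-9
  relative tolerance; integer outputs are exact and the pipeline is
  deterministic for fixed config+seed.
* The phasing-period estimate is the argmax of the discrete autocorrelation
  of the mean-removed cumulative profile over lags 100–300 bp at 50-bp bin
  resolution, so a 185-bp repeat is recovered as 200 bp (the nearest lattice
  point) — within one bin by construction.
* RPM normalization carries a composition bias: planting 100 half-strength
  sites among 600 shrinks the condition-2 library by ~8%, shifting every
  log2fc by ~+0.11 and attenuating measured folds. Detection of 2-fold
  changes at the 1.5-fold rule consequently runs at roughly 92–97%
  sensitivity across seeds with a false-positive rate near zero. A
  background-anchored normalization would remove the bias but is outside
  the emulated design, which prescribes library-size scaling only.
* Exact Mann–Whitney enumeration is limited to n₁+n₂ ≤ 12
  (≤ 924 assignments); beyond that the corrected normal approximation is
  accurate and the simulated type-I error at α = 0.05 calibrates to
  0.03–0.07.
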