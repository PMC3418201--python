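# chromcompare

Comparative analysis of two transcription factors' genome-wide ChIP-seq
binding landscapes. The motivating setting is a ubiquitous chromatin
organizer (CTCF) and a germline paralog binding a near-identical consensus
(CTCFL/BORIS): the interesting biology lives in how their site repertoires
overlap, what distinguishes the sites each factor claims for itself, and
what happens to one factor's binding when the other appears.

The package provides, as a tested library plus a `chromcompare` CLI:

* **Three-class site classification** — two peak sets are partitioned into
  A-only / B-only / shared by interval overlap (the two-set Venn of binding
  sites), with exact count conservation `|A| = |A-only| + |shared|`.
* **Signal matrices and cumulative profiles** — reads are extended to
  fragments, piled into coverage, and summarized in sites × bins matrices
  (default 80 bins of 50 bp spanning ±2 kb around peak centers); column
  means give average binding shapes, row ordering by decreasing mean gives
  the heatmap layout. Applied to histone H3 data this resolves
  nucleosome-depleted promoters versus sites flanked by phased nucleosomes.
* **PWM motif scanning** — Patser-style natural-log-odds scanning
  `score(w) = Σᵢ ln(pᵢ(wᵢ)/bg(wᵢ))` of both strands, with PWMs built from
  aligned bound-site sequences or JASPAR-style count files, and motif
  occurrences binned around sites in the same matrix layout.
* **Gene-relative annotation** — signed distance to the nearest TSS
  (gene-oriented, ±40-kb frequency profiles) and one-category genomic
  context (TSS > TES > exon > intron > intergenic).
* **Promoter-bound gene expression association** — a gene is bound when a
  site center lies in −2 kb … +1 kb of its TSS in gene orientation; bound
  versus unbound log2 expression is compared by a two-sided Mann–Whitney U
  test (exact by enumeration for small samples).
* **Competition analysis** — per-shared-site RPM signal of one factor in
  two conditions (± the competitor); sites beyond a 1.5-fold change are
  categorized up/down and summarized as log2-fold differences.
* **A synthetic-data generator** that plants all of the above — Venn
  structure, promoter-proximal A-only sites, mutated consensus motifs,
  nucleosome phasing at a 185-bp repeat, per-site fold changes, expression
  shifts — so the whole pipeline is testable with known ground truth.

## Worked example

```python
import chromcompare as cc
from chromcompare.synthetic import venn_fixture

peaks_a, peaks_b = venn_fixture(5_707, 37_691, 3_677)
result = cc.classify_sites(peaks_a, peaks_b)
print(result.counts)
print(f"{100 * result.shared_fraction_a:.1f}% of A sites shared,"
      f" {100 * result.shared_fraction_b:.1f}% of B sites shared")
```

prints

```
{'A_total': 5707, 'B_total': 37691, 'A_only': 2030, 'B_only': 34014,
 'shared': 3677, 'shared_B_side': 3677}
64.4% of A sites shared, 9.8% of B sites shared
```

i.e. of 5,707 A peaks and 37,691 B peaks, 3,677 reciprocally overlap:
64.4% of the smaller factor's sites coincide with the larger repertoire,
while only ~10% of the larger factor's sites are shared — the asymmetry
that motivates asking what the A-only sites look like.

Continuing on a generated study with planted chromatin structure:

```python
from chromcompare.synthetic import generate_fixture
import numpy as np

truth = generate_fixture(seed=1)
track = cc.normalize_track(cc.build_coverage(
    truth.h3_reads, truth.config.fragment_length, truth.chrom_sizes))
classes = cc.classify_sites(truth.peaks_a, truth.peaks_b)

matrix = cc.extract_matrix(track, classes.b_only)   # 1700 sites x 80 bins
profile = cc.cumulative_profile(matrix)
centered = profile - profile.mean()
lag = max(range(2, 7), key=lambda k: (centered[:-k] * centered[k:]).mean())
print("phasing period ≈", lag * 50, "bp")           # -> 200 bp
```

which recovers the planted 185-bp nucleosome repeat at the 50-bp bin
resolution, while the same profile around A-only sites shows a ~3-fold
H3 depletion over the promoter-proximal windows.

The same stages are available from the shell:

```bash
chromcompare simulate --seed 42 --out fixture/
chromcompare classify --a fixture/peaks_a.bed --b fixture/peaks_b.bed --out-prefix venn
chromcompare matrix --reads fixture/reads_h3.bed --sites venn_b_only.bed \
    --chrom-sizes fixture/chrom.sizes --out h3_matrix.tsv --sort
```

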