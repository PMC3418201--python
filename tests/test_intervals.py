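import numpy as np
import pytest
from scipy import stats

from chromcompare.intervals import (
    annotate_genomic_context,
    classify_sites,
    merge_overlapping,
    nearest_tss_distances,
    peak_center,
    tss_distance_profile,
)
from chromcompare.io import GeneModel, GenomicInterval, Peak


def mk_peak(chrom, start, end, summit=None):
    return Peak(GenomicInterval(chrom, start, end), summit=summit)


def random_disjoint_peaks(rng, n, span=100_000, chrom="chr1"):
    """n random non-overlapping intervals on a toy chromosome."""
    starts = np.sort(rng.choice(span // 100, size=n, replace=False)) * 100
    return [
        mk_peak(chrom, int(s), int(s) + int(rng.integers(10, 99))) for s in starts
    ]


def brute_force_classify(peaks_a, peaks_b, min_overlap=1):
    """All-pairs O(n^2) overlap oracle."""
    shared_a = [
        a
        for a in peaks_a
        if any(a.interval.overlap(b.interval) >= min_overlap for b in peaks_b)
    ]
    a_only = [a for a in peaks_a if a not in shared_a]
    shared_b = [
        b
        for b in peaks_b
        if any(b.interval.overlap(a.interval) >= min_overlap for a in peaks_a)
    ]
    b_only = [b for b in peaks_b if b not in shared_b]
    return a_only, b_only, shared_a, shared_b


class TestPeakCenter:
    def test_midpoint(self):
        assert peak_center(mk_peak("chr1", 100, 200)) == 150

    def test_floor_on_odd_length(self):
        assert peak_center(mk_peak("chr1", 100, 201)) == 150

    def test_summit_wins(self):
        assert peak_center(mk_peak("chr1", 100, 200, summit=137)) == 137


class TestClassifySites:
    def test_identical_sets_all_shared(self, rng):
        peaks = random_disjoint_peaks(rng, 30)
        result = classify_sites(peaks, list(peaks))
        assert result.a_only == [] and result.b_only == []
        assert len(result.shared) == 30 and result.n_shared_b == 30

    def test_disjoint_chromosomes_share_nothing(self, rng):
        a = random_disjoint_peaks(rng, 20, chrom="chr1")
        b = random_disjoint_peaks(rng, 20, chrom="chr2")
        result = classify_sites(a, b)
        assert result.shared == [] and len(result.a_only) == 20

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            a = random_disjoint_peaks(rng, int(rng.integers(5, 50)))
            b = random_disjoint_peaks(rng, int(rng.integers(5, 50)))
            min_ov = int(rng.integers(1, 30))
            result = classify_sites(a, b, min_overlap=min_ov)
            a_only, b_only, shared_a, shared_b = brute_force_classify(a, b, min_ov)
            assert sorted(result.a_only) == sorted(a_only)
            assert sorted(result.b_only) == sorted(b_only)
            assert sorted(x for x, _ in result.shared) == sorted(shared_a)
            assert result.n_shared_b == len(shared_b)
            # count conservation on every instance
            assert len(result.a_only) + len(result.shared) == len(a)
            assert len(result.b_only) + result.n_shared_b == len(b)

    def test_internal_overlaps_merged_with_warning(self):
        a = [mk_peak("chr1", 0, 100), mk_peak("chr1", 50, 150)]
        with pytest.warns(UserWarning, match="merged"):
            result = classify_sites(a, [mk_peak("chr2", 0, 10)])
        assert len(result.a_only) == 1
        assert result.a_only[0].end == 150

    def test_one_a_peak_spanning_many_b_counts_once(self):
        a = [mk_peak("chr1", 0, 1000)]
        b = [mk_peak("chr1", 100, 200), mk_peak("chr1", 300, 400)]
        result = classify_sites(a, b)
        assert len(result.shared) == 1
        assert result.n_shared_b == 2
        assert len(result.b_only) + result.n_shared_b == 2

    def test_min_overlap_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_sites([], [], min_overlap=0)


class TestMergeOverlapping:
    def test_scores_sum_and_spans_union(self):
        peaks = [
            Peak(GenomicInterval("chr1", 0, 100), score=5),
            Peak(GenomicInterval("chr1", 90, 200), score=7),
            Peak(GenomicInterval("chr1", 300, 400), score=1),
        ]
        merged = merge_overlapping(peaks)
        assert [(p.start, p.end, p.score) for p in merged] == [
            (0, 200, 12.0),
            (300, 400, 1.0),
        ]


class TestNearestTss:
    def mk_gene(self, chrom, start, end, strand, name):
        return GeneModel(GenomicInterval(chrom, start, end, strand), name)

    def test_site_on_tss_is_zero(self):
        genes = [self.mk_gene("chr1", 5_000, 8_000, "+", "g")]
        sites = [mk_peak("chr1", 4_900, 5_100)]  # center = 5000 = TSS
        assert nearest_tss_distances(sites, genes) == [0]

    def test_minus_strand_sign_flip(self):
        # TSS of the minus gene at 9_999; site center 500 bp to its genomic
        # right is upstream in gene orientation
        genes = [self.mk_gene("chr1", 5_000, 10_000, "-", "g")]
        sites = [mk_peak("chr1", 10_399, 10_599)]  # center 10_499 = tss + 500
        assert nearest_tss_distances(sites, genes) == [-500]

    def test_empty_gene_set_is_error(self):
        with pytest.raises(ValueError):
            nearest_tss_distances([mk_peak("chr1", 0, 10)], [])

    def test_siteless_chromosome_skipped_with_warning(self):
        genes = [self.mk_gene("chr1", 0, 100, "+", "g")]
        sites = [mk_peak("chr9", 0, 10), mk_peak("chr1", 40, 60)]
        with pytest.warns(UserWarning, match="skipped"):
            distances = nearest_tss_distances(sites, genes)
        assert len(distances) == 1

    def test_matches_exhaustive_oracle(self, rng):
        genes = [
            self.mk_gene(
                "chr1",
                int(s),
                int(s) + int(rng.integers(500, 3_000)),
                str(rng.choice(["+", "-"])),
                f"g{i:03d}",
            )
            for i, s in enumerate(rng.choice(1_000_000, size=80, replace=False))
        ]
        sites = [
            mk_peak("chr1", int(p), int(p) + 100)
            for p in rng.integers(0, 1_000_000, size=200)
        ]
        result = nearest_tss_distances(sites, genes)
        for site, got in zip(sites, result):
            center = peak_center(site)
            best = min(genes, key=lambda g: (abs(g.tss - center), g.name))
            expected = center - best.tss
            if best.strand == "-":
                expected = -expected
            assert got == expected


class TestTssDistanceProfile:
    def test_all_zero_distances_fill_central_bin(self):
        profile = tss_distance_profile([0] * 10, window=40_000, bin_size=1_000)
        central = np.flatnonzero(profile.bin_edges[:-1] == 0)[0]
        assert profile.frequencies[central] == 1.0
        assert profile.frequencies.sum() == pytest.approx(1.0)

    def test_frequencies_sum_to_one_and_outside_reported(self, rng):
        d = list(rng.integers(-60_000, 60_000, size=500))
        profile = tss_distance_profile(d, window=40_000, bin_size=2_000)
        assert profile.frequencies.sum() == pytest.approx(1.0)
        assert profile.n_in_window + profile.n_excluded == 500

    def test_uniform_distances_give_flat_profile(self, rng):
        d = rng.integers(-40_000, 40_000, size=20_000)
        profile = tss_distance_profile(d, window=40_000, bin_size=4_000)
        counts = profile.frequencies * profile.n_in_window
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01

    def test_bad_bin_rejected(self):
        with pytest.raises(ValueError):
            tss_distance_profile([0], bin_size=0)
        with pytest.raises(ValueError):
            tss_distance_profile([0], window=40_000, bin_size=7_000)


class TestGenomicContext:
    def setup_method(self):
        chrom = "chr1"
        self.gene = GeneModel(
            GenomicInterval(chrom, 10_000, 20_000, "+"),
            "g1",
            exons=(
                GenomicInterval(chrom, 10_000, 12_000, "+"),
                GenomicInterval(chrom, 15_000, 20_000, "+"),
            ),
        )

    def test_precedence_tss_beats_exon(self):
        site = mk_peak("chr1", 10_200, 10_400)  # center 300 bp from TSS
        summary = annotate_genomic_context([site], [self.gene], tss_window=1_000)
        assert summary.categories == ["TSS"]

    def test_gene_desert_is_intergenic(self):
        site = mk_peak("chr1", 500_000, 500_200)
        summary = annotate_genomic_context([site], [self.gene])
        assert summary.categories == ["intergenic"]

    def test_intron_between_exons(self):
        site = mk_peak("chr1", 13_400, 13_600)  # center 13_500, in the intron
        summary = annotate_genomic_context([site], [self.gene])
        assert summary.categories == ["intron"]

    def test_frequencies_sum_to_one(self, rng):
        sites = [
            mk_peak("chr1", int(p), int(p) + 50)
            for p in rng.integers(0, 600_000, size=300)
        ]
        summary = annotate_genomic_context(sites, [self.gene])
        assert sum(summary.frequencies.values()) == pytest.approx(1.0)

    def test_matches_literal_precedence_oracle(self, rng):
        genes = []
        for i, s in enumerate(rng.choice(500_000, size=40, replace=False)):
            start = int(s)
            end = start + int(rng.integers(1_000, 8_000))
            strand = str(rng.choice(["+", "-"]))
            mid = (start + end) // 2
            genes.append(
                GeneModel(
                    GenomicInterval("chr1", start, end, strand),
                    f"g{i}",
                    exons=(
                        GenomicInterval("chr1", start, mid, strand),
                        GenomicInterval("chr1", mid + 100, end, strand),
                    )
                    if end - mid > 200
                    else (),
                )
            )
        sites = [
            mk_peak("chr1", int(p), int(p) + 100)
            for p in rng.integers(0, 520_000, size=150)
        ]
        tss_w = tes_w = 800
        summary = annotate_genomic_context(sites, genes, tss_w, tes_w)
        for site, got in zip(sites, summary.categories):
            c = peak_center(site)
            if any(abs(c - g.tss) <= tss_w for g in genes):
                expected = "TSS"
            elif any(abs(c - g.tes) <= tes_w for g in genes):
                expected = "TES"
            elif any(
                e.start <= c < e.end for g in genes for e in g.exons
            ):
                expected = "exon"
            elif any(g.interval.start <= c < g.interval.end for g in genes):
                expected = "intron"
            else:
                expected = "intergenic"
            assert got == expected
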