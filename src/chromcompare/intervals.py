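"""Peak-set intersection and gene-relative annotation of binding sites.

Two peak sets A and B are partitioned into three classes — A-only, B-only
and shared — by interval overlap, the classification underlying a two-set
Venn diagram of binding sites.  Sites are further annotated by signed
distance to the nearest TSS (gene-oriented: negative = upstream) and by
genomic context (TSS / TES / exon / intron / intergenic) evaluated at the
peak center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import GeneModel, GenomicInterval, Peak

__all__ = [
    "ClassifiedSites",
    "GenomicContextSummary",
    "TssDistanceProfile",
    "classify_sites",
    "peak_center",
    "merge_overlapping",
    "nearest_tss_distances",
    "tss_distance_profile",
    "annotate_genomic_context",
]

CONTEXT_CATEGORIES = ("TSS", "TES", "exon", "intron", "intergenic")


def peak_center(peak: Peak) -> int:
    """Summit if recorded, else the interval midpoint (floor on ties)."""
    if peak.summit is not None:
        return peak.summit
    return (peak.start + peak.end) // 2


def merge_overlapping(peaks: Sequence[Peak]) -> list[Peak]:
    """Merge peaks that overlap within one set; summits are dropped, scores summed.

    Returns merged peaks sorted by (chrom, start).  Needed so that the
    class-count conservation invariant |A| = |A-only| + |shared| is
    well-defined.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    merged: list[Peak] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur = group[0]
        cur_start, cur_end, cur_score = cur.start, cur.end, cur.score
        cur_summit, cur_name = cur.summit, cur.name
        n_in_run = 1
        for p in group[1:]:
            if p.start < cur_end:  # overlap within the set
                cur_end = max(cur_end, p.end)
                cur_score += p.score
                cur_summit = None
                n_in_run += 1
            else:
                merged.append(
                    Peak(
                        GenomicInterval(chrom, cur_start, cur_end),
                        summit=cur_summit,
                        score=cur_score,
                        name=cur_name,
                    )
                )
                cur_start, cur_end, cur_score = p.start, p.end, p.score
                cur_summit, cur_name = p.summit, p.name
                n_in_run = 1
        merged.append(
            Peak(
                GenomicInterval(chrom, cur_start, cur_end),
                summit=cur_summit,
                score=cur_score,
                name=cur_name,
            )
        )
    return merged


@dataclass
class ClassifiedSites:
    """Three-class partition of two peak sets by interval overlap.

    ``shared`` holds (a_peak, b_peak) pairs, one per shared A peak, with the
    B partner chosen by largest overlap (leftmost on ties).  ``n_shared_b``
    counts the distinct B peaks that overlap any A peak, so that
    ``len(b_only) + n_shared_b == |B|``.
    """

    a_only: list[Peak]
    b_only: list[Peak]
    shared: list[tuple[Peak, Peak]]
    a_name: str = "A"
    b_name: str = "B"
    n_shared_b: int = 0

    @property
    def counts(self) -> dict[str, int]:
        return {
            f"{self.a_name}_total": len(self.a_only) + len(self.shared),
            f"{self.b_name}_total": len(self.b_only) + self.n_shared_b,
            f"{self.a_name}_only": len(self.a_only),
            f"{self.b_name}_only": len(self.b_only),
            "shared": len(self.shared),
            f"shared_{self.b_name}_side": self.n_shared_b,
        }

    @property
    def shared_fraction_a(self) -> float:
        """Fraction of A sites that overlap a B site."""
        n_a = len(self.a_only) + len(self.shared)
        return len(self.shared) / n_a if n_a else float("nan")

    @property
    def shared_fraction_b(self) -> float:
        """Fraction of B sites that overlap an A site."""
        n_b = len(self.b_only) + self.n_shared_b
        return self.n_shared_b / n_b if n_b else float("nan")


def _index_by_chrom(peaks: Sequence[Peak]) -> dict[str, tuple[np.ndarray, np.ndarray, list[Peak]]]:
    out: dict[str, tuple[np.ndarray, np.ndarray, list[Peak]]] = {}
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda p: (p.start, p.end))
        starts = np.array([p.start for p in group], dtype=np.int64)
        ends = np.array([p.end for p in group], dtype=np.int64)
        out[chrom] = (starts, ends, group)
    return out


def classify_sites(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    min_overlap: int = 1,
    a_name: str = "A",
    b_name: str = "B",
) -> ClassifiedSites:
    """Partition two peak sets into A-only / B-only / shared classes.

    An A peak is *shared* iff some B peak overlaps it by at least
    ``min_overlap`` bases; counting is site-level, so an A peak overlapping
    several B peaks contributes one shared site.  Peaks overlapping within a
    single set are merged first (with a warning), which makes the count
    conservation |A| = |A-only| + |shared| exact.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    merged_a = merge_overlapping(peaks_a) if peaks_a else []
    merged_b = merge_overlapping(peaks_b) if peaks_b else []
    if len(merged_a) != len(peaks_a):
        warnings.warn(
            f"{len(peaks_a) - len(merged_a)} overlapping peaks merged within set {a_name}",
            stacklevel=2,
        )
    if len(merged_b) != len(peaks_b):
        warnings.warn(
            f"{len(peaks_b) - len(merged_b)} overlapping peaks merged within set {b_name}",
            stacklevel=2,
        )

    b_index = _index_by_chrom(merged_b)
    a_only: list[Peak] = []
    shared: list[tuple[Peak, Peak]] = []
    shared_b_ids: set[int] = set()

    for a in merged_a:
        best: Peak | None = None
        best_ov = 0
        if a.chrom in b_index:
            starts, ends, group = b_index[a.chrom]
            # candidate B peaks: start before a.end and end after a.start
            lo = int(np.searchsorted(ends, a.start, side="right"))
            hi = int(np.searchsorted(starts, a.end, side="left"))
            for j in range(lo, hi):
                ov = min(a.end, ends[j]) - max(a.start, starts[j])
                if ov >= min_overlap:
                    shared_b_ids.add(id(group[j]))
                    if ov > best_ov:
                        best_ov = ov
                        best = group[j]
        if best is not None:
            shared.append((a, best))
        else:
            a_only.append(a)

    # B-only must use the full reciprocal criterion, not just partners chosen above
    a_index = _index_by_chrom(merged_a)
    b_only: list[Peak] = []
    n_shared_b = 0
    for b in merged_b:
        hit = False
        if b.chrom in a_index:
            starts, ends, _ = a_index[b.chrom]
            lo = int(np.searchsorted(ends, b.start, side="right"))
            hi = int(np.searchsorted(starts, b.end, side="left"))
            for j in range(lo, hi):
                if min(b.end, ends[j]) - max(b.start, starts[j]) >= min_overlap:
                    hit = True
                    break
        if hit:
            n_shared_b += 1
        else:
            b_only.append(b)

    return ClassifiedSites(
        a_only=a_only,
        b_only=b_only,
        shared=shared,
        a_name=a_name,
        b_name=b_name,
        n_shared_b=n_shared_b,
    )


# ---------------------------------------------------------------------------
# TSS distances


def nearest_tss_distances(
    sites: Sequence[Peak], genes: Sequence[GeneModel]
) -> list[int]:
    """Signed gene-oriented distance from each site center to the nearest TSS.

    Negative means the site lies upstream of the gene (5' of the TSS in gene
    orientation).  Nearest is by absolute genomic distance; exact ties are
    broken toward the lexicographically smaller gene name.  Sites on
    chromosomes without genes are skipped with a warning.
    """
    if not genes:
        raise ValueError("empty gene set")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, group in by_chrom.items():
        group.sort(key=lambda g: (g.tss, g.name))
        index[chrom] = (np.array([g.tss for g in group], dtype=np.int64), group)

    distances: list[int] = []
    n_skipped = 0
    for site in sites:
        if site.chrom not in index:
            n_skipped += 1
            continue
        tss_arr, group = index[site.chrom]
        center = peak_center(site)
        i = int(np.searchsorted(tss_arr, center))
        # candidates at the insertion boundary, expanded over exact ties
        best_abs = None
        best_gene: GeneModel | None = None
        for j in range(max(0, i - 1), min(len(group), i + 1)):
            d_abs = abs(int(tss_arr[j]) - center)
            if best_abs is None or d_abs < best_abs:
                best_abs, best_gene = d_abs, group[j]
        assert best_gene is not None and best_abs is not None
        for g in group:
            d_abs = abs(g.tss - center)
            if d_abs == best_abs and g.name < best_gene.name:
                best_gene = g
        signed = center - best_gene.tss
        if best_gene.strand == "-":
            signed = -signed
        distances.append(signed)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} sites on chromosomes without genes were skipped",
            stacklevel=2,
        )
    return distances


@dataclass
class TssDistanceProfile:
    """Binned frequency profile of TSS distances over a symmetric window."""

    bin_edges: np.ndarray  # length n_bins + 1, from -window to +window
    frequencies: np.ndarray  # sums to 1 over in-window sites
    n_in_window: int
    n_excluded: int


def tss_distance_profile(
    distances: Iterable[int], window: int = 40_000, bin_size: int = 1_000
) -> TssDistanceProfile:
    """Per-bin frequency of sites over [-window, +window); out-of-window
    distances are excluded from both numerator and denominator and reported."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if window % bin_size != 0:
        raise ValueError("bin size must divide the window evenly")
    d = np.asarray(list(distances), dtype=np.int64)
    in_window = (d >= -window) & (d < window)
    edges = np.arange(-window, window + bin_size, bin_size)
    counts, _ = np.histogram(d[in_window], bins=edges)
    n_in = int(in_window.sum())
    freqs = counts / n_in if n_in else counts.astype(float)
    return TssDistanceProfile(
        bin_edges=edges,
        frequencies=freqs,
        n_in_window=n_in,
        n_excluded=int(d.size - n_in),
    )


# ---------------------------------------------------------------------------
# genomic context


@dataclass
class GenomicContextSummary:
    """One category per site; frequencies over TSS/TES/exon/intron/intergenic."""

    categories: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {c: self.categories.count(c) for c in CONTEXT_CATEGORIES}

    @property
    def frequencies(self) -> dict[str, float]:
        n = len(self.categories)
        if n == 0:
            return {c: 0.0 for c in CONTEXT_CATEGORIES}
        return {c: self.categories.count(c) / n for c in CONTEXT_CATEGORIES}


def annotate_genomic_context(
    sites: Sequence[Peak],
    genes: Sequence[GeneModel],
    tss_window: int = 1_000,
    tes_window: int = 1_000,
) -> GenomicContextSummary:
    """Assign each site center one category with precedence
    TSS > TES > exon > intron > intergenic.

    A center within ``tss_window`` bases of any TSS (absolute distance) is
    TSS; likewise for TES; otherwise exon if inside any exon, intron if
    inside any gene body, else intergenic.
    """
    if tss_window < 0 or tes_window < 0:
        raise ValueError("windows must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    categories: list[str] = []
    for site in sites:
        center = peak_center(site)
        group = by_chrom.get(site.chrom, [])
        category = "intergenic"
        in_exon = in_gene = near_tss = near_tes = False
        for g in group:
            if abs(center - g.tss) <= tss_window:
                near_tss = True
                break
            if abs(center - g.tes) <= tes_window:
                near_tes = True
            if g.interval.start <= center < g.interval.end:
                in_gene = True
                for ex in g.exons:
                    if ex.start <= center < ex.end:
                        in_exon = True
                        break
        if near_tss:
            category = "TSS"
        elif near_tes:
            category = "TES"
        elif in_exon:
            category = "exon"
        elif in_gene:
            category = "intron"
        categories.append(category)
    return GenomicContextSummary(categories=categories)
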