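"""Ground-truth synthetic fixtures for the comparative ChIP-seq pipeline.

The generator emulates the statistical structure the analysis assumes:

* two factors, A and B, binding a shared ~20-bp consensus; a controllable
  fraction of A sites coincides with B sites (the shared class), A-only
  sites are preferentially promoter-proximal;
* a planted consensus motif at a configurable fraction of sites, mutated at
  a small per-position rate (so motif-free sites exist, as in real data);
* an H3-like nucleosome read set with three chromatin contexts: wide, flat
  depletion over A-only sites (loosely assembled promoter nucleosomes),
  regularly phased nucleosomes with a sharp central trough flanking B-only
  sites, and an intermediate pattern at shared sites;
* Poisson-sampled ChIP reads for factor B in two conditions (without / with
  factor A) with planted per-site fold changes at a subset of shared sites;
* log2 expression values with a planted positive shift for genes whose
  promoter window contains an A site.

All randomness flows from the single seed passed to :func:`generate_fixture`;
the same config and seed produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .expression import assign_bound_genes
from .io import (
    GeneModel,
    GenomicInterval,
    Peak,
    write_bed,
    write_expression_table,
    write_fasta,
    write_gene_table,
)
from .motif import PWM

__all__ = ["SimConfig", "SyntheticTruth", "generate_fixture", "venn_fixture"]

CONSENSUS_MOTIF = "CCACCAGGTGGCGCTATCAG"
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the study conditions every
    fixture-based test runs under."""

    # genome: sized so that the +/-2 kb site windows of ~2,700 sites rarely
    # overlap at the default minimum spacing
    n_chroms: int = 2
    chrom_length: int = 8_000_000
    gc_content: float = 0.42

    # gene models
    n_genes: int = 500
    gene_min_length: int = 2_000
    gene_max_length: int = 10_000

    # binding sites
    n_a_sites: int = 500
    n_b_sites: int = 2_000
    n_shared: int = 300
    peak_width: int = 300
    min_site_spacing: int = 4_000
    promoter_fraction_a_only: float = 0.7
    promoter_upstream: int = 2_000
    promoter_downstream: int = 1_000

    # motif planting
    motif_fraction: float = 0.7
    motif_mutation_rate: float = 0.05

    # H3-like nucleosome reads
    nucleosome_repeat: int = 185
    nucleosome_jitter_sd: float = 20.0
    depletion_halfwidth: int = 600
    depletion_factor: float = 0.25
    h3_reads_per_site: float = 200.0
    h3_background_reads: int = 100_000

    # ChIP reads (factor tracks, two conditions for factor B)
    chip_reads_per_site: float = 200.0
    chip_positional_sd: float = 80.0
    chip_background_reads: int = 20_000
    n_down_shared: int = 100
    fold_down: float = 0.5
    n_up_shared: int = 20
    fold_up: float = 2.0

    # reads / fragments
    read_length: int = 36
    fragment_length: int = 150

    # expression
    expression_mean: float = 6.0
    expression_sd: float = 1.2
    expression_shift_bound: float = 1.0

    def validate(self) -> None:
        if self.n_shared > min(self.n_a_sites, self.n_b_sites):
            raise ValueError("n_shared cannot exceed either site-set size")
        if not (0 <= self.gc_content <= 1):
            raise ValueError("gc_content must be in [0, 1]")
        for frac in (self.promoter_fraction_a_only, self.motif_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if self.n_down_shared + self.n_up_shared > self.n_shared:
            raise ValueError("more fold-change sites than shared sites")
        margin = 2 * self.min_site_spacing
        n_slots = self.n_chroms * (
            (self.chrom_length - margin) // self.min_site_spacing
        )
        n_needed = self.n_b_sites + (self.n_a_sites - self.n_shared)
        if n_needed > n_slots:
            raise ValueError(
                f"genome too small: {n_needed} sites requested but only "
                f"{n_slots} positions at spacing {self.min_site_spacing}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream truth comparison."""

    config: SimConfig
    seed: int
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    peaks_a: list[Peak]
    peaks_b: list[Peak]
    shared_pairs: list[tuple[Peak, Peak]]
    site_classes: dict[str, str]  # site id -> depleted / phased / intermediate
    planted_motifs: list[tuple[str, int, str]]  # (chrom, start, strand)
    truth_pwm: PWM
    h3_reads: list[GenomicInterval]
    chip_reads_a: list[GenomicInterval]
    chip_reads_b_cond1: list[GenomicInterval]
    chip_reads_b_cond2: list[GenomicInterval]
    shared_fold_changes: dict[str, float]  # shared site id -> planted fold
    expression: dict[str, float]
    bound_gene_names: list[str]

    def site_id(self, peak: Peak) -> str:
        return f"{peak.chrom}:{peak.start}-{peak.end}"

    def truth_summary(self) -> dict:
        return {
            "seed": self.seed,
            "n_a_sites": len(self.peaks_a),
            "n_b_sites": len(self.peaks_b),
            "n_shared": len(self.shared_pairs),
            "n_planted_motifs": len(self.planted_motifs),
            "n_down_shared": sum(
                1 for f in self.shared_fold_changes.values() if f < 1
            ),
            "n_up_shared": sum(
                1 for f in self.shared_fold_changes.values() if f > 1
            ),
            "n_bound_genes": len(self.bound_gene_names),
            "nucleosome_repeat": self.config.nucleosome_repeat,
        }


# ---------------------------------------------------------------------------
# helpers


def _random_genome(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    p_gc = cfg.gc_content / 2.0
    p_at = (1.0 - cfg.gc_content) / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])
    genome = {}
    for i in range(cfg.n_chroms):
        idx = rng.choice(4, size=cfg.chrom_length, p=probs)
        genome[f"chr{i + 1}"] = BASES[idx].tobytes().decode("ascii")
    return genome


def _place_genes(
    cfg: SimConfig, chroms: list[str], rng: np.random.Generator
) -> list[GeneModel]:
    per_chrom = cfg.n_genes // cfg.n_chroms
    extra = cfg.n_genes - per_chrom * cfg.n_chroms
    genes: list[GeneModel] = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        n = per_chrom + (1 if ci < extra else 0)
        slot = (cfg.chrom_length - 20_000) // max(n, 1)
        for k in range(n):
            length = int(rng.integers(cfg.gene_min_length, cfg.gene_max_length + 1))
            lo = 10_000 + k * slot
            start = int(rng.integers(lo, lo + max(1, slot - length)))
            strand = "+" if rng.random() < 0.5 else "-"
            interval = GenomicInterval(chrom, start, start + length, strand)
            # 2-4 exons tiled over the gene with introns between
            n_ex = int(rng.integers(2, 5))
            bounds = np.sort(
                rng.choice(
                    np.arange(start + 50, start + length - 50),
                    size=2 * n_ex - 2,
                    replace=False,
                )
            )
            edges = [start, *bounds.tolist(), start + length]
            exons = tuple(
                GenomicInterval(chrom, edges[2 * j], edges[2 * j + 1], strand)
                for j in range(n_ex)
                if edges[2 * j] < edges[2 * j + 1]
            )
            genes.append(GeneModel(interval, f"gene{gid:04d}", exons))
            gid += 1
    return genes


def _nucleosome_densities(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Per-class read-center densities over offsets [-2000, 2000)."""
    x = np.arange(-2_000, 2_000, dtype=np.float64)
    gauss = np.zeros_like(x)
    dyad = cfg.nucleosome_repeat // 2 + 8  # first flanking nucleosome center
    k = 0
    while dyad + k * cfg.nucleosome_repeat <= 1_950:
        for sign in (-1, 1):
            center = sign * (dyad + k * cfg.nucleosome_repeat)
            gauss += np.exp(
                -0.5 * ((x - center) / cfg.nucleosome_jitter_sd) ** 2
            )
        k += 1
    phased = 0.05 + gauss
    depleted = np.ones_like(x)
    depleted[np.abs(x) <= cfg.depletion_halfwidth] = cfg.depletion_factor
    intermediate = np.ones_like(x)
    intermediate[np.abs(x) <= 300] = 0.5
    intermediate = intermediate + 0.3 * gauss
    out = {}
    for name, d in (
        ("phased", phased),
        ("depleted", depleted),
        ("intermediate", intermediate),
    ):
        out[name] = d / d.sum()
    return out


def _reads_from_fragment_centers(
    chrom: str,
    centers: np.ndarray,
    strands: np.ndarray,
    cfg: SimConfig,
    chrom_size: int,
) -> list[GenomicInterval]:
    """BED6 read records whose 5' ends sit at the fragment boundaries, so
    that rebuilding coverage with the fragment-length extension recovers the
    fragments."""
    half = cfg.fragment_length // 2
    reads = []
    for c, plus in zip(centers, strands):
        c = int(c)
        if plus:
            five = c - half
            s, e = five, five + cfg.read_length
        else:
            five = c + (cfg.fragment_length - half) - 1
            s, e = five - cfg.read_length + 1, five + 1
        if s < 0 or e > chrom_size:
            continue
        reads.append(GenomicInterval(chrom, s, e, "+" if plus else "-"))
    return reads


def _background_reads(
    n: int,
    chroms: list[str],
    chrom_size: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    reads = []
    per = n // len(chroms)
    for chrom in chroms:
        centers = rng.integers(200, chrom_size - 200, size=per)
        strands = rng.random(per) < 0.5
        reads.extend(
            _reads_from_fragment_centers(chrom, centers, strands, cfg, chrom_size)
        )
    return reads


def _truth_pwm(cfg: SimConfig) -> PWM:
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(CONSENSUS_MOTIF)
    probs = np.full((L, 4), cfg.motif_mutation_rate / 3.0)
    for i, b in enumerate(CONSENSUS_MOTIF):
        probs[i, base_idx[b]] = 1.0 - cfg.motif_mutation_rate
    return PWM(
        probs=probs, background=np.full(4, 0.25), pseudocount=0.0, name="planted"
    )


# ---------------------------------------------------------------------------
# main generator


def generate_fixture(
    config: SimConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SyntheticTruth:
    """Generate a complete synthetic study with known ground truth.

    When ``outdir`` is given, all inputs are also written to disk (FASTA
    genome, BED peak sets and read sets, TSV gene/expression tables, the
    config YAML and a truth-summary JSON).
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_sizes = {c: cfg.chrom_length for c in chroms}

    genome_arrays = {
        c: np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
        for c, s in _random_genome(cfg, rng).items()
    }
    genes = _place_genes(cfg, chroms, rng)

    # ---- site placement ------------------------------------------------
    margin = cfg.min_site_spacing
    slots: list[tuple[str, int]] = []
    for chrom in chroms:
        for pos in range(margin, cfg.chrom_length - margin, cfg.min_site_spacing):
            slots.append((chrom, pos))
    order = rng.permutation(len(slots))

    n_a_only = cfg.n_a_sites - cfg.n_shared
    n_b = cfg.n_b_sites
    chosen = [slots[i] for i in order[: n_b + n_a_only]]
    b_slots = chosen[:n_b]
    a_only_slots = chosen[n_b:]

    # A-only sites are preferentially promoter-proximal: re-target the
    # configured fraction of them into a random gene's promoter window,
    # keeping the exact minimum center spacing to every other site.
    from bisect import bisect_left, insort

    centers: dict[str, list[int]] = {c: [] for c in chroms}
    for c, p in chosen:
        insort(centers[c], p)

    def far_enough(chrom: str, pos: int) -> bool:
        arr = centers[chrom]
        i = bisect_left(arr, pos)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(arr[j] - pos) < cfg.min_site_spacing:
                return False
        return True

    retargeted: list[tuple[str, int]] = []
    for chrom, pos in a_only_slots:
        if rng.random() < cfg.promoter_fraction_a_only:
            placed = False
            arr = centers[chrom]
            arr.pop(bisect_left(arr, pos))  # the site is being moved
            for _ in range(50):
                gene = genes[int(rng.integers(len(genes)))]
                if gene.strand == "+":
                    lo = gene.tss - cfg.promoter_upstream
                    hi = gene.tss + cfg.promoter_downstream
                else:  # oriented window flips genomically on the minus strand
                    lo = gene.tss - cfg.promoter_downstream
                    hi = gene.tss + cfg.promoter_upstream
                cand = int(rng.integers(lo, hi + 1))
                if (
                    margin <= cand < cfg.chrom_length - margin
                    and far_enough(gene.chrom, cand)
                ):
                    insort(centers[gene.chrom], cand)
                    retargeted.append((gene.chrom, cand))
                    placed = True
                    break
            if not placed:
                insort(centers[chrom], pos)
                retargeted.append((chrom, pos))
        else:
            retargeted.append((chrom, pos))
    a_only_slots = retargeted

    half_w = cfg.peak_width // 2

    def make_peak(chrom: str, center: int, score: float) -> Peak:
        return Peak(
            GenomicInterval(chrom, center - half_w, center + half_w),
            summit=center,
            score=score,
        )

    shared_idx = rng.choice(n_b, size=cfg.n_shared, replace=False)
    shared_mask = np.zeros(n_b, dtype=bool)
    shared_mask[shared_idx] = True

    peaks_b: list[Peak] = []
    peaks_a: list[Peak] = []
    shared_pairs: list[tuple[Peak, Peak]] = []
    site_classes: dict[str, str] = {}

    b_scores = rng.poisson(cfg.chip_reads_per_site, size=n_b).astype(float)
    for i, (chrom, center) in enumerate(b_slots):
        b_peak = make_peak(chrom, center, b_scores[i])
        peaks_b.append(b_peak)
    a_scores = rng.poisson(cfg.chip_reads_per_site, size=cfg.n_a_sites).astype(float)
    ai = 0
    for i, b_peak in enumerate(peaks_b):
        if shared_mask[i]:
            shift = int(rng.integers(-50, 51))
            a_peak = make_peak(b_peak.chrom, b_peak.summit + shift, a_scores[ai])
            ai += 1
            peaks_a.append(a_peak)
            shared_pairs.append((a_peak, b_peak))
            sid = f"{b_peak.chrom}:{b_peak.start}-{b_peak.end}"
            site_classes[sid] = "intermediate"
            site_classes[f"{a_peak.chrom}:{a_peak.start}-{a_peak.end}"] = "intermediate"
        else:
            sid = f"{b_peak.chrom}:{b_peak.start}-{b_peak.end}"
            site_classes[sid] = "phased"
    for chrom, center in a_only_slots:
        a_peak = make_peak(chrom, center, a_scores[ai])
        ai += 1
        peaks_a.append(a_peak)
        site_classes[f"{a_peak.chrom}:{a_peak.start}-{a_peak.end}"] = "depleted"

    # ---- motif planting -------------------------------------------------
    truth_pwm = _truth_pwm(cfg)
    L = len(CONSENSUS_MOTIF)
    planted: list[tuple[str, int, str]] = []
    all_sites = peaks_b + [
        p
        for p in peaks_a
        if site_classes[f"{p.chrom}:{p.start}-{p.end}"] == "depleted"
    ]
    for peak in all_sites:
        if rng.random() >= cfg.motif_fraction:
            continue
        center = peak.summit if peak.summit is not None else (peak.start + peak.end) // 2
        start = center - L // 2
        instance = list(CONSENSUS_MOTIF)
        for i in range(L):
            if rng.random() < cfg.motif_mutation_rate:
                instance[i] = "ACGT"[int(rng.integers(4))]
        strand = "+" if rng.random() < 0.5 else "-"
        written = "".join(instance) if strand == "+" else _revcomp("".join(instance))
        arr = genome_arrays[peak.chrom]
        arr[start : start + L] = np.frombuffer(written.encode("ascii"), dtype=np.uint8)
        planted.append((peak.chrom, start, strand))

    genome = {c: arr.tobytes().decode("ascii") for c, arr in genome_arrays.items()}

    # ---- H3-like nucleosome reads ---------------------------------------
    densities = _nucleosome_densities(cfg)
    h3_reads: list[GenomicInterval] = []
    class_of: list[tuple[Peak, str]] = []
    for p in peaks_b:
        sid = f"{p.chrom}:{p.start}-{p.end}"
        class_of.append((p, site_classes[sid]))
    for p in peaks_a:
        sid = f"{p.chrom}:{p.start}-{p.end}"
        if site_classes[sid] == "depleted":
            class_of.append((p, "depleted"))
    for peak, cls in class_of:
        n_reads = int(rng.poisson(cfg.h3_reads_per_site))
        if n_reads == 0:
            continue
        offsets = rng.choice(4_000, size=n_reads, p=densities[cls]) - 2_000
        centers = peak.summit + offsets
        strands = rng.random(n_reads) < 0.5
        h3_reads.extend(
            _reads_from_fragment_centers(
                peak.chrom, centers, strands, cfg, cfg.chrom_length
            )
        )
    h3_reads.extend(
        _background_reads(cfg.h3_background_reads, chroms, cfg.chrom_length, cfg, rng)
    )

    # ---- ChIP reads: factor A, and factor B in two conditions ------------
    def chip_reads_for(
        site_folds: list[tuple[Peak, float]]
    ) -> list[GenomicInterval]:
        reads: list[GenomicInterval] = []
        for peak, fold in site_folds:
            n = int(rng.poisson(cfg.chip_reads_per_site * fold))
            if n == 0:
                continue
            offsets = np.clip(
                np.rint(rng.normal(0.0, cfg.chip_positional_sd, size=n)),
                -1_000,
                1_000,
            ).astype(np.int64)
            centers = peak.summit + offsets
            strands = rng.random(n) < 0.5
            reads.extend(
                _reads_from_fragment_centers(
                    peak.chrom, centers, strands, cfg, cfg.chrom_length
                )
            )
        reads.extend(
            _background_reads(
                cfg.chip_background_reads, chroms, cfg.chrom_length, cfg, rng
            )
        )
        return reads

    chip_reads_a = chip_reads_for([(p, 1.0) for p in peaks_a])

    fold_by_shared: dict[str, float] = {}
    pick = rng.permutation(cfg.n_shared)
    down_set = set(pick[: cfg.n_down_shared].tolist())
    up_set = set(pick[cfg.n_down_shared : cfg.n_down_shared + cfg.n_up_shared].tolist())
    shared_folds: dict[int, float] = {}
    for k in range(cfg.n_shared):
        fold = cfg.fold_down if k in down_set else cfg.fold_up if k in up_set else 1.0
        shared_folds[k] = fold
        b_peak = shared_pairs[k][1]
        fold_by_shared[f"{b_peak.chrom}:{b_peak.start}-{b_peak.end}"] = fold

    shared_b_ids = {id(b) for _, b in shared_pairs}
    cond1 = [(p, 1.0) for p in peaks_b]
    cond2: list[tuple[Peak, float]] = []
    shared_rank = {id(b): k for k, (_, b) in enumerate(shared_pairs)}
    for p in peaks_b:
        fold = shared_folds[shared_rank[id(p)]] if id(p) in shared_b_ids else 1.0
        cond2.append((p, fold))
    chip_reads_b_cond1 = chip_reads_for(cond1)
    chip_reads_b_cond2 = chip_reads_for(cond2)

    # ---- expression with planted shift for A-bound genes ------------------
    table = assign_bound_genes(
        genes,
        peaks_a,
        upstream=cfg.promoter_upstream,
        downstream=cfg.promoter_downstream,
    )
    bound_names = table.loc[table["bound_a"], "name"].tolist()
    bound_set = set(bound_names)
    expression = {}
    for gene in genes:
        value = rng.normal(cfg.expression_mean, cfg.expression_sd)
        if gene.name in bound_set:
            value += cfg.expression_shift_bound
        expression[gene.name] = float(value)

    truth = SyntheticTruth(
        config=cfg,
        seed=seed,
        genome=genome,
        chrom_sizes=chrom_sizes,
        genes=genes,
        peaks_a=sorted(peaks_a),
        peaks_b=sorted(peaks_b),
        shared_pairs=shared_pairs,
        site_classes=site_classes,
        planted_motifs=sorted(planted),
        truth_pwm=truth_pwm,
        h3_reads=h3_reads,
        chip_reads_a=chip_reads_a,
        chip_reads_b_cond1=chip_reads_b_cond1,
        chip_reads_b_cond2=chip_reads_b_cond2,
        shared_fold_changes=fold_by_shared,
        expression=expression,
        bound_gene_names=bound_names,
    )
    if outdir is not None:
        _write_fixture(truth, Path(outdir))
    return truth


def _write_fixture(truth: SyntheticTruth, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.genome, outdir / "genome.fa")
    write_gene_table(truth.genes, outdir / "genes.tsv")
    write_bed(truth.peaks_a, outdir / "peaks_a.bed")
    write_bed(truth.peaks_b, outdir / "peaks_b.bed")
    for fname, reads in (
        ("reads_h3.bed", truth.h3_reads),
        ("reads_a.bed", truth.chip_reads_a),
        ("reads_b_cond1.bed", truth.chip_reads_b_cond1),
        ("reads_b_cond2.bed", truth.chip_reads_b_cond2),
    ):
        write_bed(
            [Peak(iv) for iv in reads],
            outdir / fname,
        )
    write_expression_table(truth.expression, outdir / "expression.tsv")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in truth.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    truth.config.to_yaml(outdir / "config.yaml")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                **truth.truth_summary(),
                "site_classes": truth.site_classes,
                "shared_fold_changes": truth.shared_fold_changes,
                "bound_genes": truth.bound_gene_names,
                "planted_motifs": [list(m) for m in truth.planted_motifs],
            },
            fh,
            indent=1,
        )


# ---------------------------------------------------------------------------
# deterministic Venn fixture


def venn_fixture(
    n_a: int,
    n_b: int,
    n_shared: int,
    peak_width: int = 300,
    spacing: int = 1_000,
    chrom: str = "chrV",
) -> tuple[list[Peak], list[Peak]]:
    """Deterministic peak sets realizing exact two-set Venn counts.

    Exactly ``n_shared`` A peaks each reciprocally overlap exactly one B
    peak (by ``peak_width - 100`` bases) and no other overlaps exist, so
    classification must report ``a_only = n_a - n_shared``,
    ``b_only = n_b - n_shared`` and ``shared = n_shared``.
    """
    if n_shared > min(n_a, n_b):
        raise ValueError("n_shared cannot exceed either set size")
    if spacing < peak_width + 200:
        raise ValueError("spacing too small for non-overlapping slots")
    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    n_slots = n_shared + (n_a - n_shared) + (n_b - n_shared)
    pos = spacing
    for slot in range(n_slots):
        if slot < n_shared:
            b = Peak(GenomicInterval(chrom, pos, pos + peak_width))
            a = Peak(GenomicInterval(chrom, pos + 100, pos + 100 + peak_width))
            peaks_a.append(a)
            peaks_b.append(b)
        elif slot < n_shared + (n_a - n_shared):
            peaks_a.append(Peak(GenomicInterval(chrom, pos, pos + peak_width)))
        else:
            peaks_b.append(Peak(GenomicInterval(chrom, pos, pos + peak_width)))
        pos += spacing
    return peaks_a, peaks_b
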