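"""End-to-end orchestration: classify -> profiles -> motif -> annotation ->
expression -> competition, with a reproducible run directory.

Each stage logs its in/out counts (the conservation invariants double as
sanity checks) and every run directory contains the verbatim config and
seed needed to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import competition as comp
from . import expression as expr
from .intervals import (
    annotate_genomic_context,
    classify_sites,
    nearest_tss_distances,
    tss_distance_profile,
)
from .io import (
    Peak,
    read_bed,
    read_expression_table,
    read_fasta,
    read_gene_table,
    write_bed,
)
from .motif import motif_occurrence_matrix, read_jaspar, scan_genome
from .signal import (
    build_coverage,
    cumulative_profile,
    extract_matrix,
    normalize_track,
    order_by_average_binding,
)

logger = logging.getLogger("chromcompare")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated inputs and stage parameters for a full pipeline run."""

    peaks_a: str
    peaks_b: str
    genes: str
    outdir: str
    a_name: str = "A"
    b_name: str = "B"
    chrom_sizes: str | None = None  # TSV chrom<TAB>size; required with reads
    reads: dict[str, str] = field(default_factory=dict)  # track name -> BED6 reads
    genome_fasta: str | None = None
    pwm_file: str | None = None  # JASPAR-style counts; enables the motif stage
    expression: str | None = None
    reads_cond1: str | None = None  # factor-B reads without the competitor
    reads_cond2: str | None = None  # factor-B reads with the competitor

    min_overlap: int = 1
    extension: int = 200
    flank: int = 2_000
    bin_size: int = 50
    threshold_frac: float = 0.6
    tss_window: int = 1_000
    tes_window: int = 1_000
    distance_window: int = 40_000
    distance_bin: int = 1_000
    promoter_upstream: int = 2_000
    promoter_downstream: int = 1_000
    fold_threshold: float = 1.5
    epsilon: float = 0.5
    quant_window: int = 300
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        required = {"peaks_a": self.peaks_a, "peaks_b": self.peaks_b, "genes": self.genes}
        optional = {
            "chrom_sizes": self.chrom_sizes,
            "genome_fasta": self.genome_fasta,
            "pwm_file": self.pwm_file,
            "expression": self.expression,
            "reads_cond1": self.reads_cond1,
            "reads_cond2": self.reads_cond2,
            **{f"reads[{k}]": v for k, v in self.reads.items()},
        }
        missing = [k for k, v in required.items() if not Path(v).exists()]
        missing += [
            k for k, v in optional.items() if v is not None and not Path(v).exists()
        ]
        if missing:
            raise PipelineError(f"validation: missing input files: {missing}")
        if (self.reads or self.reads_cond1 or self.reads_cond2) and not self.chrom_sizes:
            raise PipelineError("validation: chrom_sizes is required with read inputs")
        if (self.reads_cond1 is None) != (self.reads_cond2 is None):
            raise PipelineError("validation: competition needs both condition read sets")


def _read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split("\t")[:2]
                sizes[chrom] = int(size)
    return sizes


def _coverage_from_bed(
    path: str, chrom_sizes: dict[str, int], extension: int, name: str
):
    reads = [p.interval for p in read_bed(path)]
    track = build_coverage(reads, extension, chrom_sizes, name=name)
    return normalize_track(track)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the config provides inputs for; returns the summary.

    The summary (also written to ``summary.json``) holds class counts,
    per-class profile/matrix file names, context and TSS-distance tables,
    expression-test statistics, and competition category counts.  A rerun
    with identical config and seed reproduces it bitwise for integers and
    to 1e-9 for reals.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    summary: dict = {"seed": config.seed}

    def stage(name):
        logger.info("stage %s", name)

    # -- classification ----------------------------------------------------
    try:
        stage("classify")
        peaks_a = read_bed(config.peaks_a)
        peaks_b = read_bed(config.peaks_b)
        classified = classify_sites(
            peaks_a,
            peaks_b,
            min_overlap=config.min_overlap,
            a_name=config.a_name,
            b_name=config.b_name,
        )
        write_bed(classified.a_only, outdir / "sites_a_only.bed")
        write_bed(classified.b_only, outdir / "sites_b_only.bed")
        write_bed([a for a, _ in classified.shared], outdir / "sites_shared.bed")
        summary["classification"] = classified.counts
        class_sets = {
            "a_only": classified.a_only,
            "b_only": classified.b_only,
            "shared": [a for a, _ in classified.shared],
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"classify: {exc}") from exc

    genes = read_gene_table(config.genes)

    # -- signal matrices and cumulative profiles ---------------------------
    if config.reads:
        try:
            stage("profiles")
            chrom_sizes = _read_chrom_sizes(config.chrom_sizes)
            summary["profiles"] = {}
            for track_name, reads_path in config.reads.items():
                track = _coverage_from_bed(
                    reads_path, chrom_sizes, config.extension, track_name
                )
                for set_name, sites in class_sets.items():
                    if not sites:
                        continue
                    matrix = extract_matrix(
                        track,
                        sites,
                        flank=config.flank,
                        bin_size=config.bin_size,
                        site_set_name=set_name,
                    )
                    if matrix.values.shape[0] == 0:
                        continue
                    order = order_by_average_binding(matrix)
                    profile = cumulative_profile(matrix)
                    tag = f"{track_name}_{set_name}"
                    matrix.to_tsv(outdir / f"matrix_{tag}.tsv")
                    np.savetxt(
                        outdir / f"profile_{tag}.tsv",
                        np.column_stack([matrix.bin_midpoints, profile]),
                        delimiter="\t",
                        header="offset\tmean_signal",
                        comments="",
                        fmt="%.6g",
                    )
                    with open(outdir / f"order_{tag}.tsv", "w") as fh:
                        for idx in order:
                            fh.write(f"{matrix.site_ids[idx]}\n")
                    summary["profiles"][tag] = {
                        "n_sites": int(matrix.values.shape[0]),
                        "n_dropped": len(matrix.dropped),
                        "matrix": f"matrix_{tag}.tsv",
                        "profile": f"profile_{tag}.tsv",
                    }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"profiles: {exc}") from exc

    # -- motif scan and occurrence matrices --------------------------------
    if config.genome_fasta and config.pwm_file:
        try:
            stage("motif")
            genome = read_fasta(config.genome_fasta)
            pwm = read_jaspar(config.pwm_file)
            hits = scan_genome(pwm, genome, threshold_frac=config.threshold_frac)
            write_bed(
                [
                    Peak(
                        interval=_hit_interval(h, len(pwm)),
                        score=max(0.0, h.score),
                    )
                    for h in hits
                ],
                outdir / "motif_hits.bed",
            )
            summary["motif"] = {"n_hits": len(hits)}
            for set_name, sites in class_sets.items():
                if not sites:
                    continue
                occ = motif_occurrence_matrix(
                    hits,
                    sites,
                    flank=config.flank,
                    bin_size=config.bin_size,
                    site_set_name=set_name,
                )
                occ.to_tsv(outdir / f"motif_occurrence_{set_name}.tsv")
                summary["motif"][f"occurrences_{set_name}"] = float(occ.values.sum())
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"motif: {exc}") from exc

    # -- TSS distances and genomic context ---------------------------------
    try:
        stage("annotate")
        summary["annotation"] = {}
        for set_name, sites in class_sets.items():
            if not sites:
                continue
            distances = nearest_tss_distances(sites, genes)
            profile = tss_distance_profile(
                distances, window=config.distance_window, bin_size=config.distance_bin
            )
            context = annotate_genomic_context(
                sites, genes, tss_window=config.tss_window, tes_window=config.tes_window
            )
            summary["annotation"][set_name] = {
                "n_in_window": profile.n_in_window,
                "n_excluded": profile.n_excluded,
                "context_frequencies": context.frequencies,
            }
            np.savetxt(
                outdir / f"tss_distance_{set_name}.tsv",
                np.column_stack(
                    [profile.bin_edges[:-1], profile.frequencies]
                ),
                delimiter="\t",
                header="bin_start\tfrequency",
                comments="",
                fmt="%.6g",
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"annotate: {exc}") from exc

    # -- expression association --------------------------------------------
    if config.expression:
        try:
            stage("expression")
            expression = read_expression_table(config.expression)
            table = expr.assign_bound_genes(
                genes,
                peaks_a,
                peaks_b,
                upstream=config.promoter_upstream,
                downstream=config.promoter_downstream,
                expression=expression,
            )
            table.to_csv(outdir / "bound_genes.tsv", sep="\t", index=False)
            with_expr = table.dropna(subset=["log2_expression"])
            n_missing = len(table) - len(with_expr)
            bound = with_expr.loc[with_expr["bound_a"], "log2_expression"]
            unbound = with_expr.loc[~with_expr["bound_a"], "log2_expression"]
            summary["expression"] = {
                "n_genes": len(table),
                "n_missing_expression": int(n_missing),
                "n_bound_a": int(with_expr["bound_a"].sum()),
                "n_bound_b": int(with_expr["bound_b"].sum()),
            }
            if len(bound) and len(unbound):
                result = expr.compare_expression(bound, unbound)
                summary["expression"]["bound_vs_unbound_a"] = {
                    "U": result.statistic,
                    "p": result.pvalue,
                    "method": result.method,
                }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"expression: {exc}") from exc

    # -- competition --------------------------------------------------------
    if config.reads_cond1 and config.reads_cond2:
        try:
            stage("competition")
            chrom_sizes = _read_chrom_sizes(config.chrom_sizes)
            track1 = _coverage_from_bed(
                config.reads_cond1, chrom_sizes, config.extension, "cond1"
            )
            track2 = _coverage_from_bed(
                config.reads_cond2, chrom_sizes, config.extension, "cond2"
            )
            shared_b = [b for _, b in classified.shared]
            records, comp_summary = comp.competition_analysis(
                shared_b,
                track1,
                track2,
                fold_threshold=config.fold_threshold,
                epsilon=config.epsilon,
                window=config.quant_window,
            )
            comp.records_to_frame(records).to_csv(
                outdir / "competition.tsv", sep="\t", index=False
            )
            summary["competition"] = comp_summary.as_dict()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"competition: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _hit_interval(hit, length: int):
    from .io import GenomicInterval

    return GenomicInterval(hit.chrom, hit.start, hit.start + length, hit.strand)
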