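"""Readers and writers for the plain-text genomics formats the pipeline touches.

Every coordinate in this package is 0-based, half-open (the BED convention):
an interval covers the bases ``start .. end-1``.  The transcription start
site (TSS) of a minus-strand gene is therefore ``end - 1``, and its end site
(TES) is ``start``.  Adapters to and from 1-based closed coordinates (the GFF
convention) are provided for interoperability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_expression_table",
    "write_expression_table",
    "to_one_based_closed",
    "from_one_based_closed",
]

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for a malformed line in a BED-like file; names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, order=True)
class Peak:
    """A called binding site: an interval with optional summit and read-support score."""

    interval: GenomicInterval
    summit: int | None = None
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, {self.interval.end})"
            )
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES and optional exon structure."""

    interval: GenomicInterval
    name: str
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r} requires an explicit strand")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"exon of {self.name!r} on a different chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon of {self.name!r} outside the gene span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons of {self.name!r} overlap or are unsorted")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on '+', ``end - 1`` on '-'."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site: ``end - 1`` on '+', ``start`` on '-'."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


# ---------------------------------------------------------------------------
# coordinate-convention adapters


def to_one_based_closed(interval: GenomicInterval) -> tuple[str, int, int]:
    """(chrom, start, end) in 1-based closed coordinates."""
    return interval.chrom, interval.start + 1, interval.end


def from_one_based_closed(
    chrom: str, start: int, end: int, strand: str = "."
) -> GenomicInterval:
    """Build an interval from 1-based closed coordinates."""
    return GenomicInterval(chrom, start - 1, end, strand)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Peak]:
    """Read a BED3..BED6 file into Peaks, preserving input order.

    Column 5 becomes the peak score (read support); missing columns default
    to name ``'.'``, score 0 and unstranded.  Raises :class:`BedParseError`
    with the offending line number on malformed input.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                interval = GenomicInterval(chrom, start, end, strand)
                peaks.append(Peak(interval, score=score, name=name))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED6 so that ``read_bed`` reproduces them."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t{p.strand}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record) FASTA into ``{name: uppercased sequence}``."""
    records: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                if name in records:
                    raise ValueError(f"duplicate FASTA record {name!r}")
                chunks = []
            elif line:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line.upper())
    if name is not None:
        if name in records:
            raise ValueError(f"duplicate FASTA record {name!r}")
        records[name] = "".join(chunks)
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene table (flat TSV dialect; full GTF/GFF is deliberately out of scope)


def _parse_exons(chrom: str, spec: str, strand: str) -> tuple[GenomicInterval, ...]:
    if not spec or spec == ".":
        return ()
    exons = []
    for part in spec.split(";"):
        s, e = part.split("-")
        exons.append(GenomicInterval(chrom, int(s), int(e), strand))
    return tuple(exons)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a TSV gene table with header columns chrom,start,end,strand,name[,exons].

    ``exons`` is a ``;``-separated list of ``start-end`` spans within the gene.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "start", "end", "strand", "name"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"gene table must have header columns {sorted(required)}"
            )
        for row in reader:
            strand = row["strand"]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"unknown strand {strand!r} for gene {row['name']!r}"
                )
            interval = GenomicInterval(
                row["chrom"], int(row["start"]), int(row["end"]), strand
            )
            exons = _parse_exons(row["chrom"], row.get("exons", "") or "", strand)
            genes.append(GeneModel(interval, row["name"], exons))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tname\texons\n")
        for g in genes:
            exons = ";".join(f"{e.start}-{e.end}" for e in g.exons) or "."
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.strand}"
                f"\t{g.name}\t{exons}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph (chrom, start, end, value) — the on-disk form of a coverage track


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Expand a bedGraph into per-chromosome base-resolution arrays."""
    values = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: fewer than 4 columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in values:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            values[chrom][start:end] = value
    return values


def write_bedgraph(values: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-chromosome arrays as run-length-collapsed bedGraph (zeros skipped)."""
    with open(path, "w") as fh:
        for chrom in values:
            arr = np.asarray(values[chrom])
            if arr.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# expression table


def read_expression_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV ``gene<TAB>log2_expression`` (header optional)."""
    expr: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            name, value = line.split("\t")[:2]
            if lineno == 1:
                try:
                    float(value)
                except ValueError:
                    continue  # header row
            expr[name] = float(value)
    return expr


def write_expression_table(expr: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlog2_expression\n")
        for name, value in expr.items():
            fh.write(f"{name}\t{value:.6g}\n")
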