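"""Coverage tracks and site-centered binned signal matrices.

Mapped reads (BED6 5'-position records) are extended to a fixed fragment
length in their strand direction and piled up into a base-resolution
coverage track.  Signal around binding sites is summarized in a sites x bins
matrix (default 80 bins of 50 bp spanning +/-2 kb around each peak center);
column means of that matrix give the cumulative (average) binding profile,
and rows sorted by decreasing mean give the standard heatmap ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import peak_center
from .io import GenomicInterval, Peak

__all__ = [
    "SignalTrack",
    "SignalMatrix",
    "build_coverage",
    "extract_matrix",
    "cumulative_profile",
    "order_by_average_binding",
    "normalize_track",
]


@dataclass
class SignalTrack:
    """Per-chromosome base-resolution coverage plus the library size it came from."""

    values: dict[str, np.ndarray]
    library_size: float
    normalized: bool = False
    name: str = "track"

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def chrom_sizes(self) -> dict[str, int]:
        return {c: int(v.size) for c, v in self.values.items()}


def build_coverage(
    reads: Sequence[GenomicInterval | Peak],
    extension: int,
    chrom_sizes: Mapping[str, int],
    name: str = "track",
) -> SignalTrack:
    """Pile up reads extended to ``extension`` bases from their 5' ends.

    A '+' read's fragment is ``[start, start + extension)``; a '-' read's is
    ``[end - extension, end)``; ``extension == 0`` keeps each read's own
    interval.  Fragments are clipped at chromosome bounds (with a warning
    when clipping occurs).  Coverage at a base is the number of fragments
    overlapping it, so total mass equals the sum of effective fragment
    lengths.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    # difference arrays: +1 at fragment start, -1 at fragment end
    diffs = {c: np.zeros(n + 1, dtype=np.float64) for c, n in chrom_sizes.items()}
    n_clipped = 0
    n_reads = 0
    starts_by_chrom: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    ends_by_chrom: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    for r in reads:
        iv = r.interval if isinstance(r, Peak) else r
        if iv.chrom not in diffs:
            raise ValueError(f"read on unknown chromosome {iv.chrom!r}")
        size = chrom_sizes[iv.chrom]
        if extension == 0:
            s, e = iv.start, iv.end
        elif iv.strand == "-":
            s, e = iv.end - extension, iv.end
        else:
            s, e = iv.start, iv.start + extension
        cs, ce = max(0, s), min(size, e)
        if (cs, ce) != (s, e):
            n_clipped += 1
        if ce > cs:
            starts_by_chrom[iv.chrom].append(cs)
            ends_by_chrom[iv.chrom].append(ce)
        n_reads += 1
    for chrom, diff in diffs.items():
        if starts_by_chrom[chrom]:
            np.add.at(diff, np.asarray(starts_by_chrom[chrom]), 1.0)
            np.add.at(diff, np.asarray(ends_by_chrom[chrom]), -1.0)
    if n_clipped:
        warnings.warn(f"{n_clipped} fragments clipped at chromosome bounds", stacklevel=2)
    values = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return SignalTrack(values=values, library_size=float(n_reads), name=name)


def normalize_track(track: SignalTrack, mode: str = "rpm") -> SignalTrack:
    """Scale a track to reads-per-million (values x 1e6 / library size)."""
    if mode != "rpm":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if track.library_size <= 0:
        raise ValueError("cannot RPM-normalize a track with zero library size")
    factor = 1e6 / track.library_size
    return SignalTrack(
        values={c: v * factor for c, v in track.values.items()},
        library_size=track.library_size,
        normalized=True,
        name=track.name,
    )


@dataclass
class SignalMatrix:
    """Sites x bins matrix of mean per-base signal around peak centers."""

    site_ids: list[str]
    sites: list[Peak]
    bin_edges: np.ndarray  # offsets relative to center, length n_bins + 1
    values: np.ndarray  # shape (n_sites, n_bins)
    track_name: str = "track"
    site_set_name: str = "sites"
    dropped: list[Peak] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_tsv(self, path: str | Path) -> None:
        """Export as TSV: one row per site, columns labelled by bin midpoint offset."""
        with open(path, "w") as fh:
            header = "\t".join(
                ["site"] + [f"{int(m)}" for m in self.bin_midpoints]
            )
            fh.write(header + "\n")
            for sid, row in zip(self.site_ids, self.values):
                fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def _site_id(p: Peak) -> str:
    return f"{p.chrom}:{p.start}-{p.end}"


def extract_matrix(
    track: SignalTrack,
    sites: Sequence[Peak],
    flank: int = 2_000,
    bin_size: int = 50,
    site_set_name: str = "sites",
) -> SignalMatrix:
    """Mean per-base coverage in ``bin_size`` bins over +/-``flank`` around
    each peak center.

    The mean (rather than the sum) makes cell values invariant to the bin
    size.  Sites whose window leaves the chromosome are dropped and reported
    in ``.dropped`` rather than zero-padded, so cumulative profiles carry no
    artificial edge depression.
    """
    if (2 * flank) % bin_size != 0:
        raise ValueError("bin size must divide the 2*flank window evenly")
    n_bins = (2 * flank) // bin_size
    rows: list[np.ndarray] = []
    kept: list[Peak] = []
    dropped: list[Peak] = []
    for site in sites:
        chrom_values = track.values.get(site.chrom)
        center = peak_center(site)
        lo, hi = center - flank, center + flank
        if chrom_values is None or lo < 0 or hi > chrom_values.size:
            dropped.append(site)
            continue
        window = chrom_values[lo:hi]
        rows.append(window.reshape(n_bins, bin_size).mean(axis=1))
        kept.append(site)
    values = (
        np.vstack(rows) if rows else np.empty((0, n_bins), dtype=np.float64)
    )
    edges = np.arange(-flank, flank + bin_size, bin_size)
    return SignalMatrix(
        site_ids=[_site_id(p) for p in kept],
        sites=kept,
        bin_edges=edges,
        values=values,
        track_name=track.name,
        site_set_name=site_set_name,
        dropped=dropped,
    )


def cumulative_profile(matrix: SignalMatrix) -> np.ndarray:
    """Column means of the signal matrix: the average binding shape across sites."""
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot profile an empty matrix")
    return matrix.values.mean(axis=0)


def order_by_average_binding(matrix: SignalMatrix) -> np.ndarray:
    """Row permutation sorting sites by decreasing mean signal over the window.

    Ties are broken by (chrom, start) ascending, so the ordering is stable
    and deterministic — the standard top-to-bottom heatmap layout.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot order an empty matrix")
    means = matrix.values.mean(axis=1)
    keys = [
        (-means[i], matrix.sites[i].chrom, matrix.sites[i].start)
        for i in range(len(matrix.sites))
    ]
    return np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=np.int64)
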