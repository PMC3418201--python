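"""Position weight matrices and log-odds genome scanning.

A PWM is built from aligned bound-site sequences by the standard
count-matrix procedure with a background-proportional pseudocount.  Scanning
scores every window w of length L as

    score(w) = sum_i ln( p_i(w_i) / bg(w_i) )

(natural-log odds, the Patser convention); windows at or above a threshold
— by default 60% of the maximum achievable score — are reported on both
strands, with reverse-strand hits mapped back to forward coordinates.
Hit occurrences around binding sites are binned into the same sites x bins
matrix layout used for read coverage, so motif heatmaps align with binding
heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import peak_center
from .io import Peak
from .signal import SignalMatrix

__all__ = [
    "PWM",
    "MotifHit",
    "build_pwm",
    "scan_sequence",
    "scan_genome",
    "motif_occurrence_matrix",
    "read_jaspar",
    "write_jaspar",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G


def _encode(sequence: str) -> np.ndarray:
    """Map a nucleotide string to ints (A=0..T=3, anything else = 4)."""
    table = np.full(256, 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int  # 0-based forward-strand coordinate of the match
    strand: str
    score: float


@dataclass
class PWM:
    """Per-position nucleotide probabilities with a background model."""

    probs: np.ndarray  # shape (L, 4), rows sum to 1
    background: np.ndarray  # shape (4,), sums to 1
    pseudocount: float = 1.0
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (L, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Natural-log odds matrix ln(p/bg), shape (L, 4)."""
        return np.log(self.probs) - np.log(self.background)[None, :]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits, relative to uniform background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(self.probs > 0, self.probs * np.log2(self.probs * 4), 0.0)
        return terms.sum(axis=1)


def build_pwm(
    aligned_sequences: Sequence[str],
    pseudocount_weight: float = 1.0,
    background: Sequence[float] | None = None,
    name: str = "motif",
) -> PWM:
    """Count-matrix PWM from equal-length aligned sequences.

    ``p(b at i) = (count_i(b) + w * bg_b) / (n_valid_i + w)`` where ``w`` is
    the pseudocount weight distributed by background composition.  N bases
    are excluded from the counts.  The background defaults to the
    mononucleotide composition of the input sequences.
    """
    if not aligned_sequences:
        raise ValueError("need at least one sequence")
    L = len(aligned_sequences[0])
    if any(len(s) != L for s in aligned_sequences):
        raise ValueError("aligned sequences must all have the same length")
    counts = np.zeros((L, 4), dtype=np.float64)
    for seq in aligned_sequences:
        enc = _encode(seq)
        valid = enc < 4
        np.add.at(counts, (np.nonzero(valid)[0], enc[valid]), 1.0)
    if background is None:
        total = counts.sum(axis=0)
        if total.sum() == 0:
            raise ValueError("no ACGT bases in input sequences")
        bg = total / total.sum()
        bg = np.clip(bg, 1e-6, None)
        bg = bg / bg.sum()
    else:
        bg = np.asarray(background, dtype=np.float64)
        bg = bg / bg.sum()
    n_valid = counts.sum(axis=1, keepdims=True)
    if pseudocount_weight == 0 and (counts == 0).all(axis=1).any():
        raise ValueError("a position has no valid bases and pseudocount is 0")
    probs = (counts + pseudocount_weight * bg[None, :]) / (
        n_valid + pseudocount_weight
    )
    return PWM(probs=probs, background=bg, pseudocount=pseudocount_weight, name=name)


def scan_sequence(
    pwm: PWM,
    sequence: str,
    threshold: float | None = None,
    threshold_frac: float = 0.6,
    both_strands: bool = True,
    chrom: str = "seq",
) -> list[MotifHit]:
    """All windows scoring at or above the threshold, sorted by coordinate.

    ``threshold`` defaults to ``threshold_frac * pwm.max_score``.  Windows
    containing non-ACGT bases are skipped.  Reverse-strand hits are scored
    on the reverse complement and reported at forward coordinates.  Scoring
    is case-insensitive.
    """
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError("sequence shorter than the motif")
    if threshold is None:
        threshold = threshold_frac * pwm.max_score
    if threshold > pwm.max_score:
        warnings.warn(
            "threshold exceeds the maximum achievable score; no hits possible",
            stacklevel=2,
        )
        return []
    enc = _encode(sequence)
    n_windows = len(sequence) - L + 1
    is_n = enc >= 4
    # a window is valid iff it contains no N: rolling count via cumulative sum
    cs = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cs[L:] - cs[:-L]) == 0
    safe_enc = np.where(is_n, 0, enc)
    lo = pwm.log_odds
    hits: list[MotifHit] = []

    fwd_scores = np.zeros(n_windows, dtype=np.float64)
    for i in range(L):
        fwd_scores += lo[i].take(safe_enc[i : i + n_windows])
    for start in np.flatnonzero(valid & (fwd_scores >= threshold)):
        hits.append(MotifHit(chrom, int(start), "+", float(fwd_scores[start])))
    if both_strands:
        # reverse-complement scoring on the same forward encoding:
        # score_rev(w) = sum_i lo[L-1-i, complement(w_i)]
        lo_rc = lo[::-1][:, _COMPLEMENT_INDEX]
        rev_scores = np.zeros(n_windows, dtype=np.float64)
        for i in range(L):
            rev_scores += lo_rc[i].take(safe_enc[i : i + n_windows])
        for start in np.flatnonzero(valid & (rev_scores >= threshold)):
            hits.append(MotifHit(chrom, int(start), "-", float(rev_scores[start])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_genome(
    pwm: PWM,
    genome: Mapping[str, str],
    threshold: float | None = None,
    threshold_frac: float = 0.6,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan every chromosome of a genome; hits sorted by (chrom, start)."""
    hits: list[MotifHit] = []
    for chrom in sorted(genome):
        if len(genome[chrom]) < len(pwm):
            continue
        hits.extend(
            scan_sequence(
                pwm,
                genome[chrom],
                threshold=threshold,
                threshold_frac=threshold_frac,
                both_strands=both_strands,
                chrom=chrom,
            )
        )
    return hits


def motif_occurrence_matrix(
    hits: Iterable[MotifHit],
    sites: Sequence[Peak],
    flank: int = 2_000,
    bin_size: int = 50,
    site_set_name: str = "sites",
) -> SignalMatrix:
    """Count motif-hit start positions per bin around each site center.

    Same layout as the coverage matrices (default 80 bins of 50 bp over
    +/-2 kb), so occurrence heatmaps can be stacked against binding
    heatmaps row for row.
    """
    if (2 * flank) % bin_size != 0:
        raise ValueError("bin size must divide the 2*flank window evenly")
    n_bins = (2 * flank) // bin_size
    hit_starts: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[int]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h.start)
    for chrom, starts in by_chrom.items():
        hit_starts[chrom] = np.sort(np.asarray(starts, dtype=np.int64))
    values = np.zeros((len(sites), n_bins), dtype=np.float64)
    for row, site in enumerate(sites):
        starts = hit_starts.get(site.chrom)
        if starts is None:
            continue
        center = peak_center(site)
        offsets = starts - center
        in_window = offsets[(offsets >= -flank) & (offsets < flank)]
        if in_window.size:
            idx = (in_window + flank) // bin_size
            np.add.at(values, (row, idx), 1.0)
    edges = np.arange(-flank, flank + bin_size, bin_size)
    return SignalMatrix(
        site_ids=[f"{p.chrom}:{p.start}-{p.end}" for p in sites],
        sites=list(sites),
        bin_edges=edges,
        values=values,
        track_name="motif_hits",
        site_set_name=site_set_name,
    )


# ---------------------------------------------------------------------------
# JASPAR-style plain-text count matrices


def read_jaspar(path: str | Path) -> PWM:
    """Read a JASPAR-style count matrix:

        >MOTIF_NAME
        A  [ 10  2 ... ]
        C  [  1  8 ... ]
        G  [ ... ]
        T  [ ... ]

    Counts are converted to probabilities with a pseudocount of 1 and a
    uniform background.
    """
    name = "motif"
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            base = line[0].upper()
            if base not in _BASE_INDEX:
                raise ValueError(f"unexpected matrix row {line!r}")
            numbers = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in numbers]
    if set(rows) != set(ALPHABET):
        raise ValueError("JASPAR matrix must have A, C, G and T rows")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError("JASPAR matrix rows have unequal lengths")
    counts = np.array([rows[b] for b in ALPHABET], dtype=np.float64).T  # (L, 4)
    bg = np.full(4, 0.25)
    probs = (counts + 1.0 * bg[None, :]) / (
        counts.sum(axis=1, keepdims=True) + 1.0
    )
    return PWM(probs=probs, background=bg, pseudocount=1.0, name=name)


def write_jaspar(pwm: PWM, path: str | Path, scale: int = 100) -> None:
    """Write a PWM as a JASPAR-style count matrix (probabilities x ``scale``)."""
    counts = np.rint(pwm.probs * scale).astype(int)
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for j, base in enumerate(ALPHABET):
            row = "  ".join(str(c) for c in counts[:, j])
            fh.write(f"{base}  [ {row} ]\n")
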