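"""Two-condition competition analysis at shared binding sites.

For each shared site, one factor's RPM-normalized signal is quantified in a
fixed window around the peak center in two conditions (with and without the
competing factor).  Sites whose signal changes by more than a fold
threshold (default 1.5x, after adding a small pseudo-signal epsilon) are
categorized *up* or *down*; the summary contrasts the mean log2-fold change
of the changed sites against that of all shared sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import peak_center
from .io import Peak
from .signal import SignalTrack

__all__ = [
    "CompetitionRecord",
    "CompetitionSummary",
    "quantify_site_signal",
    "competition_analysis",
]


def quantify_site_signal(
    track: SignalTrack, sites: Sequence[Peak], window: int = 300
) -> np.ndarray:
    """Mean coverage over +/-window/2 around each peak center.

    Windows reaching past a chromosome end are evaluated on the clipped
    region (with a warning); an empty clipped window yields 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    out = np.zeros(len(sites), dtype=np.float64)
    n_clipped = 0
    for i, site in enumerate(sites):
        values = track.values.get(site.chrom)
        if values is None:
            raise ValueError(f"site on unknown chromosome {site.chrom!r}")
        center = peak_center(site)
        lo, hi = center - half, center + (window - half)
        clo, chi = max(0, lo), min(values.size, hi)
        if (clo, chi) != (lo, hi):
            n_clipped += 1
        out[i] = values[clo:chi].mean() if chi > clo else 0.0
    if n_clipped:
        warnings.warn(
            f"{n_clipped} site windows clipped at chromosome bounds", stacklevel=2
        )
    return out


@dataclass(frozen=True)
class CompetitionRecord:
    site: Peak
    signal_cond1: float
    signal_cond2: float
    log2fc: float
    category: str  # up / down / unchanged


@dataclass
class CompetitionSummary:
    n_up: int
    n_down: int
    n_unchanged: int
    mean_log2fc_all: float
    mean_log2fc_changed: float
    fold_threshold: float
    epsilon: float

    def as_dict(self) -> dict:
        return {
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_unchanged": self.n_unchanged,
            "mean_log2fc_all": self.mean_log2fc_all,
            "mean_log2fc_changed": self.mean_log2fc_changed,
            "fold_threshold": self.fold_threshold,
            "epsilon": self.epsilon,
        }


def competition_analysis(
    shared_sites: Sequence[Peak],
    track_without: SignalTrack,
    track_with: SignalTrack,
    fold_threshold: float = 1.5,
    epsilon: float = 0.5,
    window: int = 300,
) -> tuple[list[CompetitionRecord], CompetitionSummary]:
    """Per-site log2-fold change of signal with vs without the competitor.

    ``log2fc = log2((signal_with + eps) / (signal_without + eps))``; category
    is *up* when the fold change exceeds ``fold_threshold``, *down* when it
    falls below ``1/fold_threshold``, else *unchanged*.  Both tracks must
    carry the same normalization state (RPM vs raw), otherwise fold changes
    would mix scales.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if track_without.normalized != track_with.normalized:
        raise ValueError("condition tracks have mismatched normalization")
    s1 = quantify_site_signal(track_without, shared_sites, window=window)
    s2 = quantify_site_signal(track_with, shared_sites, window=window)
    ratio = (s2 + epsilon) / (s1 + epsilon)
    log2fc = np.log2(ratio)
    log_thr = np.log2(fold_threshold)
    records: list[CompetitionRecord] = []
    for site, v1, v2, lfc in zip(shared_sites, s1, s2, log2fc):
        if lfc > log_thr:
            category = "up"
        elif lfc < -log_thr:
            category = "down"
        else:
            category = "unchanged"
        records.append(
            CompetitionRecord(
                site=site,
                signal_cond1=float(v1),
                signal_cond2=float(v2),
                log2fc=float(lfc),
                category=category,
            )
        )
    changed = log2fc[np.abs(log2fc) > log_thr]
    summary = CompetitionSummary(
        n_up=sum(1 for r in records if r.category == "up"),
        n_down=sum(1 for r in records if r.category == "down"),
        n_unchanged=sum(1 for r in records if r.category == "unchanged"),
        mean_log2fc_all=float(log2fc.mean()) if log2fc.size else float("nan"),
        mean_log2fc_changed=float(changed.mean()) if changed.size else float("nan"),
        fold_threshold=fold_threshold,
        epsilon=epsilon,
    )
    return records, summary


def records_to_frame(records: Sequence[CompetitionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.site.chrom for r in records],
            "start": [r.site.start for r in records],
            "end": [r.site.end for r in records],
            "signal_cond1": [r.signal_cond1 for r in records],
            "signal_cond2": [r.signal_cond2 for r in records],
            "log2fc": [r.log2fc for r in records],
            "category": [r.category for r in records],
        }
    )
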