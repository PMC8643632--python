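"""HAD calling: sliding-window smoothing and threshold/gap-merge segmentation.

The caller works on a per-chromosome track of ATAC-seq log2 fold-change
values (knockout over wildtype), one point per consensus peak. The track is
smoothed with a sliding mean over a fixed number of data points (not a
fixed genomic width — peak spacing carries the local information density),
then segmented: every smoothed point at or below the cutoff is domain-like,
and consecutive domain-like points are merged into one domain whenever the
genomic gap between their peak footprints is at most ``max_gap``,
regardless of any above-cutoff points in between. The cutoff default of
-0.58 is log2 of a 1.5-fold loss of accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Domain, DomainSet, GenomicInterval
from .sites import LfcTrack

__all__ = [
    "SmoothedTrack",
    "sliding_window_average",
    "call_domains",
    "exclude_chromosomes",
]


@dataclass(frozen=True)
class SmoothedChrom:
    """Smoothed values with their footprints on one chromosome.

    ``sup_starts``/``sup_ends`` delimit each point's support interval: the
    span of its own source peak. This is what domain calling merges on, so
    a single-point domain is one peak wide (sub-kilobase), matching the
    smallest domains the method can report. ``win_starts``/``win_ends``
    record the wider union span of all peaks contributing to the point's
    smoothing window, for inspection. One output point per input point.
    """

    anchors: np.ndarray
    values: np.ndarray
    sup_starts: np.ndarray
    sup_ends: np.ndarray
    win_starts: np.ndarray
    win_ends: np.ndarray

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class SmoothedTrack:
    per_chrom: dict[str, SmoothedChrom]
    window_points: int


def sliding_window_average(
    track: LfcTrack, window_points: int = 25, align: str = "centered"
) -> SmoothedTrack:
    """Smooth each chromosome's log2FC track with a sliding mean.

    ``align="centered"`` (default): point i averages indices
    [i-h, i+h] with h = (window_points - 1) // 2, truncated at chromosome
    ends so every input point yields an output point. ``align="trailing"``:
    point i averages [i - window_points + 1, i], truncated at the start.
    Windows never span chromosomes.

    ``window_points`` must be odd (and >= 1) for the centered alignment so
    the window is symmetric; an even value raises with instructions.
    """
    if align not in ("centered", "trailing"):
        raise ValueError("align must be 'centered' or 'trailing'")
    if window_points < 1:
        raise ValueError("window_points must be >= 1")
    if align == "centered" and window_points % 2 == 0:
        raise ValueError(
            f"window_points={window_points} is even; the centered window needs an "
            "odd number of points (e.g. use "
            f"{window_points + 1})"
        )
    center = align == "centered"
    out: dict[str, SmoothedChrom] = {}
    for chrom, ct in track.per_chrom.items():
        if len(ct) == 0:
            out[chrom] = SmoothedChrom(
                ct.anchors, ct.values.astype(float), ct.starts, ct.ends,
                ct.starts, ct.ends
            )
            continue
        roll = lambda s: s.rolling(window_points, min_periods=1, center=center)
        values = roll(pd.Series(ct.values)).mean().to_numpy()
        win_starts = roll(pd.Series(ct.starts)).min().to_numpy().astype(np.int64)
        win_ends = roll(pd.Series(ct.ends)).max().to_numpy().astype(np.int64)
        out[chrom] = SmoothedChrom(
            ct.anchors.copy(), values, ct.starts.copy(), ct.ends.copy(),
            win_starts, win_ends
        )
    return SmoothedTrack(out, window_points)


def call_domains(
    smoothed: SmoothedTrack,
    cutoff: float = -0.58,
    max_gap: int = 1_000_000,
    label: str = "HAD",
) -> DomainSet:
    """Segment a smoothed track into domains by cutoff and gap merging.

    Points with smoothed value <= cutoff (ties included: the printed -0.58
    is the rounded log2 of 1.5) are marked. Scanning each chromosome's
    marked points in order, a point joins the current domain when the gap
    between the domain's running footprint end and the point's support
    start is <= max_gap; intervening unmarked points never break a domain —
    only genomic distance does. A domain's interval is the union span of
    its members' support intervals; n_support counts members; mean_value
    averages member smoothed values. A single isolated marked point yields
    a domain covering its own support interval.
    """
    domains: list[Domain] = []
    for chrom, sc in smoothed.per_chrom.items():
        if len(sc) == 0:
            continue
        marked = np.flatnonzero(sc.values <= cutoff)
        if marked.size == 0:
            continue
        cur_start = int(sc.sup_starts[marked[0]])
        cur_end = int(sc.sup_ends[marked[0]])
        members = [float(sc.values[marked[0]])]
        for idx in marked[1:]:
            s, e = int(sc.sup_starts[idx]), int(sc.sup_ends[idx])
            if s - cur_end <= max_gap:
                cur_start = min(cur_start, s)
                cur_end = max(cur_end, e)
                members.append(float(sc.values[idx]))
            else:
                domains.append(
                    Domain(
                        GenomicInterval(chrom, cur_start, cur_end),
                        n_support=len(members),
                        mean_value=float(np.mean(members)),
                    )
                )
                cur_start, cur_end = s, e
                members = [float(sc.values[idx])]
        domains.append(
            Domain(
                GenomicInterval(chrom, cur_start, cur_end),
                n_support=len(members),
                mean_value=float(np.mean(members)),
            )
        )
    return DomainSet.from_domains(domains, label=label)


def exclude_chromosomes(domains: DomainSet, excluded: set[str]) -> DomainSet:
    """Drop domains on excluded chromosomes (e.g. chrY), preserving order."""
    return DomainSet.from_domains(
        (d for d in domains if d.interval.chrom not in set(excluded)),
        label=domains.label,
    )
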