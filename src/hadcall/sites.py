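"""Differential-site selection and per-chromosome log2FC track construction.

The differential peak table (one row per ATAC-seq consensus peak, with a
knockout-vs-wildtype log2 fold change and a p-value) is the raw substrate
for domain calling. Selection picks the significantly differential sites
for the headline counts; the smoothing track is built from ALL peaks,
because the domain signal lives in the genome-wide fold-change profile,
not only in the individually significant sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GenomicInterval

__all__ = [
    "AnalysisParameters",
    "ChromTrack",
    "LfcTrack",
    "select_differential_sites",
    "build_lfc_track",
]


@dataclass(frozen=True)
class AnalysisParameters:
    """All analysis thresholds with their defaults.

    da_lfc_threshold / da_p_threshold select differentially accessible
    sites (|log2FC| >= 1, p < 0.01). window_points is the sliding-window
    size in data points; domain_cutoff is the smoothed log2FC at or below
    which a window is domain-like (-0.58, i.e. a 1.5-fold loss); max_gap is
    the largest genomic gap (bp) bridged when merging domain-like windows.
    density_bin is the bin width for peak-density tracks. de_fold_threshold
    / de_p_threshold select differentially expressed genes (1.5-fold,
    p < 0.05). Promoter windows extend upstream/downstream of the TSS.
    chrY is excluded from domain reporting by default.
    """

    da_lfc_threshold: float = 1.0
    da_p_threshold: float = 0.01
    window_points: int = 25
    domain_cutoff: float = -0.58
    max_gap: int = 1_000_000
    density_bin: int = 1_000_000
    de_fold_threshold: float = 1.5
    de_p_threshold: float = 0.05
    promoter_upstream: int = 3000
    promoter_downstream: int = 3000
    downstream_window: int = 3000
    excluded_chromosomes: frozenset[str] = frozenset({"chrY"})
    use_fdr: bool = False

    def __post_init__(self) -> None:
        if self.da_lfc_threshold <= 0 or self.da_p_threshold <= 0:
            raise ValueError("selection thresholds must be positive")
        if self.domain_cutoff >= 0:
            raise ValueError("domain_cutoff must be negative (a loss of accessibility)")
        if self.window_points < 1:
            raise ValueError("window_points must be >= 1")
        if self.max_gap < 0 or self.density_bin <= 0:
            raise ValueError("max_gap/density_bin must be non-negative/positive")
        if self.de_fold_threshold <= 1 or self.de_p_threshold <= 0:
            raise ValueError("DE thresholds must be > 1 fold and > 0 p")
        object.__setattr__(
            self, "excluded_chromosomes", frozenset(self.excluded_chromosomes)
        )


@dataclass(frozen=True)
class ChromTrack:
    """Ordered anchors with values and source-interval footprints on one
    chromosome. Arrays are parallel and sorted by (anchor, start, end)."""

    anchors: np.ndarray  # int64 bp
    values: np.ndarray  # float64 log2FC
    starts: np.ndarray  # int64, source interval start
    ends: np.ndarray  # int64, source interval end

    def __post_init__(self) -> None:
        n = len(self.anchors)
        if not (len(self.values) == len(self.starts) == len(self.ends) == n):
            raise ValueError("track arrays must be parallel")

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class LfcTrack:
    """Per-chromosome log2FC tracks keyed by chromosome name."""

    per_chrom: dict[str, ChromTrack]

    def n_points(self) -> int:
        return sum(len(t) for t in self.per_chrom.values())


def select_differential_sites(
    table: pd.DataFrame, params: AnalysisParameters = AnalysisParameters()
) -> tuple[pd.DataFrame, dict]:
    """Select differentially accessible sites and summarize directionality.

    A site is selected when |log2fc| >= da_lfc_threshold (boundary included)
    and p < da_p_threshold (strict). When ``params.use_fdr`` is set and the
    table carries an ``fdr`` column, the FDR column is thresholded instead
    of the raw p-value.

    Returns ``(selected, summary)`` where summary holds ``n_total``
    (selected count), ``n_down`` (selected with log2fc < 0) and
    ``fraction_down`` (NaN when nothing is selected).
    """
    pcol = "fdr" if (params.use_fdr and "fdr" in table.columns) else "p_value"
    mask = (table["log2fc"].abs() >= params.da_lfc_threshold) & (
        table[pcol] < params.da_p_threshold
    )
    selected = table.loc[mask].copy()
    n_total = int(len(selected))
    n_down = int((selected["log2fc"] < 0).sum())
    fraction_down = (n_down / n_total) if n_total else float("nan")
    summary = {"n_total": n_total, "n_down": n_down, "fraction_down": fraction_down}
    return selected, summary


def build_lfc_track(table: pd.DataFrame, layout: GenomeLayout) -> LfcTrack:
    """Build per-chromosome (anchor, log2fc) tracks from ALL peaks.

    The anchor is the interval midpoint, floor((start + end) / 2). Points
    are sorted by anchor within each chromosome; records sharing an anchor
    are kept and ordered by (start, end). Chromosomes absent from the table
    get an empty track; chromosomes absent from the layout are an error.
    """
    per_chrom: dict[str, ChromTrack] = {}
    for chrom in table["chrom"].unique():
        if chrom not in layout:
            raise KeyError(f"table chromosome {chrom!r} not in genome layout")
    empty = np.array([], dtype=np.int64)
    for chrom in layout.names:
        grp = table.loc[table["chrom"] == chrom]
        if grp.empty:
            per_chrom[chrom] = ChromTrack(
                empty, np.array([], dtype=float), empty.copy(), empty.copy()
            )
            continue
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        anchors = (starts + ends) // 2
        values = grp["log2fc"].to_numpy(float)
        order = np.lexsort((ends, starts, anchors))
        per_chrom[chrom] = ChromTrack(
            anchors[order], values[order], starts[order], ends[order]
        )
    return LfcTrack(per_chrom)
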