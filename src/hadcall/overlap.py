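"""Domain-set versus domain-set comparison.

Element-wise overlap fraction (the "86% of HADs overlap LADs" style
statistic), base-pair Jaccard, and a circular-rotation permutation test for
overlap significance. "Overlap" defaults to >= 1 bp, since published
domain-overlap percentages rarely state a threshold; ``min_bp`` and a
minimum-fraction variant are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import (
    DomainSet,
    GenomeLayout,
    GenomicInterval,
    intersection_bp,
    merge_intervals,
    rotate_interval,
    union_bp,
)

__all__ = [
    "overlap_fraction",
    "basepair_jaccard",
    "OverlapPermutationResult",
    "overlap_permutation_test",
]


def _merged_by_chrom(domains: DomainSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    merged = merge_intervals(list(domains.intervals))
    for chrom in {iv.chrom for iv in merged}:
        ivs = [iv for iv in merged if iv.chrom == chrom]
        out[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    return out


def _pieces_overlap_bp(pieces, subject_idx) -> int:
    total = 0
    for iv in pieces:
        entry = subject_idx.get(iv.chrom)
        if entry is None:
            continue
        starts, ends = entry
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        total += int(np.clip(ov, 0, None).sum())
    return total


def overlap_fraction(
    query: DomainSet,
    subject: DomainSet,
    min_bp: int = 1,
    min_fraction: float | None = None,
) -> float:
    """Fraction of query domains overlapping the subject union.

    Subject domains are merged first so overlapping subject annotations are
    not double counted. A query domain counts when its total overlap with
    the subject union is >= min_bp (or >= min_fraction of its own length,
    when given). NaN for an empty query. Note the statistic is asymmetric
    in (query, subject).
    """
    if len(query) == 0:
        return float("nan")
    subject_idx = _merged_by_chrom(subject)
    n_hit = 0
    for d in query:
        ov = _pieces_overlap_bp([d.interval], subject_idx)
        need = min_bp
        if min_fraction is not None:
            need = max(need, min_fraction * d.interval.length)
        if ov >= need:
            n_hit += 1
    return n_hit / len(query)


def basepair_jaccard(a: DomainSet, b: DomainSet) -> float:
    """|intersection| / |union| in base pairs over the merged sets.

    Returns NaN when both sets are empty (0/0)."""
    inter = intersection_bp(list(a.intervals), list(b.intervals))
    uni = union_bp(list(a.intervals), list(b.intervals))
    if uni == 0:
        return float("nan")
    return inter / uni


@dataclass(frozen=True)
class OverlapPermutationResult:
    observed: float
    perm_p: float
    n_perm: int
    null: np.ndarray

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null.std(ddof=1)) if len(self.null) > 1 else float("nan")


def overlap_permutation_test(
    query: DomainSet,
    subject: DomainSet,
    layout: GenomeLayout,
    n_perm: int = 199,
    seed: int = 0,
    min_bp: int = 1,
) -> OverlapPermutationResult:
    """Significance of the query/subject overlap fraction under a
    circular-rotation null.

    Each permutation rotates the query domains along their chromosomes by
    an independent uniform offset with wrap-around, preserving the length
    multiset and spacings; a wrapped domain's overlap sums over its two
    pieces. One-sided p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(query) == 0:
        raise ValueError("empty query domain set")
    subject_idx = _merged_by_chrom(subject)
    observed = overlap_fraction(query, subject, min_bp=min_bp)
    rng = np.random.default_rng(seed)
    chroms = sorted({d.interval.chrom for d in query})
    null = np.empty(n_perm)
    for k in range(n_perm):
        offsets = {c: int(rng.integers(0, layout.length_of(c))) for c in chroms}
        n_hit = 0
        for d in query:
            length = layout.length_of(d.interval.chrom)
            pieces = rotate_interval(d.interval, length, offsets[d.interval.chrom])
            if _pieces_overlap_bp(pieces, subject_idx) >= min_bp:
                n_hit += 1
        null[k] = n_hit / len(query)
    perm_p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return OverlapPermutationResult(observed, perm_p, n_perm, null)
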