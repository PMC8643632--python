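"""Coordinate conventions, interval types and interval arithmetic.

All coordinates are 0-based, half-open (BED-native) everywhere inside the
package; readers for 1-based formats (GTF) convert at the boundary.
Chromosome names match by exact text — no "chr" aliasing; use
:func:`rename_chromosomes` to harmonize inputs explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "PeakRecord",
    "Domain",
    "DomainSet",
    "interval_overlap_bp",
    "merge_intervals",
    "total_bp",
    "intersection_bp",
    "union_bp",
    "positions_in_intervals",
    "rotate_interval",
    "rename_chromosomes",
]


class HadcallError(Exception):
    """Base class for user-facing errors raised by this package."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths defining the coordinate space.

    The order of ``chromosomes`` is stable and defines genome-wide ordering
    (e.g. for report tables and genome-wide tracks).
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeLayout":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"chromosome {chrom!r} not in layout")

    def total_length(self, excluded: Iterable[str] = ()) -> int:
        excluded = set(excluded)
        return sum(l for name, l in self.chromosomes if name not in excluded)

    def validate_interval(self, iv: GenomicInterval) -> None:
        length = self.length_of(iv.chrom)
        if iv.end > length:
            raise ValueError(
                f"interval {iv.chrom}:[{iv.start},{iv.end}) exceeds chromosome "
                f"length {length}"
            )


@dataclass(frozen=True)
class PeakRecord:
    """One peak: an interval with optional score and summit offset."""

    interval: GenomicInterval
    score: float | None = None
    summit_offset: int | None = None
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None:
            if not (0 <= self.summit_offset < self.interval.length):
                raise ValueError(
                    f"summit offset {self.summit_offset} outside peak of length "
                    f"{self.interval.length}"
                )


@dataclass(frozen=True)
class Domain:
    """A called or annotated domain with its supporting statistics."""

    interval: GenomicInterval
    n_support: int = 0
    mean_value: float = 0.0
    name: str | None = None


@dataclass(frozen=True)
class DomainSet:
    """Sorted, per-chromosome non-overlapping domains with a set label."""

    domains: tuple[Domain, ...]
    label: str = ""

    @classmethod
    def from_domains(cls, domains: Iterable[Domain], label: str = "") -> "DomainSet":
        return cls(tuple(domains), label)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], label: str = ""
    ) -> "DomainSet":
        return cls(tuple(Domain(iv) for iv in intervals), label)

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self) -> Iterator[Domain]:
        return iter(self.domains)

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return tuple(d.interval for d in self.domains)

    def by_chrom(self) -> dict[str, list[Domain]]:
        out: dict[str, list[Domain]] = {}
        for d in self.domains:
            out.setdefault(d.interval.chrom, []).append(d)
        return out

    def sizes(self) -> np.ndarray:
        return np.array([d.interval.length for d in self.domains], dtype=np.int64)

    def total_bp(self) -> int:
        return int(self.sizes().sum()) if self.domains else 0

    def sorted(self, layout: GenomeLayout | None = None) -> "DomainSet":
        """Return a copy sorted genome-wide (layout order if given)."""
        if layout is not None:
            order = {name: i for i, name in enumerate(layout.names)}
            key = lambda d: (order[d.interval.chrom], d.interval.start, d.interval.end)
        else:
            key = lambda d: (d.interval.chrom, d.interval.start, d.interval.end)
        return replace(self, domains=tuple(sorted(self.domains, key=key)))

    def validate(self, layout: GenomeLayout | None = None) -> None:
        """Check sortedness and per-chromosome non-overlap; optionally bounds."""
        for chrom, doms in self.by_chrom().items():
            prev_end = -1
            for d in doms:
                if d.interval.start < prev_end:
                    raise ValueError(
                        f"domains on {chrom} overlap or are unsorted near "
                        f"{d.interval.start}"
                    )
                prev_end = d.interval.end
                if layout is not None:
                    layout.validate_interval(d.interval)

    def restricted_to(self, chroms: Iterable[str]) -> "DomainSet":
        keep = set(chroms)
        return replace(
            self, domains=tuple(d for d in self.domains if d.interval.chrom in keep)
        )


def interval_overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals (0 if on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: merged, sorted, per-chromosome non-overlapping.

    Abutting intervals ([0,10) and [10,20)) are merged into one.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def total_bp(intervals: Sequence[GenomicInterval]) -> int:
    """Total bp covered by the union of the intervals."""
    return sum(iv.length for iv in merge_intervals(intervals)) if intervals else 0


def intersection_bp(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Base pairs in the intersection of two interval collections."""
    if not a or not b:
        return 0
    bm = merge_intervals(b)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in bm}:
        ivs = [iv for iv in bm if iv.chrom == chrom]
        by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    total = 0
    for iv in merge_intervals(a):
        if iv.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[iv.chrom]
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        total += int(np.clip(ov, 0, None).sum())
    return total


def union_bp(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    return total_bp(list(a) + list(b))


def positions_in_intervals(
    positions: np.ndarray, intervals: Sequence[GenomicInterval], chrom: str
) -> np.ndarray:
    """Boolean mask: which positions (on ``chrom``) fall in the interval union."""
    ivs = merge_intervals([iv for iv in intervals if iv.chrom == chrom])
    if not ivs:
        return np.zeros(len(positions), dtype=bool)
    starts = np.array([iv.start for iv in ivs])
    ends = np.array([iv.end for iv in ivs])
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    ok[ok] &= positions[ok] < ends[idx[ok]]
    return ok


def rotate_interval(
    iv: GenomicInterval, chrom_length: int, offset: int
) -> list[GenomicInterval]:
    """Circularly shift an interval along its chromosome with wrap-around.

    Returns one piece, or two when the shifted interval crosses the
    chromosome end. Piece lengths always sum to the original length, which
    is what makes circular rotation a structure-preserving permutation null.
    """
    if iv.end > chrom_length:
        raise ValueError("interval exceeds chromosome length")
    start = (iv.start + offset) % chrom_length
    end = start + iv.length
    if end <= chrom_length:
        return [GenomicInterval(iv.chrom, start, end)]
    return [
        GenomicInterval(iv.chrom, start, chrom_length),
        GenomicInterval(iv.chrom, 0, end - chrom_length),
    ]


def rename_chromosomes(
    layout_or_domains, mapping: dict[str, str]
):
    """Explicitly rename chromosomes in a GenomeLayout or DomainSet.

    Names absent from ``mapping`` are kept as-is. Provided instead of any
    silent "chr" aliasing so that naming mismatches surface as zero overlaps
    the user must resolve deliberately.
    """
    if isinstance(layout_or_domains, GenomeLayout):
        return GenomeLayout.from_pairs(
            (mapping.get(n, n), l) for n, l in layout_or_domains.chromosomes
        )
    if isinstance(layout_or_domains, DomainSet):
        new = tuple(
            replace(
                d,
                interval=GenomicInterval(
                    mapping.get(d.interval.chrom, d.interval.chrom),
                    d.interval.start,
                    d.interval.end,
                ),
            )
            for d in layout_or_domains.domains
        )
        return replace(layout_or_domains, domains=new)
    raise TypeError("expected GenomeLayout or DomainSet")
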