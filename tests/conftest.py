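"""Shared fixtures and independent brute-force oracles.

The oracles here recompute results by exhaustive enumeration (per-base-pair
membership, all-pairs merge closure, direct window means) and are kept free
of any hadcall internals beyond the plain data types, so that agreement
with them is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hadcall.genome import Domain, DomainSet, GenomeLayout, GenomicInterval
from hadcall.simulate import SimulationParams, SyntheticTruth, generate_truth


@pytest.fixture(scope="session")
def toy_layout() -> GenomeLayout:
    return GenomeLayout.from_pairs([("chr1", 10_000_000), ("chr2", 8_000_000),
                                    ("chrY", 2_000_000)])


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A scaled-down generator configuration for fast unit tests."""
    return SimulationParams(
        n_chroms=2,
        chrom_length=20_000_000,
        n_lads_per_chrom=3,
        lad_size_range=(1_000_000, 2_000_000),
        n_de_down=60,
        n_de_up=24,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_params) -> SyntheticTruth:
    return generate_truth(small_params)


# ---------------------------------------------------------------------------
# oracle helpers


def overlap_bp_oracle(a: GenomicInterval, b: GenomicInterval) -> int:
    """Per-base-pair membership count; only for short intervals."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def sliding_mean_oracle(values, window_points: int) -> list[float]:
    """Direct truncated centered mean, one pass per point."""
    h = (window_points - 1) // 2
    n = len(values)
    return [
        float(np.mean(values[max(0, i - h): min(n, i + h + 1)])) for i in range(n)
    ]


def _interval_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    if s2 < e1 and s1 < e2:
        return 0
    return max(s2 - e1, s1 - e2)


def call_domains_oracle(anchors, values, starts, ends, cutoff, max_gap):
    """All-pairs transitive merge closure over marked points (union-find).

    Two marked points join when the gap between their support intervals is
    <= max_gap; components become domains spanning min start to max end.
    Returns a list of (start, end, n_support, mean_value) sorted by start.
    """
    marked = [i for i, v in enumerate(values) if v <= cutoff]
    if not marked:
        return []
    parent = {i: i for i in marked}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in marked:
        for b in marked:
            if a < b and _interval_gap(starts[a], ends[a], starts[b], ends[b]) <= max_gap:
                parent[find(b)] = find(a)
    comps: dict[int, list[int]] = {}
    for i in marked:
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        out.append(
            (
                min(starts[i] for i in members),
                max(ends[i] for i in members),
                len(members),
                float(np.mean([values[i] for i in members])),
            )
        )
    return sorted(out)


def random_track(rng: np.random.Generator, n_max: int = 50):
    """A random single-chromosome track with sorted, non-nested peaks.

    Anchor gaps exceed the maximum peak width so supports are strictly
    ordered, matching the geometry of real consensus-peak tracks.
    """
    n = int(rng.integers(1, n_max + 1))
    gaps = rng.integers(1_500, 120_000, size=n)
    anchors = np.cumsum(gaps)
    widths = rng.integers(200, 1_001, size=n)
    starts = anchors - widths // 2
    ends = starts + widths
    values = rng.normal(0.0, 1.0, size=n)
    return anchors, values, starts, ends


def overlap_fraction_oracle(query: DomainSet, subject: DomainSet, min_bp: int = 1):
    """Per-base membership count of each query domain against the subject
    union; only for sets whose total span is small."""
    covered: dict[str, set[int]] = {}
    for iv in subject.intervals:
        covered.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    if len(query) == 0:
        return float("nan")
    hits = 0
    for iv in query.intervals:
        n = len(covered.get(iv.chrom, set()) & set(range(iv.start, iv.end)))
        if n >= min_bp:
            hits += 1
    return hits / len(query)


def make_domains(triples, label="test") -> DomainSet:
    """DomainSet from (chrom, start, end) triples."""
    return DomainSet.from_intervals(
        [GenomicInterval(c, s, e) for c, s, e in triples], label=label
    )


def make_diff_table(rows) -> pd.DataFrame:
    """Differential table from (chrom, start, end, log2fc, p) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2fc", "p_value"])
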