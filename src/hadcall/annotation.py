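"""Domain and site characterization.

Size distributions, genome fraction, gene density inside versus outside a
domain set, genomic-feature annotation of differential sites (promoter /
exon / intron / downstream / distal intergenic, with the usual precedence),
isochore-class composition, and differential-expression integration.

Membership conventions: a site belongs to the feature containing its
midpoint; a gene belongs to a domain when its TSS lies inside (gene-body
overlap is available behind a flag). Both choices make every element count
exactly once, so reported fractions partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DomainSet, GenomeLayout, GenomicInterval, positions_in_intervals
from .io import Gene, GeneModelTable, IsochoreMap, ISOCHORE_CLASSES
from .sites import AnalysisParameters

__all__ = [
    "SizeDistribution",
    "size_distribution",
    "genome_fraction",
    "gene_density",
    "FEATURE_CATEGORIES",
    "annotate_site_features",
    "isochore_fractions",
    "DEDomainSummary",
    "de_genes_in_domains",
]

FEATURE_CATEGORIES = ("promoter", "exon", "intron", "downstream", "distal_intergenic")


# ---------------------------------------------------------------------------
# helpers


def _site_midpoints(sites) -> dict[str, np.ndarray]:
    """Per-chromosome midpoint arrays from a diff-site DataFrame or a
    sequence of GenomicInterval/PeakRecord objects."""
    if isinstance(sites, pd.DataFrame):
        out = {}
        for chrom, grp in sites.groupby("chrom", sort=False):
            mids = (grp["start"].to_numpy(np.int64) + grp["end"].to_numpy(np.int64)) // 2
            out[str(chrom)] = mids
        return out
    out: dict[str, list[int]] = {}
    for s in sites:
        iv = getattr(s, "interval", s)
        out.setdefault(iv.chrom, []).append(iv.midpoint)
    return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


# ---------------------------------------------------------------------------
# domain geometry


@dataclass(frozen=True)
class SizeDistribution:
    sizes: np.ndarray  # bp, one per domain

    def fraction_in_range(self, lo: float, hi: float) -> float:
        """Fraction of domains with lo <= size <= hi (bounds inclusive);
        NaN for an empty domain set."""
        if len(self.sizes) == 0:
            return float("nan")
        return float(((self.sizes >= lo) & (self.sizes <= hi)).mean())


def size_distribution(domains: DomainSet) -> SizeDistribution:
    return SizeDistribution(domains.sizes())


def genome_fraction(
    domains: DomainSet, layout: GenomeLayout, excluded_chromosomes=()
) -> float:
    """Fraction of the (non-excluded) genome covered by the domain set."""
    excluded = set(excluded_chromosomes)
    covered = sum(
        d.interval.length for d in domains if d.interval.chrom not in excluded
    )
    return covered / layout.total_length(excluded)


def gene_density(
    domains: DomainSet,
    genes: GeneModelTable,
    layout: GenomeLayout,
    excluded_chromosomes=(),
) -> tuple[float, float]:
    """Genes per Mb inside versus outside the domain set.

    A gene is inside when its TSS lies within a domain. Densities are gene
    counts over the summed inside/outside lengths, in genes per Mb.
    """
    excluded = set(excluded_chromosomes)
    intervals = [
        d.interval for d in domains if d.interval.chrom not in excluded
    ]
    n_in = n_out = 0
    for chrom, tss in genes.tss_positions().items():
        if chrom in excluded or chrom not in layout:
            continue
        inside = positions_in_intervals(tss, intervals, chrom)
        n_in += int(inside.sum())
        n_out += int((~inside).sum())
    bp_in = sum(iv.length for iv in intervals)
    bp_out = layout.total_length(excluded) - bp_in
    dens_in = n_in / bp_in * 1e6 if bp_in > 0 else 0.0
    dens_out = n_out / bp_out * 1e6 if bp_out > 0 else 0.0
    return dens_in, dens_out


# ---------------------------------------------------------------------------
# genomic feature annotation


def _categorize_against_gene(mid: int, gene: Gene, params: AnalysisParameters):
    """(category index into FEATURE_CATEGORIES or None, |mid - TSS|)."""
    tss = gene.tss
    dist_tss = abs(mid - tss)
    strand_pos = mid - tss if gene.strand == "+" else tss - mid
    if -params.promoter_upstream <= strand_pos < params.promoter_downstream:
        return 0, dist_tss
    if gene.interval.contains(mid):
        for ex in gene.exons:
            if ex.contains(mid):
                return 1, dist_tss
        return 2, dist_tss
    d3 = mid - gene.tes if gene.strand == "+" else gene.tes - mid
    if 1 <= d3 <= params.downstream_window:
        return 3, dist_tss
    return None, dist_tss


def annotate_site_features(
    sites,
    genes: GeneModelTable,
    params: AnalysisParameters = AnalysisParameters(),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assign each site (by midpoint) to one genomic feature category.

    Precedence: promoter > exon > intron > downstream > distal_intergenic.
    The promoter is the strand-oriented window [TSS - upstream,
    TSS + downstream); "downstream" means within 3 kb past the gene 3' end.
    When several genes would assign different categories of equal
    precedence, the gene with the nearest TSS wins.

    Returns a DataFrame (chrom, midpoint, category, gene_id) and the
    category fractions over all sites (they sum to 1).
    """
    by_chrom = genes.by_chrom()
    pad = max(
        params.promoter_upstream, params.promoter_downstream, params.downstream_window
    )
    rows = []
    for chrom, mids in _site_midpoints(sites).items():
        chrom_genes = by_chrom.get(chrom, [])
        gstarts = np.array([g.interval.start for g in chrom_genes], dtype=np.int64)
        gends = np.array([g.interval.end for g in chrom_genes], dtype=np.int64)
        for mid in mids:
            best = (len(FEATURE_CATEGORIES) - 1, np.inf, None)  # (cat, dist, gene)
            if chrom_genes:
                near = np.flatnonzero((gstarts - pad <= mid) & (mid < gends + pad))
                for gi in near:
                    cat, dist = _categorize_against_gene(int(mid), chrom_genes[gi], params)
                    if cat is not None and (cat, dist) < best[:2]:
                        best = (cat, dist, chrom_genes[gi].gene_id)
            rows.append(
                {
                    "chrom": chrom,
                    "midpoint": int(mid),
                    "category": FEATURE_CATEGORIES[best[0]],
                    "gene_id": best[2],
                }
            )
    ann = pd.DataFrame(rows, columns=["chrom", "midpoint", "category", "gene_id"])
    if len(ann):
        counts = ann["category"].value_counts()
        fractions = {c: float(counts.get(c, 0)) / len(ann) for c in FEATURE_CATEGORIES}
    else:
        fractions = {c: float("nan") for c in FEATURE_CATEGORIES}
    return ann, fractions


# ---------------------------------------------------------------------------
# isochores


def isochore_fractions(
    sites, isochores: IsochoreMap
) -> tuple[dict[str, float], int]:
    """Per-class fraction of sites whose midpoint falls in each isochore
    class. Sites covered by no segment are counted as unassigned and
    excluded from the denominator. Returns (fractions, n_unassigned);
    fractions are NaN when no site is assigned."""
    by_chrom = isochores.by_chrom()
    counts = {c: 0 for c in ISOCHORE_CLASSES}
    unassigned = 0
    for chrom, mids in _site_midpoints(sites).items():
        segs = by_chrom.get(chrom, [])
        if not segs:
            unassigned += len(mids)
            continue
        starts = np.array([iv.start for iv, _ in segs])
        ends = np.array([iv.end for iv, _ in segs])
        labels = [label for _, label in segs]
        idx = np.searchsorted(starts, mids, side="right") - 1
        for mid, i in zip(mids, idx):
            if i >= 0 and mid < ends[i]:
                counts[labels[i]] += 1
            else:
                unassigned += 1
    n_assigned = sum(counts.values())
    if n_assigned == 0:
        return {c: float("nan") for c in ISOCHORE_CLASSES}, unassigned
    return {c: counts[c] / n_assigned for c in ISOCHORE_CLASSES}, unassigned


# ---------------------------------------------------------------------------
# differential expression integration


@dataclass(frozen=True)
class DEDomainSummary:
    n_down: int
    n_up: int
    n_down_in_domains: int
    pct_down_in_domains: float  # NaN when n_down == 0
    n_missing: int  # expression gene ids absent from the gene model


def de_genes_in_domains(
    expr: pd.DataFrame,
    genes: GeneModelTable,
    domains: DomainSet,
    params: AnalysisParameters = AnalysisParameters(),
    use_gene_body: bool = False,
) -> DEDomainSummary:
    """Count differentially expressed genes and locate the down set
    relative to a domain set.

    Down: log2fc <= -log2(de_fold_threshold) and p < de_p_threshold; up is
    symmetric. A gene is in a domain when its TSS lies inside
    (``use_gene_body=True`` switches to >= 1 bp gene-body overlap).
    Expression rows whose gene id is missing from the gene model are
    counted and reported with a warning.
    """
    thr = np.log2(params.de_fold_threshold)
    sig = expr["p_value"] < params.de_p_threshold
    down = expr.loc[sig & (expr["log2fc"] <= -thr)]
    up = expr.loc[sig & (expr["log2fc"] >= thr)]
    gene_index = genes.by_id()
    missing = [gid for gid in expr["gene_id"] if gid not in gene_index]
    if missing:
        warnings.warn(
            f"{len(missing)} expression gene id(s) absent from the gene model "
            f"(e.g. {missing[0]!r})",
            stacklevel=2,
        )
    intervals = list(domains.intervals)

    def _in_domain(gid: str) -> bool:
        gene = gene_index.get(gid)
        if gene is None:
            return False
        if use_gene_body:
            from .genome import interval_overlap_bp

            return any(interval_overlap_bp(gene.interval, iv) > 0 for iv in intervals)
        mask = positions_in_intervals(
            np.array([gene.tss], dtype=np.int64), intervals, gene.interval.chrom
        )
        return bool(mask[0])

    n_down_in = int(sum(_in_domain(g) for g in down["gene_id"]))
    pct = 100.0 * n_down_in / len(down) if len(down) else float("nan")
    return DEDomainSummary(
        n_down=int(len(down)),
        n_up=int(len(up)),
        n_down_in_domains=n_down_in,
        pct_down_in_domains=pct,
        n_missing=len(missing),
    )
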