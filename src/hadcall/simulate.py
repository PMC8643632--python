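"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates the shape of a differential ATAC-seq experiment in
which a histone-chaperone knockout collapses the accessibility of
megabase-scale heterochromatic domains:

* a toy multi-chromosome genome;
* LAD-like megabase domains placed without overlap, a fraction of which
  contain one planted low-accessibility domain occupying 50-100% of the
  LAD span (so domain-in-LAD overlap statistics are nontrivial);
* a differential peak table whose log2 fold changes shift negative inside
  planted domains, with p-values computed from the background noise model
  so the joint (log2FC, p) structure resembles a volcano plot, and peak
  spacing sparser inside the gene-poor planted domains;
* ChIP-like peak sets whose per-Mb density rises inside planted domains in
  the knockout condition only;
* a gene model depleted inside planted domains, with differential
  expression calls placed mostly outside them;
* an isochore map biased so planted domains fall in the GC-poor classes.

Every output is a pure function of (params, seed): the global seed is
combined with a fixed per-stream offset (LADs=1, ATAC peaks=2, ChIP WT=3,
ChIP KO=4, genes=5, expression=6, isochores=7) via numpy's SeedSequence, so
streams are independent and individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    Domain,
    DomainSet,
    GenomeLayout,
    GenomicInterval,
    HadcallError,
    merge_intervals,
    positions_in_intervals,
)
from .io import Gene, GeneModelTable, IsochoreMap

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "SimulatedData",
    "generate_truth",
    "simulate_differential_peaks",
    "simulate_chip_peaks",
    "simulate_genes_and_expression",
    "simulate_isochores",
    "simulate_all",
]

# fixed per-stream seed offsets (documented derivation: SeedSequence(seed, offset))
_STREAM_LADS = 1
_STREAM_PEAKS = 2
_STREAM_CHIP_WT = 3
_STREAM_CHIP_KO = 4
_STREAM_GENES = 5
_STREAM_EXPR = 6
_STREAM_ISOCHORES = 7

# selection rule the down-fraction calibration targets (matches the default
# AnalysisParameters differential-site selection)
_DA_LFC_THRESHOLD = 1.0
_DA_P_THRESHOLD = 0.01

# mouse-like isochore class proportions (GC-poor L1/L2 dominate)
DEFAULT_ISOCHORE_PROPORTIONS = {
    "L1": 0.20,
    "L2": 0.38,
    "H1": 0.27,
    "H2": 0.11,
    "H3": 0.04,
}
# classes offered to tiles overlapping a planted (AT-rich, LAD-like) domain
PLANTED_ISOCHORE_PROPORTIONS = {"L1": 0.55, "L2": 0.45}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; the defaults define the standard study conditions.

    3 chromosomes x 100 Mb with 10 LADs each (2-5 Mb); two thirds of LADs
    carry one planted low-accessibility domain, giving 20 planted domains.
    Peak midpoints follow a renewal process with exponential spacing
    (10 kb background, 20 kb inside domains -> roughly 28,000 peaks).
    log2FC is N(0, 0.3) background and N(-1.5, 0.5) inside planted domains.
    88% of selected differential sites lose accessibility (calibrated, see
    ``frac_sites_down_target``). ChIP peaks are Poisson at 30/Mb with a
    +10/Mb knockout-only gain inside planted domains. Genes are 8/Mb
    outside, 1/Mb inside planted domains; 709 down- and 283 up-regulated
    genes are sampled with ~5.5% of the down set inside planted domains.
    """

    n_chroms: int = 3
    chrom_length: int = 100_000_000
    n_lads_per_chrom: int = 10
    lad_size_range: tuple[int, int] = (2_000_000, 5_000_000)
    lad_min_separation: int = 2_000_000
    frac_lads_with_planted_domain: float = 2 / 3
    domain_lfc_mean: float = -1.5
    domain_lfc_sd: float = 0.5
    background_lfc_mean: float = 0.0
    background_lfc_sd: float = 0.3
    peak_spacing_background: int = 10_000
    peak_spacing_in_domains: int = 20_000
    frac_sites_down_target: float = 0.88
    chip_density_background: float = 30.0
    chip_density_gain_in_domains: float = 10.0
    gene_density_background: float = 8.0
    gene_density_in_domains: float = 1.0
    n_de_down: int = 709
    n_de_up: int = 283
    de_frac_in_domains: float = 0.055
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_lads_with_planted_domain", "frac_sites_down_target",
                     "de_frac_in_domains"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lad_size_range[0] > self.lad_size_range[1]:
            raise ValueError("lad_size_range must be (lo, hi) with lo <= hi")
        for name in ("peak_spacing_background", "peak_spacing_in_domains",
                     "chip_density_background", "gene_density_background"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("chip_density_gain_in_domains", "gene_density_in_domains",
                     "lad_min_separation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_chroms < 1 or self.chrom_length <= 0 or self.n_lads_per_chrom < 0:
            raise ValueError("genome dimensions must be positive")
        if self.domain_lfc_sd <= 0 or self.background_lfc_sd <= 0:
            raise ValueError("log2FC standard deviations must be positive")

    def layout(self) -> GenomeLayout:
        return GenomeLayout.from_pairs(
            (f"chr{i + 1}", self.chrom_length) for i in range(self.n_chroms)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lad_size_range"] = list(self.lad_size_range)
        return d


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth: LADs and the planted domains nested inside them."""

    layout: GenomeLayout
    lads: DomainSet
    planted: DomainSet
    params: SimulationParams

    def planted_by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {c: [] for c in self.layout.names}
        for d in self.planted:
            out[d.interval.chrom].append(d.interval)
        return out


def generate_truth(params: SimulationParams) -> SyntheticTruth:
    """Place LADs and plant low-accessibility domains inside a subset.

    LADs on each chromosome get sizes uniform in ``lad_size_range`` and are
    placed uniformly at random subject to non-overlap with at least
    ``lad_min_separation`` bp between neighbours (distinct domains must
    stay distinct under the caller's 1 Mb gap-merge rule, and real LADs are
    separated by euchromatic stretches). Exactly
    round(frac * n_lads) LADs, sampled without replacement, receive one
    planted domain occupying a uniform 50-100% of the LAD span.
    """
    layout = params.layout()
    rng = _rng(params.seed, _STREAM_LADS)
    lads: list[Domain] = []
    lo, hi = params.lad_size_range
    sep = params.lad_min_separation
    for chrom, length in layout.chromosomes:
        n = params.n_lads_per_chrom
        if n == 0:
            continue
        sizes = rng.integers(lo, hi + 1, size=n)
        slack = length - int(sizes.sum()) - (n - 1) * sep
        if slack < 0:
            raise HadcallError(
                f"cannot place {n} LADs of {lo}-{hi} bp with {sep} bp separation "
                f"on a {length} bp chromosome; use fewer or smaller LADs"
            )
        u = np.sort(rng.uniform(0, slack, size=n)).astype(np.int64)
        offsets = np.concatenate([[0], np.cumsum(sizes[:-1])]) + sep * np.arange(n)
        starts = u + offsets
        for s, size in zip(starts, sizes):
            lads.append(Domain(GenomicInterval(chrom, int(s), int(s + size))))
    n_planted = int(round(params.frac_lads_with_planted_domain * len(lads)))
    chosen = np.sort(rng.choice(len(lads), size=n_planted, replace=False))
    planted: list[Domain] = []
    for i in chosen:
        lad = lads[i].interval
        size = int(round(rng.uniform(0.5, 1.0) * lad.length))
        size = max(1, min(size, lad.length))
        start = lad.start + int(rng.integers(0, lad.length - size + 1))
        planted.append(Domain(GenomicInterval(lad.chrom, start, start + size)))
    return SyntheticTruth(
        layout,
        DomainSet.from_domains(lads, "LAD").sorted(layout),
        DomainSet.from_domains(planted, "planted").sorted(layout),
        params,
    )


def _expected_up_plants(params: SimulationParams, n_in: int, n_out: int) -> int:
    """How many background peaks to shift up so the expected down-fraction
    among selected differential sites equals ``frac_sites_down_target``.

    Pass probabilities for the shifted and background populations are
    normal tail areas at the effective selection threshold
    c = max(lfc threshold, background quantile of the p threshold); the
    up-shifted population mirrors the domain distribution about the
    background mean, so its pass probability equals the domain one and the
    expected selected-down : selected-up ratio can be solved in closed form.
    """
    t = params.frac_sites_down_target
    bm, bs = params.background_lfc_mean, params.background_lfc_sd
    dm, ds = params.domain_lfc_mean, params.domain_lfc_sd
    c = max(_DA_LFC_THRESHOLD, bs * stats.norm.isf(_DA_P_THRESHOLD / 2))
    q = stats.norm.cdf((-c - (dm - bm)) / ds)  # shifted-site pass prob (either sign)
    b_each = stats.norm.sf(c / bs)  # background pass prob per side
    if t >= 1.0 or q <= 0:
        return 0
    if t <= 0.0:
        return n_out
    B = n_out * b_each
    m_pass = (n_in * q + B) * (1 - t) / t - B
    return int(np.clip(round(m_pass / q), 0, n_out))


def simulate_differential_peaks(
    truth: SyntheticTruth, params: SimulationParams | None = None
) -> pd.DataFrame:
    """Simulate the differential accessibility peak table.

    Peak midpoints follow a renewal process with exponential spacing whose
    mean depends on whether the current position is inside a planted
    domain; widths are uniform 200-500 bp. log2FC is drawn from the
    background normal outside planted domains and from the shifted normal
    inside; a calibrated number of background peaks is shifted in the
    opposite (gained-accessibility) direction so the expected fraction of
    selected differential sites that are losses equals
    ``frac_sites_down_target``. The p-value is the two-sided normal tail
    probability of the drawn log2FC under the background distribution.
    """
    params = params or truth.params
    rng = _rng(params.seed, _STREAM_PEAKS)
    planted = truth.planted_by_chrom()
    rows_chrom, rows_start, rows_end, rows_mid, rows_inside = [], [], [], [], []
    for chrom, length in truth.layout.chromosomes:
        ivs = planted.get(chrom, [])
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)

        def _inside(pos: float) -> bool:
            i = np.searchsorted(starts, pos, side="right") - 1
            return i >= 0 and pos < ends[i]

        pos = 0.0
        while True:
            mean = (
                params.peak_spacing_in_domains
                if _inside(pos)
                else params.peak_spacing_background
            )
            pos += rng.exponential(mean)
            if pos >= length - 250:
                break
            mid = int(pos)
            width = int(rng.integers(200, 501))
            start = max(0, mid - width // 2)
            end = min(length, start + width)
            rows_chrom.append(chrom)
            rows_start.append(start)
            rows_end.append(end)
            rows_mid.append(mid)
            rows_inside.append(_inside(mid))
    n = len(rows_start)
    inside = np.array(rows_inside, dtype=bool)
    bg = rng.normal(params.background_lfc_mean, params.background_lfc_sd, size=n)
    dom = rng.normal(params.domain_lfc_mean, params.domain_lfc_sd, size=n)
    lfc = np.where(inside, dom, bg)
    outside_idx = np.flatnonzero(~inside)
    m = _expected_up_plants(params, int(inside.sum()), len(outside_idx))
    if m > 0:
        up_idx = rng.choice(outside_idx, size=m, replace=False)
        up_mean = 2 * params.background_lfc_mean - params.domain_lfc_mean
        lfc[up_idx] = rng.normal(up_mean, params.domain_lfc_sd, size=m)
    z = (lfc - params.background_lfc_mean) / params.background_lfc_sd
    p = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    df = pd.DataFrame(
        {
            "chrom": rows_chrom,
            "start": np.array(rows_start, dtype=np.int64),
            "end": np.array(rows_end, dtype=np.int64),
            "log2fc": lfc,
            "p_value": p,
        }
    )
    return df.drop_duplicates(subset=["chrom", "start", "end"], ignore_index=True)


def simulate_chip_peaks(
    truth: SyntheticTruth,
    condition: str,
    params: SimulationParams | None = None,
):
    """Simulate a ChIP peak set (fixed 500 bp peaks) for one condition.

    Placement is homogeneous Poisson at ``chip_density_background``
    peaks/Mb genome-wide; the "KO" condition additionally receives
    ``chip_density_gain_in_domains`` peaks/Mb inside planted domains.
    """
    from .genome import PeakRecord

    params = params or truth.params
    if condition not in ("WT", "KO"):
        raise ValueError(f"condition must be 'WT' or 'KO', got {condition!r}")
    stream = _STREAM_CHIP_WT if condition == "WT" else _STREAM_CHIP_KO
    rng = _rng(params.seed, stream)
    width = 500
    peaks = []
    planted = truth.planted_by_chrom()
    for chrom, length in truth.layout.chromosomes:
        n_bg = rng.poisson(params.chip_density_background * length / 1e6)
        starts = rng.integers(0, max(1, length - width), size=n_bg)
        all_starts = [starts]
        if condition == "KO" and params.chip_density_gain_in_domains > 0:
            for iv in planted.get(chrom, []):
                n_extra = rng.poisson(
                    params.chip_density_gain_in_domains * iv.length / 1e6
                )
                hi = max(iv.start + 1, iv.end - width)
                all_starts.append(rng.integers(iv.start, hi, size=n_extra))
        for s in np.sort(np.concatenate(all_starts)):
            peaks.append(
                PeakRecord(GenomicInterval(chrom, int(s), min(int(s) + width, length)))
            )
    return peaks


def simulate_genes_and_expression(
    truth: SyntheticTruth, params: SimulationParams | None = None
) -> tuple[GeneModelTable, pd.DataFrame]:
    """Simulate a gene model and a differential-expression table.

    Gene starts are Poisson at ``gene_density_background`` per Mb outside
    planted domains and ``gene_density_in_domains`` inside; genes are
    5-50 kb with 2-8 exons and random strand. ``n_de_down`` + ``n_de_up``
    genes are sampled as differentially expressed (|log2FC| >= log2(1.5),
    p < 0.05), with an expected ``de_frac_in_domains`` of each DE set drawn
    from genes whose TSS lies inside a planted domain — the rest of the
    transcriptome-wide rows stay sub-threshold.
    """
    params = params or truth.params
    rng = _rng(params.seed, _STREAM_GENES)
    planted = truth.planted_by_chrom()
    genes: list[Gene] = []
    counter = 0
    for chrom, length in truth.layout.chromosomes:
        ivs = planted.get(chrom, [])
        regions: list[tuple[int, int, float]] = []
        pos = 0
        for iv in ivs:
            if iv.start > pos:
                regions.append((pos, iv.start, params.gene_density_background))
            regions.append((iv.start, iv.end, params.gene_density_in_domains))
            pos = iv.end
        if pos < length:
            regions.append((pos, length, params.gene_density_background))
        starts: list[int] = []
        for rstart, rend, dens in regions:
            n = rng.poisson(dens * (rend - rstart) / 1e6)
            if n:
                starts.extend(int(s) for s in rng.integers(rstart, rend, size=n))
        for s in sorted(starts):
            glen = int(rng.integers(5_000, 50_001))
            end = min(length, s + glen)
            if end - s < 1_000:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            k = int(rng.integers(2, 9))
            cuts = np.sort(rng.integers(0, end - s + 1, size=2 * k))
            exons = []
            prev_end = -1
            for a, b in zip(cuts[0::2], cuts[1::2]):
                if b > a and s + int(a) >= prev_end:
                    exons.append(GenomicInterval(chrom, s + int(a), s + int(b)))
                    prev_end = s + int(b)
            if not exons:
                exons = [GenomicInterval(chrom, s, end)]
            counter += 1
            genes.append(
                Gene(f"gene_{counter:05d}", GenomicInterval(chrom, s, end), strand,
                     tuple(exons))
            )
    table = GeneModelTable(tuple(genes))

    n_de = params.n_de_down + params.n_de_up
    if n_de > len(genes):
        raise HadcallError(
            f"requested {n_de} DE genes but only {len(genes)} genes were simulated"
        )
    planted_ivs = [iv for d in truth.planted for iv in [d.interval]]
    inside_flags = np.zeros(len(genes), dtype=bool)
    for chrom in truth.layout.names:
        idx = [i for i, g in enumerate(genes) if g.interval.chrom == chrom]
        if not idx:
            continue
        tss = np.array([genes[i].tss for i in idx], dtype=np.int64)
        mask = positions_in_intervals(tss, planted_ivs, chrom)
        inside_flags[np.array(idx)] = mask
    rng_expr = _rng(params.seed, _STREAM_EXPR)
    available_in = list(np.flatnonzero(inside_flags))
    available_out = list(np.flatnonzero(~inside_flags))

    def _draw_de(n_total: int) -> list[int]:
        n_in = min(int(round(params.de_frac_in_domains * n_total)), len(available_in))
        n_out = n_total - n_in
        if n_out > len(available_out):
            raise HadcallError("not enough genes outside planted domains for DE set")
        chosen_in = rng_expr.choice(len(available_in), size=n_in, replace=False)
        chosen_out = rng_expr.choice(len(available_out), size=n_out, replace=False)
        picked = [available_in[i] for i in sorted(chosen_in, reverse=True)]
        for i in sorted(chosen_in, reverse=True):
            available_in.pop(i)
        picked += [available_out[i] for i in sorted(chosen_out, reverse=True)]
        for i in sorted(chosen_out, reverse=True):
            available_out.pop(i)
        return picked

    down_idx = _draw_de(params.n_de_down)
    up_idx = _draw_de(params.n_de_up)
    thr = np.log2(1.5)
    lfc = np.clip(rng_expr.normal(0.0, 0.15, size=len(genes)), -thr + 0.01, thr - 0.01)
    pval = rng_expr.uniform(0.051, 1.0, size=len(genes))
    for idx_list, sign in ((down_idx, -1.0), (up_idx, 1.0)):
        for i in idx_list:
            lfc[i] = sign * (thr + rng_expr.exponential(0.5))
            pval[i] = rng_expr.uniform(1e-6, 0.049)
    expr = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "log2fc": lfc,
            "p_value": pval,
        }
    )
    return table, expr


def simulate_isochores(
    layout: GenomeLayout,
    seed: int,
    truth: SyntheticTruth | None = None,
    proportions: dict[str, float] | None = None,
) -> IsochoreMap:
    """Tile the genome with 0.3-3 Mb isochore segments.

    Labels are drawn from ``proportions`` (mouse-like defaults); when
    ``truth`` is supplied, tiles overlapping a planted domain draw from the
    GC-poor classes (L1/L2) only, emulating the AT-rich character of
    lamina-associated heterochromatin. The tiling partitions each
    chromosome exactly.
    """
    proportions = proportions or DEFAULT_ISOCHORE_PROPORTIONS
    labels = list(proportions)
    probs = np.array([proportions[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    planted_labels = list(PLANTED_ISOCHORE_PROPORTIONS)
    planted_probs = np.array(
        [PLANTED_ISOCHORE_PROPORTIONS[l] for l in planted_labels], dtype=float
    )
    planted_probs = planted_probs / planted_probs.sum()
    rng = _rng(seed, _STREAM_ISOCHORES)
    planted = truth.planted_by_chrom() if truth is not None else {}
    segments = []
    for chrom, length in layout.chromosomes:
        ivs = planted.get(chrom, [])
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        pos = 0
        while pos < length:
            seg_len = int(rng.uniform(300_000, 3_000_000))
            end = min(length, pos + seg_len)
            overlaps = bool(
                len(starts) and np.any((starts < end) & (ends > pos))
            )
            if overlaps:
                label = planted_labels[rng.choice(len(planted_labels), p=planted_probs)]
            else:
                label = labels[rng.choice(len(labels), p=probs)]
            segments.append((GenomicInterval(chrom, pos, end), label))
            pos = end
    return IsochoreMap(tuple(segments))


@dataclass(frozen=True)
class SimulatedData:
    """Everything one seeded run of the generator produces."""

    truth: SyntheticTruth
    diff_table: pd.DataFrame
    chip_wt: list
    chip_ko: list
    genes: GeneModelTable
    expression: pd.DataFrame
    isochores: IsochoreMap

    @property
    def layout(self) -> GenomeLayout:
        return self.truth.layout


def simulate_all(params: SimulationParams) -> SimulatedData:
    """Run every generator stage with the per-stream sub-seeds of
    ``params.seed``."""
    truth = generate_truth(params)
    diff = simulate_differential_peaks(truth)
    chip_wt = simulate_chip_peaks(truth, "WT")
    chip_ko = simulate_chip_peaks(truth, "KO")
    genes, expr = simulate_genes_and_expression(truth)
    isochores = simulate_isochores(truth.layout, params.seed, truth=truth)
    return SimulatedData(truth, diff, chip_wt, chip_ko, genes, expr, isochores)
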