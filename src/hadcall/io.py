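"""Readers and writers for the plain-text genomics formats the pipeline uses.

BED3/BED6/narrowPeak, two-column chrom-sizes, tab-separated differential and
expression tables, isochore BED (class in the name column), GTF gene models
(via gffutils) and bedGraph output. All files are tab-separated text;
lines starting with ``#`` (and ``track``/``browser`` lines) are ignored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import (
    Domain,
    DomainSet,
    GenomeLayout,
    GenomicInterval,
    HadcallError,
    PeakRecord,
)

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_intervals",
    "read_domains",
    "write_domains",
    "write_bedgraph",
    "read_diff_table",
    "write_diff_table",
    "read_expression_table",
    "write_expression_table",
    "Gene",
    "GeneModelTable",
    "read_gtf_genes",
    "write_gtf_genes",
    "IsochoreMap",
    "ISOCHORE_CLASSES",
    "read_isochores",
    "write_isochores",
]

ISOCHORE_CLASSES = ("L1", "L2", "H1", "H2", "H3")


class FormatError(HadcallError):
    """Raised when an input file does not parse under the named dialect."""


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(("track", "browser")):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# chrom sizes


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column ``name<TAB>length`` file into a GenomeLayout."""
    pairs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        try:
            pairs.append((fields[0], int(fields[1])))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return GenomeLayout.from_pairs(pairs)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak peaks

_BED_MIN_FIELDS = {"BED3": 3, "BED6": 6, "narrowPeak": 10}


def read_intervals(
    path, format: str = "BED3", layout: GenomeLayout | None = None
) -> list[PeakRecord]:
    """Read a BED3/BED6/narrowPeak file into PeakRecords, in file order.

    Coordinates are taken as-is (BED is 0-based half-open). When ``layout``
    is given, records exceeding the chromosome bounds are rejected.
    """
    if format not in _BED_MIN_FIELDS:
        raise ValueError(f"unknown format {format!r}; use BED3, BED6 or narrowPeak")
    want = _BED_MIN_FIELDS[format]
    records: list[PeakRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < want:
            raise FormatError(
                f"{path}:{lineno}: {format} needs >= {want} fields, got {len(fields)}"
            )
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
        if end <= start:
            raise FormatError(f"{path}:{lineno}: end <= start ({start}, {end})")
        try:
            iv = GenomicInterval(chrom, start, end)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if layout is not None:
            try:
                layout.validate_interval(iv)
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
        name = score = strand = summit = None
        if format in ("BED6", "narrowPeak"):
            name = fields[3] or None
            try:
                score = float(fields[4]) if fields[4] not in (".", "") else None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
            strand = fields[5] if fields[5] in ("+", "-") else None
        if format == "narrowPeak":
            try:
                summit = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad summit {fields[9]!r}") from exc
            if summit == -1:
                summit = None
            elif not (0 <= summit < iv.length):
                raise FormatError(
                    f"{path}:{lineno}: summit offset {summit} outside peak"
                )
        records.append(
            PeakRecord(iv, score=score, summit_offset=summit, name=name, strand=strand)
        )
    return records


def read_domains(
    path,
    label: str = "",
    name_filter: str | None = None,
    layout: GenomeLayout | None = None,
) -> DomainSet:
    """Read a BED file of domains; optionally keep only rows whose name
    column equals ``name_filter`` (e.g. ``cLAD`` in a mixed LAD file)."""
    domains = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 fields")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if layout is not None:
            layout.validate_interval(iv)
        name = fields[3] if len(fields) > 3 else None
        if name_filter is not None and name != name_filter:
            continue
        score = 0.0
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad score") from exc
        domains.append(Domain(iv, mean_value=score, name=name))
    return DomainSet.from_domains(domains, label=label).sorted(layout)


def write_domains(domains: DomainSet, path) -> None:
    """Write a DomainSet as BED6; the score column carries mean_value."""
    with open(path, "w") as fh:
        fh.write(f"# hadcall domains label={domains.label or '.'}\n")
        for i, d in enumerate(domains, start=1):
            name = d.name or f"{domains.label or 'domain'}_{i}"
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t"
                f"{name}\t{d.mean_value:.6g}\t.\n"
            )


def write_bedgraph(path, rows: Iterable[tuple[str, int, int, float]]) -> None:
    """Write (chrom, start, end, value) rows as bedGraph."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph\n')
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# differential accessibility / expression tables

_DIFF_SYNONYMS = {
    "chrom": {"chrom", "chr", "seqnames", "chromosome"},
    "start": {"start"},
    "end": {"end", "stop"},
    "log2fc": {"log2fc", "log2foldchange", "fold", "lfc", "log2_fc"},
    "p_value": {"p_value", "pvalue", "p", "p.value"},
    "fdr": {"fdr", "padj", "qvalue", "q_value", "p.adj"},
}


def _map_columns(columns, synonyms, required):
    mapping = {}
    lowered = {c.lower().replace(" ", ""): c for c in columns}
    for canon, alts in synonyms.items():
        for alt in alts:
            if alt in lowered:
                mapping[canon] = lowered[alt]
                break
    missing = [c for c in required if c not in mapping]
    if missing:
        raise FormatError(
            f"missing required column(s) {missing}; found {list(columns)}"
        )
    return mapping


def read_diff_table(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read a differential accessibility table (chrom, start, end, log2FC, p).

    Column names are matched case-insensitively with common synonyms
    (log2FoldChange/Fold, pvalue, padj/FDR). Returns a DataFrame with
    canonical columns ``chrom, start, end, log2fc, p_value`` and optional
    ``fdr``, sorted as in the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    mapping = _map_columns(
        df.columns, _DIFF_SYNONYMS, required=("chrom", "start", "end", "log2fc", "p_value")
    )
    out = pd.DataFrame(
        {
            canon: df[col]
            for canon, col in mapping.items()
        }
    )
    out["chrom"] = out["chrom"].astype(str)
    for c in ("start", "end"):
        out[c] = out[c].astype(np.int64)
    bad = out.index[(out["end"] <= out["start"]) | (out["start"] < 0)]
    if len(bad):
        raise FormatError(f"{path}: end <= start at data row {bad[0]}")
    if ((out["p_value"] <= 0) | (out["p_value"] > 1)).any():
        raise FormatError(f"{path}: p_value outside (0, 1]")
    if layout is not None:
        for chrom, grp in out.groupby("chrom"):
            if chrom not in layout:
                raise FormatError(f"{path}: unknown chromosome {chrom!r}")
            if int(grp["end"].max()) > layout.length_of(chrom):
                raise FormatError(f"{path}: interval beyond end of {chrom}")
    return out


def write_diff_table(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "log2fc", "p_value"]
    if "fdr" in df.columns:
        cols.append("fdr")
    df.to_csv(path, sep="\t", index=False, columns=cols)


_EXPR_SYNONYMS = {
    "gene_id": {"gene_id", "gene", "id", "geneid"},
    "log2fc": {"log2fc", "log2foldchange", "fold", "lfc"},
    "p_value": {"p_value", "pvalue", "p", "p.value"},
}


def read_expression_table(path) -> pd.DataFrame:
    """Read a differential-expression table (gene_id, log2FC, p-value)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    mapping = _map_columns(df.columns, _EXPR_SYNONYMS, required=tuple(_EXPR_SYNONYMS))
    out = pd.DataFrame({canon: df[col] for canon, col in mapping.items()})
    out["gene_id"] = out["gene_id"].astype(str)
    if ((out["p_value"] <= 0) | (out["p_value"] > 1)).any():
        raise FormatError(f"{path}: p_value outside (0, 1]")
    return out


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=["gene_id", "log2fc", "p_value"])


# ---------------------------------------------------------------------------
# gene models (GTF)


@dataclass(frozen=True)
class Gene:
    """A gene with strand-aware TSS and its exon structure."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        """Transcription start site: start on +, end-1 on -."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """3' end (last transcribed base)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class GeneModelTable:
    """An ordered collection of genes with id lookup."""

    genes: tuple[Gene, ...]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_id(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.interval.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.interval.start, g.interval.end))
        return out

    def tss_positions(self) -> dict[str, np.ndarray]:
        out = {}
        for chrom, genes in self.by_chrom().items():
            out[chrom] = np.array([g.tss for g in genes], dtype=np.int64)
        return out


def read_gtf_genes(path) -> GeneModelTable:
    """Read gene and exon features from a GTF file (1-based inclusive on
    disk, converted to 0-based half-open here). Genes are grouped by the
    ``gene_id`` attribute."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end)
        exons = []
        for ex in db.children(feat, featuretype="exon", order_by="start"):
            exons.append(GenomicInterval(ex.seqid, ex.start - 1, ex.end))
        genes.append(Gene(gid, iv, feat.strand, tuple(exons)))
    return GeneModelTable(tuple(genes))


def write_gtf_genes(table: GeneModelTable, path, source: str = "hadcall") -> None:
    with open(path, "w") as fh:
        for g in table.genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.interval.chrom}\t{source}\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# isochores


@dataclass(frozen=True)
class IsochoreMap:
    """Non-overlapping genome segments labeled by GC-content class."""

    segments: tuple[tuple[GenomicInterval, str], ...]

    def __post_init__(self) -> None:
        for _, label in self.segments:
            if label not in ISOCHORE_CLASSES:
                raise ValueError(
                    f"isochore class {label!r} not in {ISOCHORE_CLASSES}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def by_chrom(self) -> dict[str, list[tuple[GenomicInterval, str]]]:
        out: dict[str, list[tuple[GenomicInterval, str]]] = {}
        for iv, label in self.segments:
            out.setdefault(iv.chrom, []).append((iv, label))
        for lst in out.values():
            lst.sort(key=lambda t: t[0].start)
        return out


def read_isochores(path, layout: GenomeLayout | None = None) -> IsochoreMap:
    """Read an isochore BED with the class (L1/L2/H1/H2/H3) in the name column."""
    segments = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: isochore BED needs 4 fields")
        iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        if layout is not None:
            layout.validate_interval(iv)
        if fields[3] not in ISOCHORE_CLASSES:
            raise FormatError(f"{path}:{lineno}: unknown isochore class {fields[3]!r}")
        segments.append((iv, fields[3]))
    return IsochoreMap(tuple(segments))


def write_isochores(isochores: IsochoreMap, path) -> None:
    with open(path, "w") as fh:
        for iv, label in isochores.segments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")
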