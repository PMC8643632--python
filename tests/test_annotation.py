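"""Domain characterization: sizes, densities, feature and isochore
annotation, and differential-expression integration."""

import math

import numpy as np
import pandas as pd
import pytest

from hadcall.annotation import (
    FEATURE_CATEGORIES,
    annotate_site_features,
    de_genes_in_domains,
    gene_density,
    genome_fraction,
    isochore_fractions,
    size_distribution,
)
from hadcall.genome import GenomeLayout, GenomicInterval
from hadcall.io import Gene, GeneModelTable, IsochoreMap
from hadcall.sites import AnalysisParameters

from conftest import make_diff_table, make_domains

MB = 1_000_000


class TestSizeAndFraction:
    def test_fraction_in_range_hand_example(self):
        doms = make_domains(
            [("chr1", 0, int(0.5 * MB)), ("chr1", MB, 3 * MB),
             ("chr1", 4 * MB, 7 * MB), ("chr2", 0, 7 * MB)]
        )
        dist = size_distribution(doms)
        assert dist.fraction_in_range(MB, 5 * MB) == pytest.approx(0.5)
        assert dist.fraction_in_range(0, np.inf) == 1.0

    def test_empty_set_gives_nan(self):
        assert math.isnan(size_distribution(make_domains([])).fraction_in_range(0, 1))

    def test_genome_fraction(self):
        layout = GenomeLayout.from_pairs([("chr1", 60 * MB), ("chr2", 40 * MB)])
        doms = make_domains([("chr1", 0, 6 * MB), ("chr2", 0, 4 * MB)])
        assert genome_fraction(doms, layout) == pytest.approx(0.10)
        assert genome_fraction(make_domains([]), layout) == 0.0
        tiling = make_domains([("chr1", 0, 60 * MB), ("chr2", 0, 40 * MB)])
        assert genome_fraction(tiling, layout) == 1.0

    def test_genome_fraction_respects_exclusions(self):
        layout = GenomeLayout.from_pairs([("chr1", 90 * MB), ("chrY", 10 * MB)])
        doms = make_domains([("chr1", 0, 9 * MB), ("chrY", 0, 10 * MB)])
        assert genome_fraction(doms, layout, {"chrY"}) == pytest.approx(0.10)


class TestGeneDensity:
    def _genes(self, positions):
        return GeneModelTable(
            tuple(
                Gene(f"g{i}", GenomicInterval("chr1", p, p + 10_000), "+")
                for i, p in enumerate(positions)
            )
        )

    def test_hand_arithmetic_example(self):
        # 4 genes, 2 with TSS inside 10 Mb of domains on a 100 Mb genome
        layout = GenomeLayout.from_pairs([("chr1", 100 * MB)])
        doms = make_domains([("chr1", 0, 10 * MB)])
        genes = self._genes([MB, 2 * MB, 20 * MB, 30 * MB])
        inside, outside = gene_density(doms, genes, layout)
        assert inside == pytest.approx(0.2)
        assert outside == pytest.approx(2 / 90)

    def test_no_genes(self):
        layout = GenomeLayout.from_pairs([("chr1", 100 * MB)])
        doms = make_domains([("chr1", 0, 10 * MB)])
        inside, outside = gene_density(doms, GeneModelTable(()), layout)
        assert (inside, outside) == (0.0, 0.0)

    def test_all_tss_inside_domains(self):
        layout = GenomeLayout.from_pairs([("chr1", 100 * MB)])
        doms = make_domains([("chr1", 0, 50 * MB)])
        genes = self._genes([MB, 2 * MB])
        inside, outside = gene_density(doms, genes, layout)
        assert outside == 0.0 and inside == pytest.approx(2 / 50)


class TestFeatureAnnotation:
    @pytest.fixture()
    def gene_model(self):
        # one + strand gene with exons at both ends, one - strand gene
        return GeneModelTable(
            (
                Gene(
                    "gplus",
                    GenomicInterval("chr1", 10_000, 20_000),
                    "+",
                    (
                        GenomicInterval("chr1", 10_000, 11_000),
                        GenomicInterval("chr1", 19_000, 20_000),
                    ),
                ),
                Gene(
                    "gminus",
                    GenomicInterval("chr1", 100_000, 120_000),
                    "-",
                    (GenomicInterval("chr1", 110_000, 112_000),),
                ),
            )
        )

    @pytest.mark.parametrize(
        "site,expected_cat,expected_gene",
        [
            ((8_000, 9_000), "promoter", "gplus"),  # upstream of + TSS
            ((12_200, 12_400), "promoter", "gplus"),  # TSS+3kb window wins over intron
            ((14_000, 15_000), "intron", "gplus"),
            ((19_200, 19_400), "exon", "gplus"),  # midpoint in last exon
            ((21_000, 22_000), "downstream", "gplus"),  # within 3 kb past 3' end
            ((500_000, 501_000), "distal_intergenic", None),
            ((121_000, 122_000), "promoter", "gminus"),  # upstream on - strand
            ((97_500, 98_400), "downstream", "gminus"),  # past - strand 3' end
            ((111_000, 111_200), "exon", "gminus"),
        ],
    )
    def test_category_examples(self, gene_model, site, expected_cat, expected_gene):
        sites = make_diff_table([("chr1", site[0], site[1], 0.0, 0.5)])
        ann, _ = annotate_site_features(sites, gene_model)
        assert ann.loc[0, "category"] == expected_cat
        assert ann.loc[0, "gene_id"] == expected_gene

    def test_promoter_beats_exon_of_other_gene(self):
        genes = GeneModelTable(
            (
                Gene("a", GenomicInterval("chr1", 0, 10_000), "+",
                     (GenomicInterval("chr1", 0, 10_000),)),
                Gene("b", GenomicInterval("chr1", 11_000, 30_000), "+"),
            )
        )
        # midpoint 9.5 kb: inside gene a's exon AND within 3 kb of gene b's TSS
        sites = make_diff_table([("chr1", 9_000, 10_000, 0.0, 0.5)])
        ann, _ = annotate_site_features(sites, genes)
        assert ann.loc[0, "category"] == "promoter"
        assert ann.loc[0, "gene_id"] == "b"

    def test_fractions_sum_to_one(self, gene_model):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 600_000, size=40)
        sites = make_diff_table(
            [("chr1", int(s), int(s) + 200, 0.0, 0.5) for s in starts]
        )
        ann, fractions = annotate_site_features(sites, gene_model)
        assert set(ann["category"]) <= set(FEATURE_CATEGORIES)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_agrees_with_bruteforce_membership(self, gene_model):
        """Every annotated category matches a direct per-gene check."""
        params = AnalysisParameters()
        rng = np.random.default_rng(9)
        mids = rng.integers(0, 130_000, size=200)
        sites = make_diff_table(
            [("chr1", int(m) - 50, int(m) + 50, 0.0, 0.5) for m in mids]
        )
        ann, _ = annotate_site_features(sites, gene_model, params)

        def oracle(mid):
            cats = []
            for g in gene_model:
                rel = mid - g.tss if g.strand == "+" else g.tss - mid
                if -3000 <= rel < 3000:
                    cats.append(("promoter", abs(mid - g.tss)))
                elif g.interval.start <= mid < g.interval.end:
                    inside_exon = any(e.start <= mid < e.end for e in g.exons)
                    cats.append(("exon" if inside_exon else "intron", abs(mid - g.tss)))
                else:
                    d3 = mid - g.tes if g.strand == "+" else g.tes - mid
                    if 1 <= d3 <= 3000:
                        cats.append(("downstream", abs(mid - g.tss)))
            if not cats:
                return "distal_intergenic"
            order = {c: i for i, c in enumerate(FEATURE_CATEGORIES)}
            return min(cats, key=lambda t: (order[t[0]], t[1]))[0]

        for _, row in ann.iterrows():
            assert row["category"] == oracle(row["midpoint"]), row["midpoint"]


class TestIsochores:
    def test_fraction_hand_example(self):
        iso = IsochoreMap(
            (
                (GenomicInterval("chr1", 0, 50 * MB), "L1"),
                (GenomicInterval("chr1", 50 * MB, 60 * MB), "H3"),
            )
        )
        sites = make_diff_table(
            [("chr1", 10 * MB, 10 * MB + 100, 0, 0.5),
             ("chr1", 55 * MB, 55 * MB + 100, 0, 0.5)]
        )
        fractions, unassigned = isochore_fractions(sites, iso)
        assert fractions["L1"] == pytest.approx(0.5)
        assert fractions["H3"] == pytest.approx(0.5)
        assert fractions["L2"] == 0.0
        assert unassigned == 0
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_unassigned_sites_counted(self):
        iso = IsochoreMap(((GenomicInterval("chr1", 0, MB), "L2"),))
        sites = make_diff_table(
            [("chr1", 2 * MB, 2 * MB + 100, 0, 0.5), ("chr2", 0, 100, 0, 0.5)]
        )
        fractions, unassigned = isochore_fractions(sites, iso)
        assert unassigned == 2
        assert all(math.isnan(v) for v in fractions.values())

    def test_no_sites_undefined(self):
        iso = IsochoreMap(((GenomicInterval("chr1", 0, MB), "L1"),))
        fractions, _ = isochore_fractions(make_diff_table([]), iso)
        assert all(math.isnan(v) for v in fractions.values())


class TestDEIntegration:
    def _model(self, n=10, spacing=100_000):
        return GeneModelTable(
            tuple(
                Gene(f"g{i}", GenomicInterval("chr1", i * spacing, i * spacing + 10_000), "+")
                for i in range(n)
            )
        )

    def test_toy_percentage(self):
        genes = self._model(10)
        # domains covering the TSS of genes 0-2 only
        doms = make_domains([("chr1", 0, 250_000)])
        expr = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "log2fc": [-1.0] * 10,
                "p_value": [0.001] * 10,
            }
        )
        res = de_genes_in_domains(expr, genes, doms)
        assert (res.n_down, res.n_up) == (10, 0)
        assert res.n_down_in_domains == 3
        assert res.pct_down_in_domains == pytest.approx(30.0)

    def test_thresholds_and_no_hits(self):
        genes = self._model(4)
        doms = make_domains([("chr1", 900_000, 950_000)])  # covers no TSS
        expr = pd.DataFrame(
            {
                "gene_id": ["g0", "g1", "g2", "g3"],
                "log2fc": [-0.60, -0.55, 0.60, -0.60],
                "p_value": [0.01, 0.01, 0.01, 0.06],
            }
        )
        res = de_genes_in_domains(expr, genes, doms)
        # -0.55 is below the log2(1.5)=0.585 magnitude cut; p=0.06 fails
        assert (res.n_down, res.n_up) == (1, 1)
        assert res.pct_down_in_domains == 0.0

    def test_zero_down_gives_nan_pct(self):
        genes = self._model(2)
        expr = pd.DataFrame(
            {"gene_id": ["g0"], "log2fc": [1.0], "p_value": [0.001]}
        )
        res = de_genes_in_domains(expr, genes, make_domains([("chr1", 0, 100)]))
        assert math.isnan(res.pct_down_in_domains)

    def test_missing_gene_ids_warned_and_counted(self):
        genes = self._model(2)
        expr = pd.DataFrame(
            {"gene_id": ["g0", "ghost"], "log2fc": [-1.0, -1.0], "p_value": [0.001, 0.001]}
        )
        with pytest.warns(UserWarning, match="ghost"):
            res = de_genes_in_domains(expr, genes, make_domains([("chr1", 0, 100)]))
        assert res.n_missing == 1

    def test_gene_body_flag_differs_from_tss(self):
        genes = GeneModelTable(
            (Gene("g0", GenomicInterval("chr1", 0, 100_000), "-"),)
        )
        doms = make_domains([("chr1", 0, 10_000)])  # covers body start, not - TSS
        expr = pd.DataFrame({"gene_id": ["g0"], "log2fc": [-2.0], "p_value": [0.001]})
        by_tss = de_genes_in_domains(expr, genes, doms)
        by_body = de_genes_in_domains(expr, genes, doms, use_gene_body=True)
        assert by_tss.n_down_in_domains == 0
        assert by_body.n_down_in_domains == 1
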