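"""The seeded synthetic-data generator: determinism, structural invariants
and the distributional structure downstream stages rely on."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hadcall.genome import HadcallError, interval_overlap_bp, positions_in_intervals
from hadcall.simulate import (
    DEFAULT_ISOCHORE_PROPORTIONS,
    SimulationParams,
    generate_truth,
    simulate_chip_peaks,
    simulate_differential_peaks,
    simulate_genes_and_expression,
    simulate_isochores,
)
from hadcall.sites import select_differential_sites

MB = 1_000_000


class TestTruth:
    def test_counts_and_nesting(self, small_params, small_truth):
        assert len(small_truth.lads) == small_params.n_chroms * small_params.n_lads_per_chrom
        # each planted domain lies wholly inside exactly one LAD
        for planted in small_truth.planted:
            containing = [
                lad
                for lad in small_truth.lads
                if interval_overlap_bp(planted.interval, lad.interval)
                == planted.interval.length
            ]
            assert len(containing) == 1
            frac = planted.interval.length / containing[0].interval.length
            assert 0.5 <= frac <= 1.0

    def test_lads_disjoint_with_separation(self, small_params, small_truth):
        by_chrom = small_truth.lads.by_chrom()
        for doms in by_chrom.values():
            for a, b in zip(doms, doms[1:]):
                assert b.interval.start - a.interval.end >= small_params.lad_min_separation

    def test_deterministic_per_seed(self, small_params):
        t1 = generate_truth(small_params)
        t2 = generate_truth(small_params)
        assert t1.lads.intervals == t2.lads.intervals
        assert t1.planted.intervals == t2.planted.intervals
        other = generate_truth(SimulationParams(**{**small_params.to_dict(),
                                                   "lad_size_range": tuple(small_params.lad_size_range),
                                                   "seed": 8}))
        assert other.lads.intervals != t1.lads.intervals

    def test_frac_one_plants_every_lad(self, small_params):
        params = SimulationParams(
            **{
                **small_params.to_dict(),
                "lad_size_range": tuple(small_params.lad_size_range),
                "frac_lads_with_planted_domain": 1.0,
            }
        )
        truth = generate_truth(params)
        assert len(truth.planted) == len(truth.lads)

    def test_impossible_packing_raises_helpful_error(self):
        with pytest.raises(HadcallError, match="fewer or smaller"):
            generate_truth(
                SimulationParams(
                    n_chroms=1,
                    chrom_length=5 * MB,
                    n_lads_per_chrom=10,
                    lad_size_range=(MB, 2 * MB),
                )
            )


@pytest.fixture(scope="module")
def default_peak_run():
    params = SimulationParams(seed=5)
    truth = generate_truth(params)
    return params, truth, simulate_differential_peaks(truth)


@pytest.fixture(scope="module")
def default_gene_run():
    params = SimulationParams(seed=13)
    truth = generate_truth(params)
    genes, expr = simulate_genes_and_expression(truth)
    return params, truth, genes, expr


class TestDifferentialPeaks:
    def test_deterministic(self, small_truth):
        a = simulate_differential_peaks(small_truth)
        b = simulate_differential_peaks(small_truth)
        pd.testing.assert_frame_equal(a, b)

    def test_volcano_structure(self, default_peak_run):
        """p is the two-sided background tail of the drawn log2FC."""
        params, _, table = default_peak_run
        z = np.abs(table["log2fc"] - params.background_lfc_mean) / params.background_lfc_sd
        expected = np.clip(2 * stats.norm.sf(z), 1e-300, 1.0)
        assert np.allclose(table["p_value"], expected)

    def test_planted_mean_recovers_configured_shift(self, default_peak_run):
        params, truth, table = default_peak_run
        mids = ((table["start"] + table["end"]) // 2).to_numpy()
        planted = truth.planted_by_chrom()
        inside = np.zeros(len(table), dtype=bool)
        for chrom, ivs in planted.items():
            sel = (table["chrom"] == chrom).to_numpy()
            inside[sel] = positions_in_intervals(mids[sel], ivs, chrom)
        vals = table.loc[inside, "log2fc"]
        assert len(vals) >= 1000
        se = params.domain_lfc_sd / np.sqrt(len(vals))
        # a calibrated minority of in-domain draws is irrelevant here: the
        # up-shifted sites are planted outside domains only
        assert abs(vals.mean() - params.domain_lfc_mean) <= 3 * se

    def test_selected_sites_concentrate_in_planted_domains(self, default_peak_run):
        params, truth, table = default_peak_run
        selected, summary = select_differential_sites(table)
        mids = ((selected["start"] + selected["end"]) // 2).to_numpy()
        inside = np.zeros(len(selected), dtype=bool)
        for chrom, ivs in truth.planted_by_chrom().items():
            sel = (selected["chrom"] == chrom).to_numpy()
            inside[sel] = positions_in_intervals(mids[sel], ivs, chrom)
        assert inside.mean() > 0.8

    def test_down_fraction_hits_configured_target(self, default_peak_run):
        params, _, table = default_peak_run
        _, summary = select_differential_sites(table)
        t = params.frac_sites_down_target
        half_ci = 1.96 * np.sqrt(t * (1 - t) / summary["n_total"])
        assert abs(summary["fraction_down"] - t) <= half_ci

    def test_null_degeneracy_keeps_distributions_identical(self):
        params = SimulationParams(
            n_chroms=1,
            chrom_length=30 * MB,
            n_lads_per_chrom=4,
            lad_size_range=(2 * MB, 3 * MB),
            domain_lfc_mean=0.0,
            domain_lfc_sd=0.3,
            frac_sites_down_target=0.5,
            peak_spacing_in_domains=10_000,
            seed=3,
        )
        truth = generate_truth(params)
        table = simulate_differential_peaks(truth)
        mids = ((table["start"] + table["end"]) // 2).to_numpy()
        ivs = truth.planted_by_chrom()["chr1"]
        inside = positions_in_intervals(mids, ivs, "chr1")
        # same mean/sd inside and out: two-sample t should not reject wildly
        t, p = stats.ttest_ind(table.loc[inside, "log2fc"], table.loc[~inside, "log2fc"])
        assert p > 1e-3

    def test_sparser_spacing_inside_domains(self, default_peak_run):
        params, truth, table = default_peak_run
        mids = ((table["start"] + table["end"]) // 2).to_numpy()
        planted_bp = truth.planted.total_bp()
        total_bp = truth.layout.total_length()
        inside = np.zeros(len(table), dtype=bool)
        for chrom, ivs in truth.planted_by_chrom().items():
            sel = (table["chrom"] == chrom).to_numpy()
            inside[sel] = positions_in_intervals(mids[sel], ivs, chrom)
        dens_in = inside.sum() / planted_bp
        dens_out = (~inside).sum() / (total_bp - planted_bp)
        assert dens_in < 0.75 * dens_out


class TestChipPeaks:
    def test_deterministic_and_condition_validated(self, small_truth):
        a = simulate_chip_peaks(small_truth, "WT")
        b = simulate_chip_peaks(small_truth, "WT")
        assert a == b
        with pytest.raises(ValueError):
            simulate_chip_peaks(small_truth, "mutant")

    def test_total_count_within_poisson_bound(self, small_truth, small_params):
        peaks = simulate_chip_peaks(small_truth, "WT")
        expected = small_params.chip_density_background * (
            small_params.n_chroms * small_params.chrom_length / 1e6
        )
        assert abs(len(peaks) - expected) <= 4 * np.sqrt(expected)

    def test_ko_gain_concentrates_in_planted(self):
        params = SimulationParams(seed=11)
        truth = generate_truth(params)
        wt = simulate_chip_peaks(truth, "WT")
        ko = simulate_chip_peaks(truth, "KO")
        planted_bp = truth.planted.total_bp()
        expected_gain = params.chip_density_gain_in_domains * planted_bp / 1e6
        assert abs((len(ko) - len(wt)) - expected_gain) <= 6 * np.sqrt(
            len(wt) + len(ko)
        )

    def test_zero_gain_degeneracy(self):
        params = SimulationParams(
            n_chroms=1, chrom_length=20 * MB, n_lads_per_chrom=2,
            lad_size_range=(MB, 2 * MB), chip_density_gain_in_domains=0.0, seed=2,
        )
        truth = generate_truth(params)
        n_wt = len(simulate_chip_peaks(truth, "WT"))
        n_ko = len(simulate_chip_peaks(truth, "KO"))
        expected = params.chip_density_background * 20
        assert abs(n_wt - n_ko) <= 8 * np.sqrt(expected)


class TestGenesAndExpression:
    def test_deterministic(self, small_truth):
        g1, e1 = simulate_genes_and_expression(small_truth)
        g2, e2 = simulate_genes_and_expression(small_truth)
        assert g1.genes == g2.genes
        pd.testing.assert_frame_equal(e1, e2)

    def test_zero_domain_density_means_no_genes_inside(self):
        params = SimulationParams(
            n_chroms=1, chrom_length=30 * MB, n_lads_per_chrom=3,
            lad_size_range=(2 * MB, 4 * MB), gene_density_in_domains=0.0,
            n_de_down=20, n_de_up=5, de_frac_in_domains=0.0, seed=4,
        )
        truth = generate_truth(params)
        genes, _ = simulate_genes_and_expression(truth)
        ivs = truth.planted_by_chrom()["chr1"]
        tss = np.array([g.tss for g in genes], dtype=np.int64)
        assert not positions_in_intervals(tss, ivs, "chr1").any()

    def test_de_counts_and_thresholds(self, default_gene_run):
        params, _, _, expr = default_gene_run
        thr = np.log2(1.5)
        down = expr[(expr["log2fc"] <= -thr) & (expr["p_value"] < 0.05)]
        up = expr[(expr["log2fc"] >= thr) & (expr["p_value"] < 0.05)]
        assert len(down) == params.n_de_down
        assert len(up) == params.n_de_up

    def test_down_genes_mostly_outside_planted(self, default_gene_run):
        params, truth, genes, expr = default_gene_run
        thr = np.log2(1.5)
        down_ids = set(
            expr.loc[(expr["log2fc"] <= -thr) & (expr["p_value"] < 0.05), "gene_id"]
        )
        gene_map = genes.by_id()
        n_in = 0
        planted = truth.planted_by_chrom()
        for gid in down_ids:
            g = gene_map[gid]
            mask = positions_in_intervals(
                np.array([g.tss]), planted[g.interval.chrom], g.interval.chrom
            )
            n_in += int(mask[0])
        frac = n_in / len(down_ids)
        half_ci = 1.96 * np.sqrt(
            params.de_frac_in_domains * (1 - params.de_frac_in_domains) / len(down_ids)
        )
        assert abs(frac - params.de_frac_in_domains) <= half_ci + 1 / len(down_ids)

    def test_requesting_more_de_genes_than_exist_errors(self, small_truth):
        params = SimulationParams(
            **{
                **small_truth.params.to_dict(),
                "lad_size_range": tuple(small_truth.params.lad_size_range),
                "n_de_down": 10**6,
            }
        )
        with pytest.raises(HadcallError, match="DE genes"):
            simulate_genes_and_expression(small_truth, params)

    def test_exon_structure_valid(self, default_gene_run):
        _, _, genes, _ = default_gene_run
        for g in list(genes)[:200]:
            prev_end = -1
            for ex in g.exons:
                assert g.interval.start <= ex.start < ex.end <= g.interval.end
                assert ex.start >= prev_end
                prev_end = ex.end


class TestIsochores:
    def test_partition_covers_every_bp_once(self, toy_layout):
        iso = simulate_isochores(toy_layout, seed=1)
        for chrom, length in toy_layout.chromosomes:
            segs = [iv for iv, _ in iso.segments if iv.chrom == chrom]
            assert segs[0].start == 0
            assert segs[-1].end == length
            for a, b in zip(segs, segs[1:]):
                assert a.end == b.start

    def test_deterministic(self, toy_layout):
        assert simulate_isochores(toy_layout, 9) == simulate_isochores(toy_layout, 9)
        assert simulate_isochores(toy_layout, 9) != simulate_isochores(toy_layout, 10)

    def test_label_proportions_chi_square(self):
        from hadcall.genome import GenomeLayout

        layout = GenomeLayout.from_pairs([("chr1", 500 * MB)])
        iso = simulate_isochores(layout, seed=6)
        labels = [label for _, label in iso.segments]
        n = len(labels)
        observed = [labels.count(c) for c in DEFAULT_ISOCHORE_PROPORTIONS]
        expected = [p * n for p in DEFAULT_ISOCHORE_PROPORTIONS.values()]
        _, p = stats.chisquare(observed, expected)
        assert p > 0.001

    def test_planted_bias_toward_gc_poor_classes(self, small_truth):
        iso = simulate_isochores(small_truth.layout, small_truth.params.seed,
                                 truth=small_truth)
        planted = small_truth.planted_by_chrom()
        for iv, label in iso.segments:
            ivs = planted.get(iv.chrom, [])
            overlaps = any(
                iv.start < p.end and p.start < iv.end for p in ivs
            )
            if overlaps:
                assert label in ("L1", "L2")
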