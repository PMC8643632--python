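"""End-to-end orchestration: simulate or load inputs, call domains,
annotate, and collect a machine-readable report.

The pipeline is configured by a single nested mapping (YAML/JSON on disk).
Exactly one of the ``simulation`` and ``inputs`` blocks must be present;
stages downstream of domain calling are individually skippable. Every
randomized stage derives its randomness from the single top-level ``seed``,
so a config fully determines the report.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
from typing import Any

import numpy as np

from . import annotation, caller, density, io, overlap, simulate, sites
from .genome import DomainSet, HadcallError

log = logging.getLogger("hadcall")

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "output_dir": None,
    "n_perm": 199,
    "simulation": None,  # dict of SimulationParams overrides, or None
    "inputs": None,  # dict of file paths, or None
    "analysis": {},  # AnalysisParameters overrides
    "stages": {
        "annotate": True,
        "overlap": True,
        "density": True,
        "expression": True,
    },
}

_INPUT_KEYS = {
    "diff_table",
    "chrom_sizes",
    "lads",
    "lad_class",
    "chip_wt",
    "chip_ko",
    "chip_format",
    "gtf",
    "expression",
    "isochores",
}


def _check_keys(block: dict, allowed, where: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise HadcallError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Fill defaults, reject unknown keys and return the resolved config.

    The resolved config echoes every analysis parameter and simulation
    parameter explicitly, so writing it next to the outputs makes the run
    replayable from one artifact.
    """
    _check_keys(config, DEFAULT_CONFIG, "top level")
    resolved = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in config.items():
        if key == "stages":
            _check_keys(value, DEFAULT_CONFIG["stages"], "stages")
            resolved["stages"].update(value)
        else:
            resolved[key] = copy.deepcopy(value)
    if resolved["simulation"] is not None and resolved["inputs"] is not None:
        raise HadcallError("config must name either 'simulation' or 'inputs', not both")
    if resolved["simulation"] is None and resolved["inputs"] is None:
        raise HadcallError("config must contain a 'simulation' block or an 'inputs' block")
    ap_fields = {
        f for f in sites.AnalysisParameters.__dataclass_fields__
    }
    _check_keys(resolved["analysis"], ap_fields, "analysis")
    resolved["analysis"] = {
        **{
            k: getattr(sites.AnalysisParameters(), k)
            for k in ap_fields
        },
        **resolved["analysis"],
    }
    resolved["analysis"]["excluded_chromosomes"] = sorted(
        resolved["analysis"]["excluded_chromosomes"]
    )
    if resolved["simulation"] is not None:
        sim_fields = set(simulate.SimulationParams.__dataclass_fields__)
        _check_keys(resolved["simulation"], sim_fields, "simulation")
        sim = dict(resolved["simulation"])
        sim.setdefault("seed", resolved["seed"])
        if "lad_size_range" in sim:
            sim["lad_size_range"] = tuple(sim["lad_size_range"])
        resolved["simulation"] = simulate.SimulationParams(**sim).to_dict()
    else:
        _check_keys(resolved["inputs"], _INPUT_KEYS, "inputs")
        for required in ("diff_table", "chrom_sizes"):
            if required not in resolved["inputs"]:
                raise HadcallError(
                    f"stage 'call' needs inputs.{required}; it is missing from the config"
                )
    if resolved["n_perm"] < 1:
        raise HadcallError("n_perm must be >= 1")
    return resolved


def _file_checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require_input(inputs: dict, key: str, stage: str):
    if key not in inputs or inputs[key] is None:
        raise HadcallError(
            f"stage {stage!r} needs inputs.{key}, which is missing from the config; "
            f"disable the stage or provide the file"
        )
    return inputs[key]


def _jsonable(value):
    if isinstance(value, (np.floating, float)):
        v = float(value)
        return None if np.isnan(v) else v
    if isinstance(value, (np.integer, int)):
        return int(value)
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run the full analysis described by ``config`` and return the report.

    Stage order: simulate (optional) -> differential-site selection ->
    log2FC track -> sliding-window smoothing -> domain calling -> chrY
    exclusion -> size/genome-fraction/gene-density/feature/isochore
    annotation -> LAD overlap -> ChIP density association -> expression
    integration. When ``output_dir`` is set, every stage's product and the
    resolved config are written there.
    """
    cfg = validate_config(config)
    params = sites.AnalysisParameters(
        **{
            **{k: v for k, v in cfg["analysis"].items()
               if k != "excluded_chromosomes"},
            "excluded_chromosomes": frozenset(cfg["analysis"]["excluded_chromosomes"]),
        }
    )
    stages = cfg["stages"]
    outdir = cfg["output_dir"]
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    lads = genes = expr = isochores = None
    chip_wt = chip_ko = None
    if cfg["simulation"] is not None:
        sim_params = simulate.SimulationParams(
            **{
                **cfg["simulation"],
                "lad_size_range": tuple(cfg["simulation"]["lad_size_range"]),
            }
        )
        log.info("simulating synthetic data with seed %d", sim_params.seed)
        data = simulate.simulate_all(sim_params)
        layout = data.layout
        diff = data.diff_table
        lads = data.truth.lads
        genes, expr, isochores = data.genes, data.expression, data.isochores
        chip_wt, chip_ko = data.chip_wt, data.chip_ko
        truth = data.truth
    else:
        inputs = cfg["inputs"]
        truth = None
        layout = io.read_chrom_sizes(_require_input(inputs, "chrom_sizes", "call"))
        diff_path = _require_input(inputs, "diff_table", "call")
        log.info("input %s md5=%s", diff_path, _file_checksum(diff_path))
        diff = io.read_diff_table(diff_path, layout=layout)
        if stages["overlap"]:
            lads = io.read_domains(
                _require_input(inputs, "lads", "overlap"),
                label="LAD",
                name_filter=inputs.get("lad_class"),
                layout=layout,
            )
        if stages["density"]:
            fmt = inputs.get("chip_format", "narrowPeak")
            chip_wt = io.read_intervals(
                _require_input(inputs, "chip_wt", "density"), fmt, layout=layout
            )
            chip_ko = io.read_intervals(
                _require_input(inputs, "chip_ko", "density"), fmt, layout=layout
            )
        if stages["annotate"] and inputs.get("gtf"):
            genes = io.read_gtf_genes(inputs["gtf"])
        if stages["annotate"] and inputs.get("isochores"):
            isochores = io.read_isochores(inputs["isochores"], layout=layout)
        if stages["expression"]:
            expr = io.read_expression_table(
                _require_input(inputs, "expression", "expression")
            )
            if genes is None:
                genes = io.read_gtf_genes(_require_input(inputs, "gtf", "expression"))

    report: dict[str, Any] = {"seed": cfg["seed"], "n_peaks": int(len(diff))}

    selected, summary = sites.select_differential_sites(diff, params)
    report["n_differential"] = summary["n_total"]
    report["n_down"] = summary["n_down"]
    report["fraction_down"] = summary["fraction_down"]

    track = sites.build_lfc_track(diff, layout)
    smoothed = caller.sliding_window_average(track, params.window_points)
    called = caller.call_domains(
        smoothed, cutoff=params.domain_cutoff, max_gap=params.max_gap
    )
    report["n_domains_before_exclusion"] = len(called)
    hads = caller.exclude_chromosomes(called, params.excluded_chromosomes)
    report["n_domains"] = len(hads)

    if stages["annotate"]:
        dist = annotation.size_distribution(hads)
        report["fraction_1_5Mb"] = dist.fraction_in_range(1e6, 5e6)
        report["genome_fraction"] = annotation.genome_fraction(
            hads, layout, params.excluded_chromosomes
        )
        if genes is not None:
            dens_in, dens_out = annotation.gene_density(
                hads, genes, layout, params.excluded_chromosomes
            )
            report["gene_density_inside"] = dens_in
            report["gene_density_outside"] = dens_out
            _, fractions = annotation.annotate_site_features(selected, genes, params)
            report["feature_fractions"] = fractions
        if isochores is not None:
            iso_frac, n_unassigned = annotation.isochore_fractions(selected, isochores)
            report["isochore_fractions"] = iso_frac
            report["isochore_unassigned"] = n_unassigned

    if stages["overlap"] and lads is not None:
        report["overlap_fraction_lads"] = overlap.overlap_fraction(hads, lads)
        report["jaccard_lads"] = overlap.basepair_jaccard(hads, lads)
        perm = overlap.overlap_permutation_test(
            hads, lads, layout, n_perm=cfg["n_perm"], seed=cfg["seed"]
        )
        report["overlap_perm_p"] = perm.perm_p

    delta_track = None
    if stages["density"] and chip_wt is not None:
        counts_wt = density.bin_peak_counts(
            chip_wt, layout, params.density_bin, params.excluded_chromosomes
        )
        counts_ko = density.bin_peak_counts(
            chip_ko, layout, params.density_bin, params.excluded_chromosomes
        )
        delta_track = density.density_difference(counts_wt, counts_ko)
        assoc = density.domain_density_association(
            delta_track, hads, n_perm=cfg["n_perm"], seed=cfg["seed"]
        )
        report["mean_delta_inside"] = assoc.mean_delta_inside
        report["mean_delta_outside"] = assoc.mean_delta_outside
        report["density_perm_p"] = assoc.perm_p

    if stages["expression"] and expr is not None and genes is not None:
        de = annotation.de_genes_in_domains(expr, genes, hads, params)
        report["n_de_down"] = de.n_down
        report["n_de_up"] = de.n_up
        report["n_down_de_in_domains"] = de.n_down_in_domains
        report["pct_down_de_in_domains"] = de.pct_down_in_domains

    if truth is not None:
        from .genome import intersection_bp

        planted_ivs = list(truth.planted.intervals)
        called_ivs = list(hads.intervals)
        planted_bp = truth.planted.total_bp()
        called_bp = hads.total_bp()
        inter = intersection_bp(called_ivs, planted_ivs)
        report["planted_bp"] = planted_bp
        report["called_bp"] = called_bp
        report["planted_recovery"] = inter / planted_bp if planted_bp else float("nan")
        report["called_outside_planted"] = (
            (called_bp - inter) / called_bp if called_bp else float("nan")
        )

    report = _jsonable(report)

    if outdir:
        import yaml

        with open(os.path.join(outdir, "config.resolved.yaml"), "w") as fh:
            yaml.safe_dump(_jsonable(cfg), fh, sort_keys=True)
        io.write_domains(hads, os.path.join(outdir, "hads.bed"))
        io.write_diff_table(selected, os.path.join(outdir, "differential_sites.tsv"))
        rows = []
        for chrom in layout.names:
            sc = smoothed.per_chrom.get(chrom)
            if sc is None:
                continue
            for a, v in zip(sc.anchors, sc.values):
                rows.append((chrom, int(a), int(a) + 1, float(v)))
        io.write_bedgraph(os.path.join(outdir, "smoothed_lfc.bedgraph"), rows)
        if delta_track is not None:
            io.write_bedgraph(
                os.path.join(outdir, "density_delta.bedgraph"),
                delta_track.iter_bedgraph_rows(),
            )
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            for key in sorted(report):
                fh.write(f"{key}: {report[key]}\n")
    return report
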