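"""Characterize domains and differential sites, and integrate expression.

Reports domain sizes and genome fraction, gene density inside versus
outside domains, genomic-feature and isochore composition of the selected
differential sites, and the share of down-regulated genes whose TSS lies
in a called domain.
"""

from hadcall import (
    AnalysisParameters,
    SimulationParams,
    annotate_site_features,
    build_lfc_track,
    call_domains,
    de_genes_in_domains,
    exclude_chromosomes,
    gene_density,
    genome_fraction,
    isochore_fractions,
    select_differential_sites,
    simulate_all,
    size_distribution,
    sliding_window_average,
)

data = simulate_all(SimulationParams(seed=1))
params = AnalysisParameters()
selected, summary = select_differential_sites(data.diff_table, params)
track = build_lfc_track(data.diff_table, data.layout)
domains = exclude_chromosomes(
    call_domains(sliding_window_average(track, params.window_points),
                 params.domain_cutoff, params.max_gap),
    params.excluded_chromosomes,
)

print(f"differential sites: {summary['n_total']} "
      f"({100 * summary['fraction_down']:.1f}% lose accessibility)")
dist = size_distribution(domains)
print(f"domains: {len(domains)}, "
      f"{100 * dist.fraction_in_range(1e6, 5e6):.0f}% between 1 and 5 Mb, "
      f"{100 * genome_fraction(domains, data.layout, params.excluded_chromosomes):.1f}% of the genome")
dens_in, dens_out = gene_density(domains, data.genes, data.layout)
print(f"gene density: {dens_in:.2f}/Mb inside vs {dens_out:.2f}/Mb outside domains")

_, fractions = annotate_site_features(selected, data.genes, params)
print("site features:",
      ", ".join(f"{k} {100 * v:.1f}%" for k, v in fractions.items()))
iso, _ = isochore_fractions(selected, data.isochores)
print("isochore classes:",
      ", ".join(f"{k} {100 * v:.1f}%" for k, v in iso.items()))

de = de_genes_in_domains(data.expression, data.genes, domains, params)
print(f"expression: {de.n_down} down / {de.n_up} up; "
      f"{de.n_down_in_domains} down genes ({de.pct_down_in_domains:.1f}%) in domains")
print()
print("Differential sites sit overwhelmingly in gene-poor, GC-poor (L1/L2)")
print("territory, and transcriptional changes are mostly outside the")
print("domains - accessibility loss here is not driven by transcription.")
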