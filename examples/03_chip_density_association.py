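"""Megabase-binned ChIP peak-density change inside called domains.

Counts simulated ChIP peaks per 1 Mb bin in each condition, forms the
knockout-minus-wildtype density change, and tests whether the change
concentrates inside the called domains with a rotation permutation null.
"""

from hadcall import (
    AnalysisParameters,
    SimulationParams,
    bin_peak_counts,
    build_lfc_track,
    call_domains,
    density_difference,
    domain_density_association,
    exclude_chromosomes,
    simulate_all,
    sliding_window_average,
)

data = simulate_all(SimulationParams(seed=1))
params = AnalysisParameters()
track = build_lfc_track(data.diff_table, data.layout)
domains = exclude_chromosomes(
    call_domains(sliding_window_average(track, params.window_points),
                 params.domain_cutoff, params.max_gap),
    params.excluded_chromosomes,
)

delta = density_difference(
    bin_peak_counts(data.chip_wt, data.layout, params.density_bin),
    bin_peak_counts(data.chip_ko, data.layout, params.density_bin),
)
assoc = domain_density_association(delta, domains, n_perm=199, seed=1)

print(f"WT peaks: {len(data.chip_wt)}   KO peaks: {len(data.chip_ko)}")
print(f"mean density change inside domains:  {assoc.mean_delta_inside:+.2f} peaks/Mb")
print(f"mean density change outside domains: {assoc.mean_delta_outside:+.2f} peaks/Mb")
print(f"difference (inside - outside):       {assoc.difference:+.2f} peaks/Mb")
print(f"permutation p-value:                 {assoc.perm_p:.4g}")
print()
print("The generator plants a +10 peaks/Mb knockout-only gain inside the")
print("low-accessibility domains; the binned difference recovers it and the")
print("rotation null shows the spatial coincidence is not chance.")
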