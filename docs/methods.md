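# Methods

## The domain-calling model

The caller assumes that a knockout-vs-wildtype differential accessibility
experiment has been summarized as one log2 fold change and one p-value per
consensus ATAC-seq peak, and that domain-scale loss of accessibility
manifests as a run of consecutive peaks with negative fold changes. It
does not model read counts, peak widths or signal intensity; the peak
table is the interface, and whatever produced it (DiffBind, DESeq2 csaw,
…) owns the statistics of the individual values.

Smoothing is a sliding mean over a fixed number of **data points** (25 by
default), not a fixed genomic window. This is deliberate: consensus-peak
spacing tracks the accessibility landscape, so a point-count window adapts
its genomic span to the local information density — narrow where peaks are
dense, wide in peak deserts — and never averages over an empty stretch.
The window is centered and truncated at chromosome ends, so each input
point yields one output point and no window spans two chromosomes. A
trailing window is available (`align="trailing"`) since the choice of
alignment is a genuine free parameter of such pipelines; centered is the
default because it avoids a systematic half-window shift of domain
boundaries.

Marking uses `smoothed value <= cutoff` with the cutoff at −0.58. The
threshold is the log2 of a 1.5-fold loss (log2(1/1.5) = −0.585, printed
rounded); ties are included so that the rounded printed value still
captures the 1.5-fold intent.

Merging is governed only by genomic distance: two marked points join the
same domain when the gap between their peak footprints is at most 1 Mb,
**regardless of unmarked points in between**. An isolated marked point is
a valid single-peak domain. Each point's footprint is its own source
peak's interval, so the smallest callable domain is one peak wide
(sub-kilobase); the wider union span of each smoothing window is retained
on the smoothed track (`win_starts`/`win_ends`) for inspection but plays
no role in calling. Domain statistics are the member count (`n_support`)
and the mean smoothed value of members; unmarked points never contribute.

Consequences worth knowing: lowering the cutoff can only shrink total
domain bases, and widening the gap can only reduce the number of domains
(both are tested properties); above-cutoff "islands" inside a domain are
absorbed, which matches the biology (domains are defined by their
envelope, not by every window passing threshold) but means domain mean
values summarize only the sub-threshold windows.

## Analysis parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| `da_lfc_threshold` / `da_p_threshold` | 1.0 / 0.01 | log2 / p | differential-site selection (|log2FC| inclusive, p strict) |
| `window_points` | 25 | data points | sliding-mean width |
| `domain_cutoff` | −0.58 | log2 | 1.5-fold loss threshold, ties marked |
| `max_gap` | 1,000,000 | bp | largest bridged footprint gap |
| `density_bin` | 1,000,000 | bp | ChIP peak-density bin width |
| `de_fold_threshold` / `de_p_threshold` | 1.5 / 0.05 | fold / p | differential-expression selection |
| `promoter_upstream` / `promoter_downstream` | 3000 / 3000 | bp | strand-oriented promoter window around the TSS |
| `excluded_chromosomes` | {chrY} | — | dropped from domain reporting and genome fractions |

Raw p-values are thresholded by default; `use_fdr=True` substitutes an
FDR column when the table carries one. Site-to-feature assignment uses the
site midpoint with precedence promoter > exon > intron > downstream
(≤3 kb past the 3′ end) > distal intergenic, ties across genes broken by
nearest TSS; a site whose midpoint sits within 3 kb downstream of a TSS is
a promoter hit even when that position is intronic, which is how the
standard annotation tools behave. Gene-to-domain membership uses the TSS
(gene-body overlap behind a flag): midpoint/TSS containment makes every
element count exactly once, so reported fractions partition.

## Permutation null

Domain–track and domain–domain association use a circular-rotation null:
all intervals on a chromosome are shifted by one uniform random offset
with wrap-around (intervals crossing the end split into two pieces whose
lengths sum correctly). This preserves the number, sizes and spacings of
the intervals and the full structure of the other variable, asking only
whether the *positions* coincide. p = (1 + #{null ≥ observed}) /
(1 + n_perm), one-sided, so p is never 0 and equals 1 under saturation.
With the default n_perm = 199 the smallest attainable p is 0.005.

## The synthetic benchmark

`SimulationParams` defaults define the standard conditions: 3 chromosomes
× 100 Mb; 10 LADs per chromosome, 2–5 Mb, placed uniformly with ≥2 Mb
separation (distinct domains must remain distinct under 1 Mb gap merging,
and real LADs are separated by euchromatic stretches); two thirds of LADs
(20 of 30) carry one planted domain covering 50–100% of the LAD. Peaks
follow a renewal process with exponential spacing, mean 10 kb background
and 20 kb inside planted domains (domains are gene- and peak-poor),
giving ~28,000 peaks and ≥50 per planted domain. log2FC is N(0, 0.3²)
background and N(−1.5, 0.5²) inside planted domains; the p-value is the
two-sided background tail of the drawn value, so the joint (log2FC, p)
distribution has volcano structure and selection on both columns behaves
like the real pipeline.

Two generator quantities are calibrated rather than emergent:

* **Down-fraction of differential sites** (default target 0.88). Inside
  planted domains essentially every selected site is a loss, so without
  intervention the selected down-fraction would be ≈0.99. The generator
  therefore plants a computed number of *gained* sites in the background,
  drawn from the domain distribution mirrored about the background mean.
  The count is solved in closed form from normal tail areas at the
  selection threshold so that the expected selected down:up ratio equals
  the target.
* **Down-regulated genes inside domains** (default target 5.5%). Genes are
  Poisson-placed at 8/Mb outside and 1/Mb inside planted domains; the
  709 down- and 283 up-regulated genes are sampled with the target
  fraction drawn from inside-domain genes, because no fixed per-gene
  weight can hit a stated inside-fraction across gene-density settings.

ChIP peaks are homogeneous Poisson (30/Mb, 500 bp) with a knockout-only
+10/Mb gain inside planted domains. Isochore tiles (0.3–3 Mb) partition
each chromosome; tiles overlapping a planted domain draw from the GC-poor
classes only, the rest from mouse-like proportions (L1 20%, L2 38%,
H1 27%, H2 11%, H3 4%).

All streams derive from one seed through fixed per-stream offsets
(SeedSequence(seed, k) with k = 1…7 for LADs, ATAC peaks, ChIP WT, ChIP
KO, genes, expression, isochores), so regenerating any one product does
not perturb the others.

**What passing the benchmark does and does not show.** The generator
reproduces the *spatial and distributional* structure the method relies
on — domain-scale fold-change shifts, sparser peaks and genes inside
domains, density gains, nested LAD geometry — under clean normal noise and
exact renewal spacing. It does not model correlated replicate noise,
mappability or copy-number artifacts, peak-caller boundary jitter,
chromosome-scale covariates (centromeres, segmental duplication), or any
nucleotide sequence. Recovery of planted domains here bounds the method's
behaviour under its own assumptions; it does not certify performance on
real data, where threshold choice and input quality dominate.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open throughout; GTF converts at the reader
boundary. Chromosome names match exactly (a rename utility is provided,
no silent "chr" aliasing). Empty selections, empty domain sets and
zero-denominator fractions report NaN rather than 0, so "no signal" is
distinguishable from "signal absent". The density statistic raises when a
domain set captures no bins or tiles a genome (no outside bins) — both
leave the inside/outside contrast undefined. Peak-to-bin assignment is by
midpoint with half-open bins (a midpoint exactly on a boundary belongs to
the right bin); the final partial bin is kept and density-scaled by its
true width. Expression percentages are returned as exact floats; display
rounding is left to the caller (the published 39/709 prints as ~5%).

## Scale of the shipped computations

The test suite and acceptance script run the default synthetic genome
(300 Mb, ~28k peaks) end to end in about a second per run; the oracle
comparisons use 1,000 random tracks of ≤50 points, and the null-calibration
check uses 50 replicates at n_perm = 199. These sizes were chosen to make
the statistical checks decisive (binomial CIs of ±1–2 percentage points,
KS at n = 50) while keeping a full run interactive on one CPU.

## Known limitations

* The caller is threshold-based; it has no notion of uncertainty on
  domain boundaries and no alternative segmentation (HMM/changepoint)
  backend.
* Overlap statistics treat "overlap" as ≥1 bp by default, as published
  domain-overlap percentages usually do; use `min_bp`/`min_fraction` for
  stricter notions.
* The rotation null preserves per-chromosome structure but assumes
  exchangeability of positions along a chromosome; strong large-scale
  covariates (e.g. acrocentric chromosome ends) are not conditioned on.
* Isochore classes are consumed from an input map; GC content is never
  computed from sequence.
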