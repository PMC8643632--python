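# hadcall

Calling and characterizing **HAT1-dependent accessibility domains (HADs)**
from differential ATAC-seq peak tables.

Loss of the histone acetyltransferase HAT1, which acetylates newly
synthesized histone H4 during replication-coupled chromatin assembly,
collapses the accessibility of megabase-scale heterochromatic domains.
These domains are gene-poor, AT-rich (isochores L1/L2), largely coincide
with lamin-associated domains (LADs), and coincide with regions where the
density of H3 K9me3 ChIP peaks rises in the knockout. `hadcall` implements
the computational side of that analysis as a tested, reusable library for
anyone who has a differential accessibility peak table (e.g. from
DiffBind/DESeq2) and wants to ask whether the signal is organized into
large domains rather than scattered peaks.

## The method

Given peaks with knockout-vs-wildtype log2 fold changes
$x_1, \dots, x_n$ at midpoints $m_1 < \dots < m_n$ along a chromosome:

1. **Smoothing** — a sliding mean over $w = 25$ data points (not a fixed
   genomic width), centered and truncated at chromosome ends:
   $\bar x_i = \operatorname{mean}(x_{i-h}, \dots, x_{i+h})$,
   $h = (w-1)/2$.
2. **Marking** — points with $\bar x_i \le c$ are domain-like, with
   $c = -0.58 \approx \log_2(1/1.5)$, i.e. a 1.5-fold accessibility loss.
3. **Gap merging** — consecutive marked points whose peak footprints are
   separated by at most $g = 1$ Mb belong to the same domain, regardless
   of intervening unmarked points; a domain spans from its first to its
   last member peak. Domains on chrY are excluded from reporting.

Around the caller: differential-site selection ($|\log_2 FC| \ge 1$,
$p < 0.01$), domain size/genome-fraction/gene-density statistics,
promoter/exon/intron/downstream/distal annotation of sites, isochore-class
composition, element-wise domain overlap and base-pair Jaccard against LAD
sets with a **circular-rotation permutation null**, per-Mb ChIP
peak-density differencing with the same null, and integration with a
differential-expression table ($\ge$1.5-fold, $p < 0.05$). A seeded
synthetic-data generator produces toy genomes with planted
low-accessibility domains nested in LAD-like regions, so every stage is
testable without any download.

## Worked example

```sh
python examples/01_simulate_and_call.py
```

```
peaks in the differential table: 27037
planted domains:                 20
called domains:                  20
planted bp recovered:            99.81%
called bp outside planted:       1.85%
```

The default synthetic genome (3 × 100 Mb, 30 LADs, 20 of them with a
planted accessibility loss of mean log2FC −1.5 against background noise of
SD 0.3) is recovered essentially exactly: one called domain per planted
domain, with <2% of called bases spilling past the true boundaries —
the expected edge overreach of a 25-point window at ~10 kb peak spacing.
The other examples print the LAD overlap statistics (100% of called
domains in LADs, rotation-null p = 0.005), the ChIP density change
(+7.8 peaks/Mb concentrated inside domains, p = 0.005), and the
annotation/expression summary (87.9% of differential sites lose
accessibility; 6.1% of down-regulated genes lie inside domains).

The same analyses run from files via the CLI:

```sh
hadcall simulate --seed 1 --out sim/
hadcall call --diff-table sim/differential_peaks.tsv \
             --chrom-sizes sim/genome.chrom.sizes --out hads.bed
hadcall overlap --query hads.bed --subject sim/lads.bed \
                --chrom-sizes sim/genome.chrom.sizes
hadcall density --wt sim/chip_wt.narrowPeak --ko sim/chip_ko.narrowPeak \
                --chrom-sizes sim/genome.chrom.sizes --domains hads.bed
hadcall run --config config.yaml --out results/
```

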