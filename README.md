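# minquant

Quantitative multiplexed (MINUTE-style) ChIP-seq scaling and
bivalent-promoter landscape analysis.

## The problem

Conventional ChIP-seq normalization erases global differences between
conditions: every library is scaled to the same depth, so a genome-wide gain
or loss of a histone modification is invisible. In a multiplexed
(MINUTE-style) experiment, barcoded samples are pooled *before*
immunoprecipitation, so each sample's share of sequenced reads is
proportional to the amount of epitope it carries — up to unevenness in how
much chromatin each barcode contributed. The **input-normalized read count**

    INRC = #mapped[ChIP] / #mapped[Input]

corrects that unevenness, and the ratio of a sample's INRC to a reference
condition's INRC is its **global level**. Tracks are expressed in
**reads-per-genome-coverage (RPGC)** units: the reference (untreated naive
hESCs, pooled replicates) is scaled so its genome-wide mean coverage is 1,
and every other sample is scaled so its mean equals its global level
(per-sample factor = global_level x genome_size / (unique_reads x
fragment_length); genome size 3,095,978,588 for hg38, the chromosome-length
sum for synthetic genomes).

This package re-implements that analysis end to end for the naive/primed
human embryonic stem cell (hESC) design with and without PRC2 (EZH2)
inhibition, profiling H3K27me3, H3K4me3 and H2Aub:

* **simdata** — a seeded generator of synthetic genomes, modification
  landscapes, pooled tagged-read libraries (6 nt UMI + 8 nt barcode read
  prefix, PCR duplicates, substitution errors) and NB-distributed expression
  matrices, with every downstream quantity planted as ground truth;
* **demux** — barcode assignment at <=1 mismatch (guaranteed unambiguous by a
  minimum pairwise Hamming distance of 3 in the barcode set) and
  UMI-sensitive duplicate marking: reads at the same (chrom, 5' position,
  strand) with UMIs within Hamming distance 1 are one molecule (connected
  components);
* **scaling** — INRC, reference-anchored global levels, RPGC coverage tracks
  (bedGraph);
* **landscape** — 10-kb bin, chromatin-state, promoter-window and
  per-chromosome summaries, including X:autosome density ratios and each
  chromosome's share of total signal;
* **diffstats** — a negative-binomial Wald test with fixed size factors
  (a documented DESeq2-style approximation), Benjamini–Hochberg adjustment,
  Wilcoxon rank-sum and Cohen's *d*;
* **bivalency** — five-class promoter annotation
  (`primed_bivalent`, `naive_bivalent`, `common_bivalent`, `k4_only`,
  `k4_negative`) from H3K4me3/H3K27me3 positivity and the promoter H3K27me3
  differential test (padj < 0.05, fold change > 1.5), class-switch tables,
  and class-stratified transcriptional-response statistics (derepression at
  FDR < 5%, |log2FC| > 1; H2Aub change at derepressed genes);
* **gating** — the two single-cell gating rules: marker positivity above
  1.5x the matching control mean intensity, and ground-state classification
  below the 0.95 quantile of control pseudotimes.

## Worked example

```python
from minquant.pipeline import PipelineConfig, run_pipeline
from minquant.simdata import SimulationConfig

res = run_pipeline(PipelineConfig(sim=SimulationConfig(seed=1, depth=20_000)),
                   "runs/demo")
pooled = res.factors.table[res.factors.table["replicate"] == "pooled"]
print(pooled[["mark", "condition", "global_level"]].round(3).to_string(index=False))
print(res.classes["promoter_class"].value_counts().to_string())
print(f"class accuracy vs simulation truth: {res.class_accuracy:.3f}")
```

prints (seed 1, 20,000 reads per sample):

```
    mark        condition  global_level
H3K27me3  naive_untreated         1.000
H3K27me3      naive_ezh2i         0.031
H3K27me3 primed_untreated         0.691
H3K27me3     primed_ezh2i         0.053
 H3K4me3  naive_untreated         1.000
 H3K4me3      naive_ezh2i         1.020
 H3K4me3 primed_untreated         1.009
 H3K4me3     primed_ezh2i         0.993
   H2Aub  naive_untreated         1.000
   H2Aub      naive_ezh2i         0.879
   H2Aub primed_untreated         0.710
   H2Aub     primed_ezh2i         0.660
promoter_class
naive_bivalent     119
k4_negative        100
primed_bivalent    100
k4_only             96
common_bivalent     85
class accuracy vs simulation truth: 0.962
```

The global-level column is the estimated INRC ratio to the untreated naive
reference: EZH2 inhibition leaves ~3% of H3K27me3 in naive cells (a 97%
depletion) and ~8% in primed cells, H3K4me3 is globally unchanged, and H2Aub
drops only mildly. The class table shows the recovered five-way promoter
annotation (100 promoters per class were planted; the surplus of
`naive_bivalent` calls comes from X-chromosome promoters whose naive signal
is genuinely doubled by the planted X hypermethylation). The run directory
contains demux/dedup statistics, the scale-factor table, scaled bedGraph
tracks, bin/state/promoter/chromosome summaries, differential tables,
classification and response tables, gate tables and a cross-checked
`report/summary.tsv`.

The same pipeline is available from the shell:

```
minquant run --seed 1 --depth 20000 --outdir runs/demo
minquant report runs/demo
```

plus file-level subcommands (`demux`, `dedup`, `scale`, `quantify`, `diff`,
`classify`, `respond`, `gate marker`, `gate pseudotime`) for running single
stages on TSV/BED/bedGraph inputs.

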