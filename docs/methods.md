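# Methods

## Quantitative scaling model

A multiplexed ChIP experiment pools barcoded chromatin from all samples
before immunoprecipitation. Under the assumptions that (i) antibody capture
within a pool is not saturated and (ii) barcode identity does not affect
capture efficiency, the number of unique reads a sample contributes to the
ChIP pool is proportional to its epitope content times its (uneven) share of
pooled chromatin. The matched input library measures that share directly, so
the input-normalized read count INRC = unique ChIP reads / unique input reads
is proportional to epitope abundance, and global levels are INRC ratios to a
reference condition.

Tracks are reported in RPGC units. The per-sample track factor is

    factor = global_level * genome_size / (unique_reads * fragment_length)

which makes the reference's genome-wide mean coverage exactly 1 and every
other sample's mean exactly its global level. In an ideal pool with even
barcode representation this is identical to scaling every sample by the
reference's 1x factor times its INRC ratio; with uneven representation the
per-sample form is the one that preserves the INRC ratios on the tracks,
which is the entire point of the method, so it is the form implemented.
Reference INRC uses pooled replicates (summed ChIP and input counts).
Reads are extended to a fixed fragment length (default 150 bp, the typical
mononucleosome footprint) toward 3'; coverage is binned at 50 bp by exact
per-basepair averaging, so sum(bin value x bin width) = factor x reads x
fragment length whenever fragments fit inside their chromosome.

## Demultiplexing and deduplication

Read 1 begins with a 6 nt UMI followed by an 8 nt sample barcode. A read is
assigned when exactly one design barcode lies within one mismatch; the
barcode set is required to have minimum pairwise Hamming distance
2 x max_mismatch + 1 = 3, which makes the assignment unambiguous by
construction rather than by tie-breaking. Duplicates are defined per
(sample, chromosome, 0-based 5' position of read 1, strand): UMIs at one
location are clustered by connected components of the <=1-mismatch graph,
the number of molecules is the number of components, and the retained
representative is the highest-multiplicity UMI (ties broken by
lexicographically smallest). Connected components are the most permissive
reading of a pairwise one-mismatch rule; directional-adjacency schemes
(which only merge an error UMI into a more abundant parent) would split
some chains that components join — on synthetic data the difference is
confined to rare three-UMI chains. Fragment-end information is not used;
single-end 5' anchoring matches the simulator's read model.

## The synthetic study

The generator plants a complete ground truth for a 2 Mb genome: four
autosomes (500/400/400/400 kb) plus a 300 kb chrX, 10 kb chromatin-state
segments (polycomb / active / heterochromatin / quiescent at 20/20/20/40%,
exact per-chromosome quotas), and 500 promoters — 100 in each of five
classes — placed on an even grid stratified by chromosome so that class
composition is identical per basepair everywhere. Stratification matters:
promoter windows cover half of this small genome, so random placement would
put several percent of sampling noise on every chromosome-scale ratio.

Landscapes are built in absolute units (reference background = 1):

* the diffuse, non-promoter background carries the between-state global
  differences — H3K27me3 background 3.3-fold and H2Aub 2.1-fold higher in
  naive than primed; H3K4me3 background equal;
* promoter windows (TSS +/- 1 kb) are overwritten at absolute class heights:
  H3K27me3 8 for the enriched state and 8/4 for the depleted state of the
  state-specific bivalent classes, 8 in both states for common bivalent;
  H3K4me3 8 at every class except `k4_negative`; H2Aub 3 and 3/2 following
  the H3K27me3 pattern. Common-bivalent promoters therefore carry *equal*
  scaled signal in both states — the global gain is diffuse, not
  promoter-driven — which is what makes the five classes identifiable on
  quantitatively scaled tracks at all;
* naive chrX H3K27me3 is doubled wholesale (x_boost = 2), emulating diffuse
  X hypermethylation;
* EZH2 inhibition multiplies the whole H3K27me3 landscape by a residual
  (0.03 naive, 0.08 primed), leaves H3K4me3 untouched, and multiplies H2Aub
  by 0.85 only inside derepressed-class promoter windows.

True global factors are the emergent landscape-mass ratios to untreated
naive. A consequence of desk scale: because promoters occupy ~50% of the
genome (vs a few percent of a mammalian genome), the emergent naive/primed
global H3K27me3 ratio is ~1.45, not the 3.3 of the background — at this
genome size the published global ratio and an intact class structure cannot
coexist, and the class structure is what downstream modules consume. The
EZH2i residuals and the X ratio are exact by construction.

Reads: per sample, counts are Poisson with mean depth x global factor x
barcode-representation noise (lognormal sigma 0.10, shared between a
sample's ChIP and input libraries — exactly the unevenness INRC removes) x
biological replicate noise (lognormal sigma 0.02, ChIP only). Each emitted
read is a PCR duplicate with probability dup_rate (default 0.15), re-emitting
the coordinates and UMI of a uniformly chosen existing molecule; all tag
bases pass through an independent substitution channel (default 1% per
base), so duplicates can acquire one-mismatch UMIs and genuinely exercise
the mismatch-tolerant collapse. Fragment starts are drawn proportional to
the landscape at 200 bp granularity and constrained to fit, so track
conservation is exact. Input pools are uniform over the genome.

Expression: per-gene NB counts with base means log-uniform on [20, 500] and
dispersions uniform on [0.01, 0.15] across 4 conditions x 3 replicates.
State-specific bivalent genes are repressed (log2 effect -1) in their marked
state and derepressed (+1) by treatment there; common-bivalent genes are
repressed and derepressed in both states; half of the K27-devoid genes
respond to treatment anyway (secondary activation downstream of derepressed
regulators), so not every upregulated gene is K27-marked.

Defaults: 100,000 reads per sample, 3 replicates, 4 conditions, 3 marks plus
input. The full pipeline runs in well under two minutes on one CPU.

What the generator does *not* emulate: mappability and GC bias, fragment-
length variation, copy-number structure in inputs, quality scores, adaptor
artefacts, between-replicate promoter-specific variability, and any coupling
between chromatin state and expression beyond the planted class effects.
Passing tests therefore demonstrate correctness of the estimators under the
stated generative model, not robustness to alignment or library-preparation
pathology.

## Differential testing

Features (promoter windows or bins) are tested on integer pseudo-counts,
round(scaled mean x width / fragment length), restoring count support for NB
inference while keeping the fixed-size-factor semantics of pre-scaled
tracks; RNA counts are tested raw. For two conditions with n_a and n_b
replicates:

* per-feature dispersion by method of moments, alpha_i = (var - mu)/mu^2
  pooled within groups, floored at 1e-4 and capped at 10;
* a mean-dispersion trend by bin-pooled moment regression (through the
  origin) in 10 quantile bins of log mean, linearly interpolated;
* moderation: alpha = w alpha_i + (1 - w) trend with w = d/(d + d0),
  residual df d = n_a + n_b - 2 and prior df d0 = 20. The prior df plays the
  same role as the empirical-Bayes prior in established RNA-seq moderation
  schemes; 20 was chosen by null simulation (20,000 NB features across mean
  and dispersion regimes) as the weight at which the test's size is closest
  to nominal at n = 3 vs 3;
* group means by vectorized Newton MLE of the NB GLM with log link and known
  dispersion (score sum (y - mu s)/(1 + alpha mu s) = 0); a pseudocount of
  0.1 enters the fold change when a group mean is zero, and the Fisher
  information is evaluated at that floor so all-zero groups get a large but
  finite SE;
* Wald p values are two-sided normal on log2FC / SE, with the SE multiplied
  by t(d + d0, 0.975)/z(0.975) to propagate dispersion-estimation
  uncertainty. Measured type-I error at nominal 0.05 is 0.042–0.055 across
  regimes (it would be 0.07–0.10 without the moderation and SE adjustment).

This is deliberately an approximation of the reference NB machinery (no
Cox–Reid adjustment, no posterior fold-change shrinkage beyond an optional
normal-prior ridge with prior SD 1.0 used for the RNA branch); the tests
cross-check it against an independent NB-GLM implementation on a small
fixture (log2FC correlation > 0.999).

Significance rules: ChIP, adjusted p < 0.05 and fold change > 1.5; RNA,
FDR < 5% and fold change > 2 (the |log2FC| > 1 volcano rule).
Benjamini–Hochberg is standard step-up with NaN propagation. Note that BH is
not idempotent: re-adjusting an adjusted vector can only raise values, with
constant vectors the fixed points.

Class responses compare a gene class against *all* genes (class included):
two-sided Wilcoxon rank-sum with tie-corrected normal approximation, or
exact enumeration over assignments when both groups have <=10 members
("at least as extreme" convention, midranks for ties), plus Cohen's d with
the pooled SD of the two groups as given.

## Promoter classification

Mark positivity is promoter mean >= 2 x the genome median of the scaled
track. The median is computed after rebinning to 1 kb: the native 50 bp
median collapses to zero on sparse tracks, while coarser bins on this
promoter-dense genome mix promoter and background signal. Both the fold
(2x) and the anchor width are configuration. Classes:

1. `k4_negative` — H3K4me3-negative in both states, regardless of H3K27me3;
2. `primed_bivalent` — K27 significantly higher in primed and K27-positive
   there; 3. `naive_bivalent` — the mirror image;
4. `common_bivalent` — K27-positive in both states, no significant state
   difference; 5. `k4_only` — everything else.

The rules are applied in that order; since the significant-higher conditions
are mutually exclusive, the partition is exhaustive, exclusive, and exactly
symmetric under swapping the state labels. On default synthetic data ~96% of
promoters recover their planted class; the systematic residual is chrX
common-bivalent promoters, whose naive signal really is doubled by the
planted X hypermethylation and which the classifier accordingly calls
naive-bivalent.

## Gating rules

Marker positivity: threshold = 1.5 x the arithmetic mean intensity of all
control objects of the matching experiment; positive means strictly above.
Jointly rescaling a sample and its control leaves every call unchanged.
Ground-state gating: threshold = the 0.95 linear-interpolation quantile of
control pseudotimes (pooled controls); ground means strictly below. Cells
above the threshold are split by branch label into activated,
trophectoderm-activated and mesoderm-activated subsets; activated cells
without a branch label are flagged unclassified rather than guessed.

## Numerical and format conventions

All intervals are 0-based half-open. bedGraph (4-column) is the canonical
track format; TSV values are written at %.6g so reruns are byte-identical.
Promoter windows are strand-aware (upstream flank mirrored on the minus
strand) and clipped at chromosome ends. Chromosome "autosome mean" densities
are length-weighted. Degenerate inputs fail loudly: zero input counts, zero
genome medians, out-of-bounds reads or regions, barcode sets violating the
distance bound, and quantiles outside (0, 1) raise typed errors that the CLI
maps to exit codes 2 (configuration) and 3 (data).

## Known limitations

* The NB test's calibration is established by simulation, not proof, and
  degrades below two replicates by construction (it refuses to run).
* Pseudo-counts discard within-window shape; a fragment-level count would be
  needed to detect sub-window redistribution.
* Blacklist subtraction is available as interval filtering but defaults to
  off for synthetic genomes.
* The duplicate model re-samples molecules uniformly, so duplicate counts
  per molecule are geometric-like rather than PCR-branching distributed;
  unique-molecule recovery is unaffected.
* bigWig output is not produced; bedGraph keeps the on-disk form text-exact.
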