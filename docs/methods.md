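# Methods

This note describes the models and procedures implemented in `tregdegron`,
the choices behind them, and what the synthetic data generator does and
does not emulate.

## The experimental design being modelled

The pipeline targets acute transcription-factor degradation experiments in
regulatory T (Treg) cells: Foxp3 is fused to an auxin-inducible degron so
that ligand dosing removes the protein within hours, and the transcriptome
is profiled by multiplexed scRNA-seq at days 0, 3 and 7 of treatment in a
degrader genotype versus a degradation-incompetent control, with four
biological replicates per genotype hashed together per time point. The
questions the analyses answer are: which genes respond to acute Foxp3
loss, in which cell state (resting vs. activated), how the response grows
over time, whether responding genes are directly Foxp3-bound relative to
their chromatin accessibility, which chromatin/motif context they sit in,
how response signatures track Foxp3 dose, and how Treg suppressive
function reads out in vitro.

## Synthetic data generator

The generator (`simulate`) plants a fully known truth so every downstream
stage can be tested for recovery, calibration and direction.

**Counts.** Cells × genes UMI counts are negative binomial with mean
`mu = libsize × p_g` and variance `mu + alpha·mu²` (`nb_dispersion = alpha
= 0.05`). Per-gene baselines are log-normal (sigma = 1); per-cell library
sizes are log-normal around `libsize_mean = 5000`. Gene proportions `p_g`
are baseline weights modified by three multiplicative layers:

- *State markers.* Two disjoint 30-gene marker modules are up-weighted
  3-fold in their own state and down-weighted 3-fold in the other,
  emulating reciprocally regulated resting/activated Treg signatures.
- *Degradation response.* All contrasts are oriented log2(degrader /
  control). A `direct_activated` module (Foxp3-induced) gets
  −log2(effect) and a `direct_repressed` module +log2(effect), with
  effect 2× at day 3 and 4× at day 7 (time-dependent augmentation). An
  `indirect` module responds only at day 7 at half the direct log-effect,
  alternating sign — a testable stand-in for relay-like propagation.
  Null genes never respond.
- *Proliferation.* In proliferating degrader cells the planted log2
  effect is multiplied by `proliferation_amplification = 2`, so the
  response concentrates in cycling cells.

The Foxp3-proxy anchor gene (the first `direct_activated` gene) has its
baseline pinned at the +1.5 sigma point of the baseline distribution:
Foxp3 is among the most abundant TF transcripts in Treg cells, and an
anchor drawn from the low-expression tail would measure shot noise rather
than dose. Mitochondrial genes are a designated 10-gene subset re-weighted
to contribute `mito_gene_frac = 2%` of expected counts.

**Hashtags.** Each sample in a pool is hashed with one tag. Singlet
droplets get Poisson(`hto_positive_mean = 150`) counts on their tag,
doublets on two tags, negatives on none; Poisson(`hto_background_mean =
3`) background sits on every tag. Default doublet and negative rates are
5% and 1%. Doublets carry only additive tag counts — expression mixing is
deliberately out of scope.

**Toy genome.** Non-overlapping gene loci are spaced along one chromosome
so TSS ± 50 kb windows never collide. Each gene receives 1 + Poisson(4)
open-chromatin (ATAC) peaks of 300 bp within ±40 kb of its TSS. Peaks near
direct-module genes are flagged Foxp3-bound with probability 0.6 versus
0.2 elsewhere; bound peaks are a subset of open peaks by construction.
Histone signals are log-normal around module means — `direct_activated`
peaks high H3K27ac (8) / low H3K27me3 (1), `direct_repressed` the
reverse, others 3/3. Peak sequences are uniform random DNA; a STAT-like
consensus (TTCCAGGAA) is planted with probability 0.8 in bound peaks near
`direct_activated` genes and 0.05 elsewhere, plus a bZIP-like decoy
planted uniformly at 0.05 (never overwriting an earlier plant). Planted
positions are recorded for exhaustive-search verification.

**Suppression wells.** A no-Treg control divides at 0.8; a well at Treg
ratio r has planted suppression `0.75·r` and Beta-distributed divided
fractions (concentration 200) around `0.8·(1 − 0.75·r)`.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: ambient RNA and barcode swapping, doublet
expression profiles, batch and replicate-level biological variation beyond
count noise, gene–gene correlation within modules, UMI saturation,
transcript-length and GC biases, realistic genome architecture (overlapping
genes, enhancer sharing, peak width variation), and motif grammar beyond a
single planted consensus. Calibration results on this generator show the
statistics behave correctly under their assumed noise model, not that the
assumptions hold in any particular dataset.

**Determinism.** Every operation draws from `default_rng([seed, offset])`
with a fixed per-operation offset, so identical configs give bit-identical
outputs while stages stay independent.

## QC and demultiplexing

Filters follow strict-inequality boundary semantics: cells with fewer
than 1000 UMIs or fewer than 1000 detected genes, or more than the
mitochondrial fraction cap, are removed; a cell exactly at a threshold is
retained. Two profiles ship: `flex` (5% mito cap) and `steady_state`
(20%). Cell filtering precedes gene filtering, so the "detected in more
than 5 cells" gene rule counts only retained cells. The removal report
attributes each cell to the first violated rule (UMI → genes → mito).
Normalization scales each cell to the median pre-scaling total and applies
ln(1 + x).

Hashtag demultiplexing partitions ln(1+count) values per tag into a
background and a positive component with an **exact one-dimensional
two-means**: all boundaries between distinct sorted values are scanned and
the split minimizing the within-cluster sum of squares is taken. This is
globally optimal, deterministic (no random initialization) and directly
checkable against the exhaustive oracle. A tag whose values are all equal
yields no positive droplets. Droplets positive for one tag are singlets,
for two or more doublets, for none negatives.

## Signature scoring and cell states

The score of a signature in a cell is the mean normalized expression of
the signature genes minus the mean of a size-matched, expression-bin-
matched control set: genes are ranked by mean expression into 25
equal-occupancy bins and 50 control genes per signature gene are sampled
from its bin, excluding the signature itself. A random gene set therefore
scores ≈ 0. Cells are called resting (activated) when they exceed the
resting (activated) threshold and not the other; both or neither leaves
the cell unassigned. Default thresholds are 0 and config-exposed — on
real data they should be set from the score distributions.

Meta-cells are built within (sample × state) strata: cells are embedded by
the top 10 principal components of the 500 most variable genes and
partitioned by k-means with k = ⌈n / target_size⌉ (target 20). Strata
smaller than the target collapse to one meta-cell. Dose–response is the
Pearson correlation of meta-cell mean anchor expression against meta-cell
mean signature expression.

## Pseudo-bulk differential expression

Cells are summed into replicate × genotype (× state × day) samples, so
biological replicates are the sampled units. Counts are normalized by
**median-of-ratios size factors** computed jointly across both arms, then
log2(normalized CPM + 1); per gene, a Welch two-sample t-test compares
degrader versus control and Benjamini–Hochberg controls the FDR within
the contrast. The size-factor choice is deliberate: a responding gene
module shifts library composition, and total-count scaling would push
every non-responding gene's fold change off zero (in simulations with a
4× planted module, plain CPM biased null genes to ≈ −0.15 log2 and
inflated the type-I rate to ≈ 0.13; median-of-ratios restores ≈ 0.04 at
nominal 0.05). Genes with zero variance in both arms get p = 1 when the
means agree. A Welch t on the log scale was preferred over an NB GLM as a
dependency-light test whose calibration is verified by simulation.

Day-7 significant genes (q < 0.05, any fold change by default) are grouped
per state into TIR1-up (up in the degrader, i.e. Foxp3-repressed) and
TIR1-down (Foxp3-activated) sets. P-value stratification ranks genes
within each fold-change direction (p ascending, ties by |log2FC|
descending then gene id), takes the top 50 and splits the remainder into
rank quartiles.

## Binding enrichment, histone signal and motifs

Peaks are assigned to every gene whose TSS ± 50 kb window (0-based,
half-open) they intersect; a peak may serve several genes, matching the
per-gene normalization. A group's statistic is the pooled
`Σ bound / Σ open` over its genes (per-gene rates are also reported).
Significance is a one-sided **gene-label permutation**: |focal| genes are
drawn from the background uniformly, the pooled fraction recomputed, and
p = (1 + #{null ≥ observed}) / (n_perm + 1). Genes, not peaks, are
permuted because genes are the sampled units and per-gene peak counts are
preserved under the null. Histone comparisons average a signal over each
group's (bound, by default) peaks.

PWM scanning scores every window on both strands as
Σ log2((p_base + 1e-4)/bg_base), skipping windows containing N; the 1e-4
pseudo-probability bounds log-odds away from −∞. Motif enrichment is a
peak-level hypergeometric upper tail on presence of ≥1 hit in foreground
versus background peaks, with fold = foreground rate / background rate.
The default scan threshold is 80% of a motif's maximum score.

## Assay statistics

The divided fraction counts responder cells that divided strictly more
than 4 times (the dilution-dye convention). Percent suppression is
100·(divided(noTreg) − divided(X)) / divided(noTreg) — scale-invariant,
negative if the sample divides more than control, undefined when the
control does not divide. Positive fractions (e.g. Ki67+, EdU+) carry exact
Clopper–Pearson 95% intervals from the beta quantiles.

## Problem sizes used in tests and the acceptance script

Simulated checks run at deliberately small sizes chosen to keep Monte
Carlo error well inside the tested margins: 2000 genes with 50/50/100
direct/indirect module genes; 50 cells per replicate sample for
calibration and state-classification checks; 200 cells per replicate
sample for DE power, recovery and day-scaling (a scaled-down analogue of
the ~1400 cells per sample a pooled experiment yields — 50 cells/sample
leaves a 4-replicate Welch t underpowered for the knocked-down module,
which is a property of the design, not of the implementation); 5000
droplets for demultiplexing accuracy; 600 genes for the toy genome; 999
permutations for planted-enrichment p-values and 199 × 200 repeats for
permutation-null calibration. The end-to-end demo uses 600 genes × 960
cells and completes in seconds.

## Known limitations

- The Welch t-test assumes approximate normality of per-sample log
  expression; with very few cells per pseudo-bulk sample or very low
  counts an NB GLM (e.g. DESeq2/edgeR) is preferable.
- Median-of-ratios retains a small bias when a large, one-directional
  fraction of genes responds (a known property of the estimator).
- Signature scoring samples controls within expression bins only; it does
  not match dropout rate separately from mean.
- The meta-cell construction (PC k-means within strata) is one reasonable
  choice; graph-based meta-cell methods would serve equally.
- Cluster labels and embeddings are consumed as inputs; clustering itself
  is out of scope.
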