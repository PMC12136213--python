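# tregdegron

Analysis pipeline for **acute Foxp3-degron perturbation experiments in
regulatory T (Treg) cells**. When Foxp3 protein is degraded on demand (an
auxin-inducible degron plus ligand dosing) and cells are profiled by
multiplexed scRNA-seq over a treatment time course, the analysis has to
answer: which genes respond, in which cell state, how the response grows
with time, whether responding genes are directly Foxp3-bound, what
chromatin and motif context they sit in, how response signatures track
Foxp3 dose, and how Treg suppressive function reads out in vitro. This
package implements that analysis end to end, together with a synthetic
data generator that plants a known truth so every stage is testable for
recovery, calibration and direction.

Intended users: computational biologists analysing degron/perturbation
scRNA-seq time courses, and method developers who need a planted-truth
benchmark for the component statistics.

## What is implemented

| Stage | Statistic / algorithm |
|---|---|
| QC | strict-boundary cell filters (≥1000 UMIs, ≥1000 genes, mito ≤5% or ≤20%), genes detected in >5 cells, median-total + ln(1+x) normalization |
| Demultiplexing | exact 1-D two-means split of ln(1+count) per hashtag; singlet/doublet/negative calls |
| Cell states | bin-matched background signature scores; resting/activated gating by dual thresholds |
| Pseudo-bulk DE | replicate-level sums, median-of-ratios size factors, Welch t on log2(CPM+1), BH FDR; log2FC oriented degrader/control |
| Gene groups | per-state TIR1-up / TIR1-down sets at day 7; p-value strata within fold-change direction |
| Binding enrichment | Foxp3-bound fraction of open-chromatin peaks per gene group, `Σ n_bound / Σ n_open` over TSS±50 kb windows, gene-label permutation p |
| Chromatin context | H3K27ac/H3K27me3 means at bound peaks; PWM log-odds scanning (both strands) with hypergeometric motif enrichment |
| Dose–response | PC/k-means meta-cells within sample×state strata; Pearson r of signature vs. anchor (Foxp3-proxy) expression |
| Assays | divided fraction (strictly >4 divisions), %Suppression = 100·(divided(noTreg) − divided(X))/divided(noTreg), Clopper–Pearson intervals |

The core quantities, in the field's notation: for gene *g* in state *s*,
the pseudo-bulk contrast reports log2FC(g,s) = mean log2 CPM(degrader) −
mean log2 CPM(control) with Welch-t p and BH q; a gene group *G* has
bound fraction `f(G) = Σ_{g∈G} n_Foxp3(g) / Σ_{g∈G} n_ATAC(g)` with a
permutation p from uniform gene draws; a motif's enrichment in foreground
peaks is the hypergeometric upper tail on peaks with ≥1 hit at ≥80% of
the motif's maximum log-odds.

## Worked example

Generate a self-contained synthetic experiment (2 genotypes × days 0/3/7 ×
4 replicates, hashed per time point) and run the full pipeline:

```bash
degron-pipeline demo --seed 1 --out demo
degron-pipeline run --config demo/config.yaml
```

Selected outputs from `demo/run/` (seed 1):

`binding_enrichment.tsv` — degradation-responsive gene groups carry more
Foxp3-bound open-chromatin peaks than expected from random gene draws
(planted rates: 0.6 near direct targets vs. 0.2 elsewhere):

```
group                n_genes  n_atac  n_foxp3  bound_fraction  perm_p
resting_TIR1_up      28       138     76       0.551           0.001
resting_TIR1_down    26       134     57       0.425           0.001
activated_TIR1_up    31       159     82       0.516           0.001
activated_TIR1_down  22       120     54       0.450           0.001
```

`metacell_correlations.tsv` — across degrader meta-cells, the recovered
Foxp3-activated (TIR1-down) signature tracks the Foxp3-proxy anchor
positively and the Foxp3-repressed (TIR1-up) signature negatively,
i.e. dose-dependent activation and repression:

```
signature  n_metacells  pearson_r  p
TIR1_down  34           0.810      6.8e-09
TIR1_up    34           -0.760     1.8e-07
```

`motif_enrichment.tsv` — the STAT-like motif planted in bound peaks near
Foxp3-activated genes ranks first; the uniformly planted decoy is flat:

```
motif_id    p         fold   n_peaks_with_hit
STAT_like   1.8e-26   11.2   211
bZIP_decoy  0.50      1.1    147
```

`suppression_curve.tsv` — the titrated suppression assay recovers the
planted strength (75% at ratio 1:1, halving with each dilution):

```
condition   percent_suppression  sd    n_wells
noTreg      -0.0                 1.62  3
Treg_1to1   72.7                 2.99  3
Treg_1to2   45.4                 4.17  3
Treg_1to4   19.8                 2.77  3
Treg_1to8   10.8                 1.83  3
```

A rerun with the same config reproduces every output byte for byte; the
manifest (`manifest.json`) records the config hash and per-file digests.

The same stages are available as library calls (`tregdegron.simulate`,
`.qc`, `.scoring`, `.pseudobulk`, `.enrichment`, `.motifs`, `.assays`)
and as individual subcommands (`qc`, `demux`, `score`, `metacell`, `de`,
`strata`, `enrich`, `motif`, `suppress`).

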