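"""Synthetic degron-experiment generator with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: negative-binomially distributed UMI counts over resting / activated
/ proliferating Treg states for a control and a degrader genotype at days
0/3/7 with replicate structure; hashtag (HTO) tag counts with background
noise, doublets and negatives; a toy genome in which direct-target genes
carry a higher density of TF-bound open-chromatin peaks, module-dependent
histone signals and planted motifs; and suppression-assay well tables.

Every operation draws from its own RNG stream derived from ``config.seed``
plus a fixed per-operation offset, so identical configs give bit-identical
outputs and stages remain independent.

Planted effects follow the degrader-vs-control orientation: all fold
changes are log2(degrader / control), so degradation of a gene's activator
yields a negative log2FC. Direct modules respond at day 3 and more strongly
at day 7; the indirect module responds only at day 7 at half the direct
log-effect (a relay-like delay); null genes never respond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import ConfigError, SimulationConfig
from .containers import CountMatrix

# fixed per-operation RNG stream offsets
_STREAM_TRUTH = 11
_STREAM_CELLS = 23
_STREAM_HTO = 37
_STREAM_REGULATORY = 41
_STREAM_SUPPRESSION = 53

STAT_CONSENSUS = "TTCCAGGAA"  # STAT-family-like palindromic half-site consensus
DECOY_CONSENSUS = "TGACGTCA"  # bZIP-like decoy, planted uniformly at random


def _rng(config: SimulationConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), offset])


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted simulation parameters for recovery tests."""

    gene_ids: List[str]
    gene_module: pd.Series  # gene_id -> module label
    state_markers: Dict[str, List[str]]  # state -> marker genes
    mito_genes: List[str]
    anchor_gene: Optional[str]  # dose-proxy gene (first direct_activated gene)
    cells: pd.DataFrame  # cell_id, genotype, day, replicate, sample, state, proliferating
    log2fc_by_day: pd.DataFrame  # genes x days, planted degrader-vs-control log2 FC

    def true_log2fc(self, gene: str, state: str, day: int) -> float:
        """Planted base (non-proliferating) log2 FC; identical across states."""
        return float(self.log2fc_by_day.loc[gene, day])

    def module_genes(self, *labels: str) -> List[str]:
        mask = self.gene_module.isin(labels)
        return list(self.gene_module.index[mask])

    def to_json_dict(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "gene_module": self.gene_module.to_dict(),
            "state_markers": self.state_markers,
            "mito_genes": self.mito_genes,
            "anchor_gene": self.anchor_gene,
            "cells": self.cells.to_dict(orient="list"),
            "log2fc_by_day": {
                str(day): self.log2fc_by_day[day].tolist()
                for day in self.log2fc_by_day.columns
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        gene_ids = list(d["gene_ids"])
        lfc = pd.DataFrame(
            {int(day): vals for day, vals in d["log2fc_by_day"].items()},
            index=gene_ids,
        )
        return cls(
            gene_ids=gene_ids,
            gene_module=pd.Series(d["gene_module"]).reindex(gene_ids),
            state_markers={k: list(v) for k, v in d["state_markers"].items()},
            mito_genes=list(d["mito_genes"]),
            anchor_gene=d["anchor_gene"],
            cells=pd.DataFrame(d["cells"]),
            log2fc_by_day=lfc,
        )


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Assign gene modules, plant per-day effects and lay out the cells.

    Module assignment partitions the first sum(module_sizes) genes in the
    fixed order direct_activated, direct_repressed, indirect, null; any
    remaining genes are null. State-marker and mitochondrial gene subsets
    are carved deterministically out of the null module.
    """
    config.validate()
    rng = _rng(config, _STREAM_TRUTH)

    width = max(4, len(str(max(config.n_genes, 1))))
    gene_ids = [f"G{i:0{width}d}" for i in range(config.n_genes)]

    modules = np.array(["null"] * config.n_genes, dtype=object)
    pos = 0
    for label in ("direct_activated", "direct_repressed", "indirect", "null"):
        size = config.module_sizes.get(label, 0)
        modules[pos:pos + size] = label
        pos += size
    gene_module = pd.Series(modules, index=gene_ids, name="module")

    null_genes = [g for g, m in gene_module.items() if m == "null"]
    n_mark = config.n_state_marker_genes
    needed = 2 * n_mark + config.n_mito_genes
    if len(null_genes) < needed:
        raise ConfigError(
            f"null module ({len(null_genes)} genes) too small to host "
            f"{needed} marker/mito genes"
        )
    state_markers = {
        "resting": null_genes[:n_mark],
        "activated": null_genes[n_mark:2 * n_mark],
    }
    mito_genes = null_genes[len(null_genes) - config.n_mito_genes:]

    direct_act = [g for g, m in gene_module.items() if m == "direct_activated"]
    anchor_gene = direct_act[0] if direct_act else None

    # planted degrader-vs-control log2 effects per day
    lfc = pd.DataFrame(0.0, index=gene_ids, columns=list(config.days))
    day_effects = {3: config.effect_day3, 7: config.effect_day7}
    indirect_sign = 1
    for gene, module in gene_module.items():
        if module == "direct_activated":
            for day, eff in day_effects.items():
                if day in lfc.columns:
                    lfc.loc[gene, day] = -math.log2(eff)
        elif module == "direct_repressed":
            for day, eff in day_effects.items():
                if day in lfc.columns:
                    lfc.loc[gene, day] = math.log2(eff)
        elif module == "indirect":
            if 7 in lfc.columns:
                lfc.loc[gene, 7] = indirect_sign * 0.5 * math.log2(config.effect_day7)
            indirect_sign = -indirect_sign

    # cell layout: genotype x day x replicate, n_cells_per_group cells each
    rows = []
    idx = 0
    for day in config.days:
        for genotype in config.genotypes:
            for rep in range(1, config.n_replicates_per_genotype + 1):
                sample = f"{genotype}_d{day}_r{rep}"
                for _ in range(config.n_cells_per_group):
                    state = (
                        "activated"
                        if rng.random() < config.frac_activated
                        else "resting"
                    )
                    prolif = bool(
                        rng.random()
                        < config.frac_proliferating_given_state.get(state, 0.0)
                    )
                    rows.append((f"C{idx:06d}", genotype, day, rep, sample, state, prolif))
                    idx += 1
    cells = pd.DataFrame(
        rows,
        columns=["cell_id", "genotype", "day", "replicate", "sample", "state",
                 "proliferating"],
    )

    return GroundTruth(
        gene_ids=gene_ids,
        gene_module=gene_module,
        state_markers=state_markers,
        mito_genes=mito_genes,
        anchor_gene=anchor_gene,
        cells=cells,
        log2fc_by_day=lfc,
    )


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_cells(
    truth: GroundTruth, config: SimulationConfig
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Draw the cells x genes UMI count matrix.

    Counts are NB(mean = library-size-scaled gene baseline x state-marker
    effect x planted degradation effect, variance = mu + dispersion * mu^2).
    State-marker genes are up-weighted ``state_marker_fold``-fold in their
    own state and down-weighted by the same factor in the other, mimicking
    reciprocally regulated activation signatures. In proliferating cells of
    the degrader genotype the planted log2 effect is multiplied by
    ``proliferation_amplification``. Mitochondrial genes are re-weighted so
    they contribute ``mito_gene_frac`` of expected counts.
    """
    rng = _rng(config, _STREAM_CELLS)
    cells = truth.cells
    n_cells, n_genes = len(cells), len(truth.gene_ids)
    if n_cells == 0 or n_genes == 0:
        return (
            CountMatrix(sp.csr_matrix((n_cells, n_genes), dtype=np.int64),
                        list(cells["cell_id"]), truth.gene_ids),
            cells.copy().reset_index(drop=True),
        )

    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n_genes)

    gene_idx = {g: j for j, g in enumerate(truth.gene_ids)}
    if truth.anchor_gene is not None:
        # the dose-proxy anchor emulates Foxp3, which is highly expressed in
        # Treg cells; pin it near the top of the baseline distribution
        baseline[gene_idx[truth.anchor_gene]] = math.exp(1.5 * config.baseline_sigma)
    mito_idx = np.array([gene_idx[g] for g in truth.mito_genes], dtype=int)
    if mito_idx.size and 0 < config.mito_gene_frac < 1:
        non_mito = np.setdiff1d(np.arange(n_genes), mito_idx)
        target = (
            config.mito_gene_frac / (1 - config.mito_gene_frac)
            * baseline[non_mito].sum()
        )
        baseline[mito_idx] *= target / baseline[mito_idx].sum()

    weights = np.tile(baseline, (n_cells, 1))

    fold = config.state_marker_fold
    for state, markers in truth.state_markers.items():
        cols = np.array([gene_idx[g] for g in markers], dtype=int)
        if cols.size == 0:
            continue
        own = (cells["state"] == state).to_numpy()
        weights[np.ix_(own, cols)] *= fold
        weights[np.ix_(~own, cols)] /= fold

    # planted degradation effects in the degrader genotype
    degrader = (cells["genotype"] != config.genotypes[0]).to_numpy()
    amp = np.where(cells["proliferating"].to_numpy(), config.proliferation_amplification, 1.0)
    lfc = truth.log2fc_by_day  # genes x days
    for day in config.days:
        day_rows = degrader & (cells["day"] == day).to_numpy()
        if not day_rows.any():
            continue
        base = lfc[day].to_numpy()  # per-gene log2 effect
        cell_amp = amp[day_rows][:, None]
        weights[day_rows] *= np.exp2(base[None, :] * cell_amp)

    libsize = rng.lognormal(
        mean=math.log(config.libsize_mean) - config.libsize_sigma**2 / 2,
        sigma=config.libsize_sigma,
        size=n_cells,
    )
    mu = weights / weights.sum(axis=1, keepdims=True) * libsize[:, None]

    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    cm = CountMatrix(sp.csr_matrix(counts), list(cells["cell_id"]), truth.gene_ids)
    return cm, cells.copy().reset_index(drop=True)


# ---------------------------------------------------------------------------
# hashtag (HTO) counts
# ---------------------------------------------------------------------------

def simulate_hto(
    cell_meta: pd.DataFrame,
    config: SimulationConfig,
    sample_col: str = "sample",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate tag counts for one multiplexed pool of droplets.

    Each distinct sample in ``cell_meta[sample_col]`` is hashed with one
    tag. Singlet droplets get one high-mean tag, doublets two, negatives
    none; Poisson background counts sit on every tag. Returns the droplet x
    tag count table and the planted truth (true call and planted tag set).
    """
    config.validate()
    if config.doublet_rate + config.negative_rate > 1:
        raise ConfigError("doublet_rate + negative_rate must not exceed 1")
    rng = _rng(config, _STREAM_HTO)

    samples = sorted(cell_meta[sample_col].unique())
    if len(samples) > config.n_hto_tags:
        raise ConfigError(
            f"{len(samples)} samples cannot be hashed with {config.n_hto_tags} tags"
        )
    tag_of = {s: i for i, s in enumerate(samples)}
    tags = [f"HTO{i + 1}" for i in range(config.n_hto_tags)]

    n = len(cell_meta)
    counts = rng.poisson(config.hto_background_mean, size=(n, config.n_hto_tags))
    calls, planted = [], []
    for i, sample in enumerate(cell_meta[sample_col]):
        u = rng.random()
        own = tag_of[sample]
        if u < config.negative_rate:
            calls.append("negative")
            planted.append("")
        elif u < config.negative_rate + config.doublet_rate:
            other = int(rng.integers(config.n_hto_tags - 1))
            if other >= own:
                other += 1
            pos = sorted([own, other])
            counts[i, pos] += rng.poisson(config.hto_positive_mean, size=2)
            calls.append("doublet")
            planted.append(",".join(tags[t] for t in pos))
        else:
            counts[i, own] += rng.poisson(config.hto_positive_mean)
            calls.append(sample)
            planted.append(tags[own])

    hto = pd.DataFrame(counts, index=list(cell_meta["cell_id"]), columns=tags)
    hto.index.name = "cell_id"
    truth = pd.DataFrame(
        {
            "cell_id": list(cell_meta["cell_id"]),
            "true_call": calls,
            "planted_tags": planted,
        }
    )
    return hto, truth


# ---------------------------------------------------------------------------
# regulatory annotation
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryTruth:
    """Toy genome: gene loci, peaks, sequences and planted motifs."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, tss
    peaks: pd.DataFrame  # PEAK_COLUMNS plus source_gene
    sequences: Dict[str, str]  # peak_id -> DNA sequence
    planted_motifs: Dict[str, List[Tuple[str, int, str]]]  # peak_id -> (motif, offset, strand)
    pwms: list = field(default_factory=list)

    def gene_windows(self, halfwidth: int) -> pd.DataFrame:
        g = self.genes.copy()
        g["win_start"] = np.maximum(0, g["tss"] - halfwidth)
        g["win_end"] = g["tss"] + halfwidth
        return g


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


_BASES = np.array(list("ACGT"))


def consensus_pwm(motif_id: str, consensus: str, p_match: float = 0.91):
    """Near-deterministic PWM from a consensus string."""
    from .motifs import PWM

    mat = np.full((4, len(consensus)), (1 - p_match) / 3)
    for j, base in enumerate(consensus.upper()):
        mat["ACGT".index(base), j] = p_match
    return PWM(motif_id=motif_id, matrix=mat, background=np.full(4, 0.25))


def simulate_regulatory_annotation(
    truth: GroundTruth, config: SimulationConfig
) -> RegulatoryTruth:
    """Build the toy genome and its regulatory layer.

    Non-overlapping gene loci are laid along one chromosome. Open-chromatin
    (ATAC) peaks are placed within each gene's TSS window; peaks near
    direct-module genes are flagged TF-bound with probability
    ``foxp3_bound_frac_direct`` versus ``foxp3_bound_frac_other`` elsewhere
    (bound peaks are by construction a subset of open peaks). Histone
    signals are drawn per module: direct_activated peaks high H3K27ac / low
    H3K27me3 and direct_repressed the reverse. Random peak sequences carry a
    STAT-like consensus planted preferentially in bound peaks near
    direct_activated genes, plus a uniformly planted decoy motif.
    """
    if config.gene_locus_halfwidth <= 0:
        raise ConfigError("gene_locus_halfwidth must be positive")
    rng = _rng(config, _STREAM_REGULATORY)

    W = config.gene_locus_halfwidth
    spacing = 2 * W + 10_000
    gene_rows = []
    for i, gene in enumerate(truth.gene_ids):
        strand = "+" if i % 2 == 0 else "-"
        body_start = W + i * spacing
        body_end = body_start + 2_000
        gene_rows.append((gene, "chr1", body_start, body_end, strand))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)

    direct = set(truth.module_genes("direct_activated", "direct_repressed"))
    direct_act = set(truth.module_genes("direct_activated"))

    peak_rows, sequences, planted = [], {}, {}
    pid = 0
    R = min(config.peak_region_halfwidth, W - config.peak_width - 1)
    for grow in genes.itertuples(index=False):
        module = truth.gene_module[grow.gene_id]
        n_peaks = 1 + rng.poisson(config.mean_extra_peaks_per_gene)
        bound_p = (
            config.foxp3_bound_frac_direct
            if grow.gene_id in direct
            else config.foxp3_bound_frac_other
        )
        ac_mean, me3_mean = config.histone_means.get(module, (3.0, 3.0))
        for _ in range(n_peaks):
            start = int(rng.integers(grow.tss - R, grow.tss + R - config.peak_width))
            start = max(0, start)
            end = start + config.peak_width
            peak_id = f"peak{pid:06d}"
            pid += 1
            bound = bool(rng.random() < bound_p)
            ac = float(rng.lognormal(math.log(ac_mean), 0.25))
            me3 = float(rng.lognormal(math.log(me3_mean), 0.25))
            peak_rows.append(
                ("chr1", start, end, peak_id, 0, ".", True, bound, ac, me3,
                 grow.gene_id)
            )

            seq = _random_dna(rng, config.peak_seq_len)
            hits: List[Tuple[str, int, str]] = []
            plant_p = (
                config.motif_plant_prob_target
                if bound and grow.gene_id in direct_act
                else config.motif_plant_prob_background
            )
            if rng.random() < plant_p:
                off = int(rng.integers(0, config.peak_seq_len - len(STAT_CONSENSUS)))
                seq[off:off + len(STAT_CONSENSUS)] = [
                    "ACGT".index(b) for b in STAT_CONSENSUS
                ]
                hits.append(("STAT_like", off, "+"))
            if rng.random() < config.motif_plant_prob_background:
                w = len(DECOY_CONSENSUS)
                for _ in range(20):  # avoid overwriting an earlier plant
                    off = int(rng.integers(0, config.peak_seq_len - w))
                    if all(off + w <= o or off >= o + len(STAT_CONSENSUS)
                           for _, o, _ in hits):
                        seq[off:off + w] = ["ACGT".index(b) for b in DECOY_CONSENSUS]
                        hits.append(("bZIP_decoy", off, "+"))
                        break
            sequences[peak_id] = "".join(_BASES[seq])
            if hits:
                planted[peak_id] = hits

    peaks = pd.DataFrame(
        peak_rows,
        columns=["chrom", "start", "end", "peak_id", "score", "strand",
                 "atac_flag", "foxp3_flag", "h3k27ac", "h3k27me3", "source_gene"],
    )
    pwms = [
        consensus_pwm("STAT_like", STAT_CONSENSUS),
        consensus_pwm("bZIP_decoy", DECOY_CONSENSUS),
    ]
    return RegulatoryTruth(
        genes=genes, peaks=peaks, sequences=sequences,
        planted_motifs=planted, pwms=pwms,
    )


# ---------------------------------------------------------------------------
# suppression assay
# ---------------------------------------------------------------------------

def simulate_suppression_assay(config: SimulationConfig) -> pd.DataFrame:
    """Per-well divided fractions for a Treg:Tresponder titration.

    The no-Treg control divides around ``control_divided_mean``; a well at
    Treg ratio r has planted suppression ``suppression_max * r`` (linear
    titration), i.e. its mean divided fraction is control * (1 - S). Well
    noise is Beta-distributed with concentration ``well_concentration``.
    """
    rng = _rng(config, _STREAM_SUPPRESSION)
    conc = config.well_concentration

    def draw(mean: float) -> float:
        if mean <= 0.0:
            return 0.0
        if mean >= 1.0:
            return 1.0
        return float(rng.beta(mean * conc, (1 - mean) * conc))

    rows = []
    for well in range(1, config.n_wells + 1):
        rows.append(("noTreg", 0.0, well, draw(config.control_divided_mean), 0.0))
    for ratio in config.treg_ratios:
        s = config.suppression_max * ratio
        mean = config.control_divided_mean * (1 - s)
        for well in range(1, config.n_wells + 1):
            rows.append((f"Treg_1to{round(1 / ratio):d}", ratio, well, draw(mean), s))
    return pd.DataFrame(
        rows,
        columns=["condition", "treg_ratio", "well", "divided_fraction",
                 "planted_suppression"],
    )
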