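"""TF-binding-per-open-chromatin enrichment around gene groups.

The statistic normalizes TF (Foxp3) binding to chromatin accessibility:
open-chromatin (ATAC) peaks are assigned to every gene whose TSS window
(TSS +/- window, 0-based half-open) they intersect, and a gene group's
bound fraction is the pooled count of TF-bound peaks over the pooled count
of open peaks across its genes. Significance comes from a gene-label
permutation that preserves each gene's own peak structure — genes, not
peaks, are the sampled units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import FormatError

logger = logging.getLogger(__name__)


@dataclass
class PeakGeneMap:
    """Per-gene open/bound peak assignments within the TSS window."""

    window: int  # halfwidth in bp
    peaks_by_gene: Dict[str, List[str]]  # gene -> overlapping ATAC peak ids
    n_atac: pd.Series  # per-gene open peak count
    n_foxp3: pd.Series  # per-gene bound peak count

    def genes(self) -> List[str]:
        return list(self.n_atac.index)


def assign_peaks_to_genes(
    peaks: pd.DataFrame, genes: pd.DataFrame, window_kb: float = 50.0
) -> PeakGeneMap:
    """Map ATAC peaks to every gene window they intersect.

    A peak [start, end) maps to gene g iff it intersects [tss-w, tss+w)
    (both 0-based half-open); a peak may map to multiple genes. Only
    atac-flagged peaks are counted.
    """
    if window_kb <= 0:
        raise FormatError("window_kb must be positive")
    w = int(round(window_kb * 1000))
    atac = peaks[peaks["atac_flag"]]

    trees: Dict[str, IntervalTree] = {}
    for chrom, sub in atac.groupby("chrom"):
        tree = IntervalTree()
        for row in sub.itertuples(index=False):
            tree.addi(row.start, row.end, (row.peak_id, bool(row.foxp3_flag)))
        trees[chrom] = tree

    peaks_by_gene: Dict[str, List[str]] = {}
    n_atac, n_foxp3 = {}, {}
    for g in genes.itertuples(index=False):
        lo, hi = g.tss - w, g.tss + w
        hits = trees.get(g.chrom, IntervalTree()).overlap(lo, hi) if hi > lo else set()
        ids = sorted(h.data[0] for h in hits)
        peaks_by_gene[g.gene_id] = ids
        n_atac[g.gene_id] = len(ids)
        n_foxp3[g.gene_id] = sum(1 for h in hits if h.data[1])
    return PeakGeneMap(
        window=w,
        peaks_by_gene=peaks_by_gene,
        n_atac=pd.Series(n_atac, name="n_atac"),
        n_foxp3=pd.Series(n_foxp3, name="n_foxp3"),
    )


@dataclass
class GroupEnrichment:
    group: str
    n_genes: int
    total_atac: int
    total_foxp3: int
    bound_fraction: float  # pooled: sum n_foxp3 / sum n_atac
    per_gene_rate: pd.Series  # n_foxp3/n_atac for genes with peaks
    defined: bool = True


def group_bound_fraction(
    pgmap: PeakGeneMap, groups: Dict[str, Sequence[str]]
) -> Dict[str, GroupEnrichment]:
    """Pooled bound fraction and per-gene normalized rates per gene group."""
    out = {}
    for name, gene_list in groups.items():
        genes = [g for g in gene_list if g in pgmap.n_atac.index]
        if len(genes) < len(gene_list):
            logger.warning(
                "group %s: %d genes not in peak map, dropped",
                name, len(gene_list) - len(genes),
            )
        na = pgmap.n_atac.loc[genes]
        nf = pgmap.n_foxp3.loc[genes]
        total_a, total_f = int(na.sum()), int(nf.sum())
        with_peaks = na > 0
        rate = (nf[with_peaks] / na[with_peaks]).rename("rate")
        if total_a == 0:
            out[name] = GroupEnrichment(name, len(genes), 0, 0, np.nan, rate, defined=False)
        else:
            out[name] = GroupEnrichment(
                name, len(genes), total_a, total_f, total_f / total_a, rate
            )
    return out


def _pooled_fraction(na: np.ndarray, nf: np.ndarray, idx: np.ndarray) -> float:
    tot = na[idx].sum()
    return nf[idx].sum() / tot if tot > 0 else np.nan


def enrichment_test(
    pgmap: PeakGeneMap,
    focal_genes: Sequence[str],
    background_genes: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> Tuple[float, float, np.ndarray]:
    """One-sided gene-label permutation test of the pooled bound fraction.

    Draws |focal| genes from the background uniformly without replacement
    ``n_perm`` times, recomputes the pooled bound fraction each time, and
    returns (p, observed, null_fractions) with
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if not len(focal_genes):
        raise FormatError("focal group is empty")
    if n_perm < 100:
        raise FormatError("n_perm must be >= 100")
    if len(background_genes) < len(focal_genes):
        raise FormatError("background must be at least as large as the focal group")
    rng = np.random.default_rng(seed)

    genes = pgmap.n_atac.index
    na = pgmap.n_atac.to_numpy(dtype=float)
    nf = pgmap.n_foxp3.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    try:
        focal_idx = np.array([pos[g] for g in focal_genes])
        bg_idx = np.array([pos[g] for g in background_genes])
    except KeyError as exc:
        raise FormatError(f"gene {exc.args[0]!r} not in the peak map") from None

    observed = _pooled_fraction(na, nf, focal_idx)
    if np.isnan(observed):
        raise FormatError("focal group has no open-chromatin peaks")

    null = np.empty(n_perm)
    k = len(focal_idx)
    for b in range(n_perm):
        draw = rng.choice(bg_idx, size=k, replace=False)
        null[b] = _pooled_fraction(na, nf, draw)
    null = np.where(np.isnan(null), -np.inf, null)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return float(p), float(observed), null


def aggregate_signal_at_peaks(
    pgmap: PeakGeneMap,
    peaks: pd.DataFrame,
    groups: Dict[str, Sequence[str]],
    signal: str = "h3k27ac",
    bound_only: bool = True,
) -> pd.DataFrame:
    """Mean (and dispersion) of a histone signal over each group's peaks.

    With ``bound_only`` the average runs over TF-bound peaks only,
    mirroring signal profiles at bound open-chromatin sites near the
    response genes.
    """
    if signal not in ("h3k27ac", "h3k27me3"):
        raise FormatError(f"unknown signal {signal!r}")
    ptab = peaks.set_index("peak_id")
    rows = []
    for name, gene_list in groups.items():
        pids = sorted({p for g in gene_list for p in pgmap.peaks_by_gene.get(g, [])})
        sel = ptab.loc[pids]
        if bound_only:
            sel = sel[sel["foxp3_flag"]]
        vals = sel[signal].to_numpy()
        if vals.size == 0:
            rows.append((name, 0, np.nan, np.nan))
        else:
            rows.append((name, vals.size, float(vals.mean()), float(vals.std(ddof=0))))
    return pd.DataFrame(rows, columns=["group", "n_peaks", "mean_signal", "sd_signal"])
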