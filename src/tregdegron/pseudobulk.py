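"""Pseudo-bulk aggregation, differential expression, gene grouping and strata.

Cells are summed into pseudo-bulk samples keyed by replicate x genotype x
state x day (treating biological replicates, not cells, as the sampled
units). Differential expression between genotypes is a Welch two-sample
t-test on log2 CPM with pseudocount 1, Benjamini-Hochberg adjusted across
all tested genes of a contrast; the log2 fold change is the difference of
arm means on that scale, oriented degrader over control so that degradation
of an activator yields a negative value. Significant genes at day 7 are
grouped per state into TIR1-up (up in the degrader) and TIR1-down sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, FormatError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_pseudobulk(
    counts: CountMatrix,
    cell_meta: pd.DataFrame,
    keys: Sequence[str] = ("replicate", "genotype", "state", "day"),
) -> pd.DataFrame:
    """Sum raw counts into per-sample pseudo-bulk profiles.

    ``cell_meta`` must carry one row per cell (cell_id column) with values
    for every key; cells with an 'unassigned' state are excluded. Returns a
    samples x genes frame whose index is a MultiIndex over the keys.
    """
    meta = cell_meta.set_index("cell_id").reindex(counts.cell_ids)
    missing = [k for k in keys if k not in meta.columns]
    if missing:
        raise FormatError(f"cell metadata missing keys: {missing}")
    if meta[list(keys)].isna().any().any():
        raise FormatError("every cell needs a value for every aggregation key")

    include = np.ones(len(meta), dtype=bool)
    if "state" in keys:
        include &= (meta["state"] != "unassigned").to_numpy()

    codes, uniques = pd.factorize(
        pd.MultiIndex.from_frame(meta.loc[include, list(keys)]), sort=True
    )
    mat = counts.values[np.flatnonzero(include)]
    n_samples = len(uniques)
    onehot = np.zeros((n_samples, mat.shape[0]))
    onehot[codes, np.arange(mat.shape[0])] = 1.0
    sums = onehot @ mat.toarray()
    pb = pd.DataFrame(np.rint(sums).astype(np.int64), index=uniques, columns=counts.gene_ids)
    pb.index = pd.MultiIndex.from_tuples(pb.index, names=list(keys))
    empty = pb.sum(axis=1) == 0
    if empty.any():
        logger.warning("dropping %d empty pseudo-bulk samples", int(empty.sum()))
        pb = pb.loc[~empty]
    return pb


def size_factors(pb: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (robust to composition shifts).

    Per sample, the median over genes of count / geometric-mean count,
    computed over genes expressed in every sample. Total-count scaling is
    biased when a planted (or real) response module shifts the library
    composition; the median of ratios ignores the responding minority.
    """
    logs = np.log(pb.where(pb > 0))
    all_pos = logs.notna().all(axis=0)
    if not all_pos.any():
        # degenerate table: fall back to library-size scaling
        lib = pb.sum(axis=1).astype(float)
        return lib / lib.mean()
    log_gm = logs.loc[:, all_pos].mean(axis=0)
    sf = np.exp((logs.loc[:, all_pos] - log_gm).median(axis=1))
    return sf / sf.mean()


def log2cpm(pb: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2 of size-factor-normalized counts per million (+ pseudocount)."""
    sf = size_factors(pb)
    eff_lib = float((pb.sum(axis=1) / sf).mean())
    cpm = pb.div(sf, axis=0) / eff_lib * 1e6
    return np.log2(cpm + pseudocount)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    pb: pd.DataFrame,
    contrast_key: str = "genotype",
    reference: str = "control",
    treatment: str = "degrader",
) -> pd.DataFrame:
    """Welch t-test of treatment vs. reference pseudo-bulk samples per gene.

    Returns a DE table with gene_id, log2fc (treatment minus reference mean
    log2 CPM), p, BH-adjusted q, mean_logcpm and per-arm sample counts.
    Genes with zero variance in both arms and equal means get p = 1.
    """
    levels = pb.index.get_level_values(contrast_key)
    lc = log2cpm(pb)  # normalize jointly so size factors span both arms
    a = lc.loc[levels == reference]
    b = lc.loc[levels == treatment]
    if len(a) < 2 or len(b) < 2:
        raise FormatError(
            f"need >= 2 samples per arm, got {len(a)} {reference!r} / {len(b)} {treatment!r}"
        )

    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    lfc = mean_b - mean_a
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(b.to_numpy(), a.to_numpy(), axis=0, equal_var=False)
    p = np.asarray(p)

    var_a = a.var(axis=0, ddof=1).to_numpy()
    var_b = b.var(axis=0, ddof=1).to_numpy()
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        diff = lfc.to_numpy()[degenerate]
        p[np.flatnonzero(degenerate)[np.isclose(diff, 0)]] = 1.0
        p[np.flatnonzero(degenerate)[~np.isclose(diff, 0)]] = 0.0
        logger.info("%d genes had zero variance in both arms", int(degenerate.sum()))
    p = np.where(np.isnan(p), 1.0, p)

    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": pb.columns,
            "log2fc": lfc.to_numpy(),
            "p": p,
            "q": q,
            "mean_logcpm": (mean_a + mean_b).to_numpy() / 2,
            "n_reference": len(a),
            "n_treatment": len(b),
        }
    )


# ---------------------------------------------------------------------------
# gene groups
# ---------------------------------------------------------------------------

@dataclass
class GeneGroups:
    """Degradation-response gene sets per state ('TIR1' = the degrader arm)."""

    resting_TIR1_up: List[str] = field(default_factory=list)
    resting_TIR1_down: List[str] = field(default_factory=list)
    activated_TIR1_up: List[str] = field(default_factory=list)
    activated_TIR1_down: List[str] = field(default_factory=list)

    def by_state(self, state: str) -> Dict[str, List[str]]:
        return {
            "TIR1_up": getattr(self, f"{state}_TIR1_up"),
            "TIR1_down": getattr(self, f"{state}_TIR1_down"),
        }

    def to_dict(self) -> Dict[str, List[str]]:
        return {
            "resting_TIR1_up": self.resting_TIR1_up,
            "resting_TIR1_down": self.resting_TIR1_down,
            "activated_TIR1_up": self.activated_TIR1_up,
            "activated_TIR1_down": self.activated_TIR1_down,
        }


def classify_gene_groups(
    de_by_state: Dict[str, pd.DataFrame],
    q_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
) -> GeneGroups:
    """Group significant day-7 genes into per-state TIR1-up/-down sets.

    ``de_by_state`` maps 'resting'/'activated' to that state's day-7 DE
    table. A gene is TIR1-up in a state iff q < q_threshold and
    log2fc > lfc_threshold there; TIR1-down symmetrically.
    """
    groups = GeneGroups()
    for state, de in de_by_state.items():
        if state not in ("resting", "activated"):
            raise FormatError(f"unknown state {state!r}")
        sig = de["q"] < q_threshold
        up = de.loc[sig & (de["log2fc"] > lfc_threshold), "gene_id"].tolist()
        down = de.loc[sig & (de["log2fc"] < -lfc_threshold), "gene_id"].tolist()
        setattr(groups, f"{state}_TIR1_up", up)
        setattr(groups, f"{state}_TIR1_down", down)
    return groups


# ---------------------------------------------------------------------------
# cross-condition comparisons
# ---------------------------------------------------------------------------

def logfc_correlation(
    de_a: pd.DataFrame, de_b: pd.DataFrame, gene_subset: Optional[Sequence[str]] = None
) -> float:
    """Pearson r of per-gene log2 fold changes shared by two DE tables."""
    a = de_a.set_index("gene_id")["log2fc"]
    b = de_b.set_index("gene_id")["log2fc"]
    shared = a.index.intersection(b.index)
    if gene_subset is not None:
        shared = shared.intersection(pd.Index(gene_subset))
    if len(shared) < 3:
        raise FormatError("need >= 3 shared genes for a correlation")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise FormatError("zero variance makes the correlation undefined")
    return float(stats.pearsonr(x, y)[0])


def logfc_slope(
    de_a: pd.DataFrame, de_b: pd.DataFrame, gene_subset: Sequence[str]
) -> float:
    """Least-squares slope of de_b log2FC regressed on de_a log2FC."""
    a = de_a.set_index("gene_id")["log2fc"]
    b = de_b.set_index("gene_id")["log2fc"]
    shared = a.index.intersection(b.index).intersection(pd.Index(gene_subset))
    if len(shared) < 3:
        raise FormatError("need >= 3 shared genes for a slope")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    return float(stats.linregress(x, y).slope)


# ---------------------------------------------------------------------------
# p-value strata
# ---------------------------------------------------------------------------

def stratify_by_pvalue(
    de: pd.DataFrame, top_k: int = 50, n_quantile_bins: int = 4
) -> pd.DataFrame:
    """Stratify tested genes by significance within each fold-change direction.

    Within each direction (up: log2fc > 0; down: log2fc <= 0) genes are
    ranked by ascending p, ties broken by descending |log2fc| then gene id.
    The first ``top_k`` genes form the 'top' stratum; the remainder is cut
    into ``n_quantile_bins`` equal-occupancy rank bins labelled q1..qN.
    Every tested gene receives exactly one stratum in its direction.
    """
    if "p" not in de.columns:
        raise FormatError("DE table has no p-value column")
    out = []
    for direction, sub in (
        ("up", de[de["log2fc"] > 0]),
        ("down", de[de["log2fc"] <= 0]),
    ):
        if sub.empty:
            continue
        sub = sub.assign(abs_lfc=sub["log2fc"].abs())
        sub = sub.sort_values(
            ["p", "abs_lfc", "gene_id"], ascending=[True, False, True], kind="stable"
        ).reset_index(drop=True)
        k = min(top_k, len(sub))
        strata = np.empty(len(sub), dtype=object)
        strata[:k] = "top"
        n_rest = len(sub) - k
        if n_rest > 0:
            edges = np.linspace(0, n_rest, n_quantile_bins + 1).astype(int)
            for b in range(n_quantile_bins):
                strata[k + edges[b]:k + edges[b + 1]] = f"q{b + 1}"
        out.append(
            pd.DataFrame(
                {
                    "gene_id": sub["gene_id"],
                    "direction": direction,
                    "stratum": strata,
                    "rank": np.arange(1, len(sub) + 1),
                }
            )
        )
    return pd.concat(out, ignore_index=True)
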