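"""Signature scoring, cell-state gating, meta-cells and composition summaries.

The signature score of a cell is the mean normalized expression of the
signature genes minus the mean of a size-matched, expression-bin-matched
background gene set: genes are binned by their mean expression across cells
and for each signature gene ``ctrl_size`` control genes are sampled (without
the signature genes) from its bin, so a random gene set scores ~0.

Cells are classified resting/activated by exceeding exactly one of the two
signature thresholds; exceeding both or neither leaves the cell unassigned.

Meta-cells are built within (sample x state) strata: cells are embedded by
the top principal components of the most variable genes and partitioned by
k-means with k = ceil(n / target_size); each meta-cell is represented by
its mean normalized expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix, FormatError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# signature scoring
# ---------------------------------------------------------------------------

def signature_score(
    norm_expr: ExpressionMatrix,
    signature: Sequence[str],
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Background-matched signature score per cell.

    Signature genes absent from the matrix are dropped with a warning; an
    empty intersection is an error.
    """
    present = [g for g in signature if g in set(norm_expr.gene_ids)]
    dropped = len(signature) - len(present)
    if dropped:
        logger.warning("%d signature genes absent from matrix, dropped", dropped)
    if not present:
        raise FormatError("no signature gene is present in the matrix")

    rng = np.random.default_rng(seed)
    dense = norm_expr.to_dense()
    gene_means = dense.mean(axis=0)

    order = np.argsort(gene_means, kind="stable")
    n_genes = len(order)
    bin_of = np.empty(n_genes, dtype=int)
    # equal-occupancy bins over the expression ranking
    edges = np.linspace(0, n_genes, n_bins + 1).astype(int)
    for b in range(n_bins):
        bin_of[order[edges[b]:edges[b + 1]]] = b

    sig_idx = norm_expr.gene_index(present)
    sig_set = set(sig_idx.tolist())
    ctrl_idx: List[int] = []
    for gi in sig_idx:
        pool = np.flatnonzero((bin_of == bin_of[gi]))
        pool = pool[~np.isin(pool, list(sig_set))]
        if pool.size == 0:
            continue
        take = min(ctrl_size, pool.size)
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl_idx:
        raise FormatError("no control genes available outside the signature")

    score = dense[:, sig_idx].mean(axis=1) - dense[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=norm_expr.cell_ids, name="score")


def classify_states(
    score_rest: pd.Series,
    score_act: pd.Series,
    thresholds: Tuple[float, float] = (0.0, 0.0),
) -> pd.Series:
    """Call resting/activated/unassigned from two signature score vectors.

    resting iff score_rest > tau_rest and score_act <= tau_act; activated
    symmetrically; cells exceeding both thresholds or neither are
    unassigned.
    """
    if not score_rest.index.equals(score_act.index):
        score_act = score_act.reindex(score_rest.index)
        if score_act.isna().any():
            raise FormatError("score vectors are not aligned on the same cells")
    tau_rest, tau_act = thresholds
    rest_hi = score_rest > tau_rest
    act_hi = score_act > tau_act
    state = np.where(
        rest_hi & ~act_hi, "resting",
        np.where(act_hi & ~rest_hi, "activated", "unassigned"),
    )
    return pd.Series(state, index=score_rest.index, name="state")


# ---------------------------------------------------------------------------
# meta-cells
# ---------------------------------------------------------------------------

@dataclass
class MetaCell:
    metacell_id: str
    member_cells: List[str]
    mean_expression: np.ndarray  # per-gene mean normalized expression

    @property
    def size(self) -> int:
        return len(self.member_cells)


def build_metacells(
    norm_expr: ExpressionMatrix,
    groups: pd.Series,
    target_size: int = 20,
    n_pcs: int = 10,
    n_hvg: int = 500,
    seed: int = 0,
) -> List[MetaCell]:
    """Partition cells into meta-cells of roughly ``target_size`` members.

    ``groups`` maps each cell to its stratum (typically sample x state);
    partitioning never crosses strata. A stratum smaller than the target
    size becomes a single meta-cell.
    """
    if target_size < 2:
        raise FormatError("target_size must be >= 2")
    groups = groups.reindex(norm_expr.cell_ids)
    if groups.isna().any():
        raise FormatError("every cell needs a stratum label")
    dense = norm_expr.to_dense()

    variances = dense.var(axis=0)
    hvg = np.argsort(variances, kind="stable")[::-1][: min(n_hvg, dense.shape[1])]

    metacells: List[MetaCell] = []
    for stratum in sorted(groups.unique()):
        rows = np.flatnonzero((groups == stratum).to_numpy())
        n = rows.size
        k = max(1, int(np.ceil(n / target_size)))
        if n < target_size:
            logger.info("stratum %s has %d < %d cells; single meta-cell", stratum, n, target_size)
            k = 1
        if k == 1 or n <= k:
            labels = np.zeros(n, dtype=int) if k == 1 else np.arange(n)
        else:
            x = dense[np.ix_(rows, hvg)]
            n_comp = int(min(n_pcs, n - 1, x.shape[1]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                emb = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
                labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb)
        for lab in np.unique(labels):
            members = rows[labels == lab]
            metacells.append(
                MetaCell(
                    metacell_id=f"{stratum}|mc{lab}",
                    member_cells=[norm_expr.cell_ids[i] for i in members],
                    mean_expression=dense[members].mean(axis=0),
                )
            )
    return metacells


def metacell_expression(
    metacells: Sequence[MetaCell], gene_ids: Sequence[str]
) -> pd.DataFrame:
    """Meta-cell x gene mean-expression table."""
    return pd.DataFrame(
        np.vstack([m.mean_expression for m in metacells]),
        index=[m.metacell_id for m in metacells],
        columns=list(gene_ids),
    )


def metacell_score(
    metacells: Sequence[MetaCell],
    gene_ids: Sequence[str],
    signature: Sequence[str],
) -> pd.Series:
    """Mean expression of a signature per meta-cell (dose-response readout)."""
    expr = metacell_expression(metacells, gene_ids)
    present = [g for g in signature if g in expr.columns]
    if not present:
        raise FormatError("no signature gene is present")
    return expr[present].mean(axis=1)


def metacell_dose_correlation(
    metacells: Sequence[MetaCell],
    gene_ids: Sequence[str],
    anchor_gene: str,
    signature_scores: pd.Series,
) -> Tuple[float, float]:
    """Pearson correlation of meta-cell anchor expression vs. signature score."""
    if len(metacells) < 3:
        raise FormatError("need >= 3 meta-cells for a correlation")
    expr = metacell_expression(metacells, gene_ids)
    if anchor_gene not in expr.columns:
        raise KeyError(f"anchor gene {anchor_gene!r} not present")
    anchor = expr[anchor_gene]
    scores = signature_scores.reindex(anchor.index)
    if scores.isna().any():
        raise FormatError("signature scores not aligned with meta-cells")
    if np.isclose(anchor.std(ddof=0), 0) or np.isclose(scores.std(ddof=0), 0):
        raise FormatError("zero variance makes the correlation undefined")
    r, p = stats.pearsonr(anchor.to_numpy(), scores.to_numpy())
    return float(r), float(p)


# ---------------------------------------------------------------------------
# cluster composition
# ---------------------------------------------------------------------------

def cluster_composition(
    cell_meta: pd.DataFrame,
    cluster_col: str = "cluster",
    group_cols: Sequence[str] = ("genotype", "day"),
) -> pd.DataFrame:
    """Per-cluster fraction of cells by group; rows sum to 1."""
    if cluster_col not in cell_meta.columns:
        raise FormatError(f"missing cluster column {cluster_col!r}")
    counts = (
        cell_meta.groupby([cluster_col, *group_cols], observed=True)
        .size()
        .unstack(list(group_cols), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)
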