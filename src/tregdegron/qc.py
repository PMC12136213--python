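"""Cell/gene QC filters, median normalization and hashtag demultiplexing.

Filters follow the stated boundary semantics exactly: cells with *fewer
than* ``min_umi`` UMIs or detected genes, or *more than* ``max_mito_frac``
mitochondrial counts, are removed (a cell exactly at a threshold is
retained); genes detected in *more than* ``min_cells_per_gene`` cells are
retained. Cell filtering precedes gene filtering, so gene detection is
counted over the retained cells.

The demultiplexer partitions ln(1+count) values of each tag into a
background (lower-mean) and a positive (higher-mean) component with an
exact one-dimensional two-means: the globally optimal split of the sorted
values is found by scanning every boundary between distinct values, which
makes the solver deterministic and oracle-checkable. Droplets positive for
exactly one tag are singlets assigned to that tag's sample; multiple
positives make a doublet, none a negative.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import QCThresholds
from .containers import CountMatrix, ExpressionMatrix, FormatError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_cells(
    counts: CountMatrix,
    mito_genes: Sequence[str],
    thresholds: QCThresholds = QCThresholds(),
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Remove low-quality cells; report each removal with its first violated rule.

    Rules are checked in the order umi -> genes -> mito and the report
    attributes each removed cell to the first rule it violates.
    """
    if counts.n_cells == 0:
        raise FormatError("cannot QC an empty count matrix")
    unknown = set(mito_genes) - set(counts.gene_ids)
    if unknown:
        raise FormatError(f"mito genes absent from matrix: {sorted(unknown)[:5]}")

    total = np.asarray(counts.values.sum(axis=1)).ravel().astype(float)
    n_detected = np.asarray((counts.values > 0).sum(axis=1)).ravel()
    if mito_genes:
        mito_cols = counts.gene_index(list(mito_genes))
        mito_total = np.asarray(counts.values[:, mito_cols].sum(axis=1)).ravel()
    else:
        mito_total = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 1.0)

    fail_umi = total < thresholds.min_umi
    fail_genes = n_detected < thresholds.min_genes
    fail_mito = mito_frac > thresholds.max_mito_frac
    removed = fail_umi | fail_genes | fail_mito

    reasons = np.full(counts.n_cells, "", dtype=object)
    reasons[fail_mito] = "mito_frac"
    reasons[fail_genes] = "low_genes"
    reasons[fail_umi] = "low_umi"  # highest precedence written last

    report = pd.DataFrame(
        {
            "cell_id": [counts.cell_ids[i] for i in np.flatnonzero(removed)],
            "reason": reasons[removed],
            "total_umi": total[removed].astype(int),
            "n_genes": n_detected[removed],
            "mito_frac": mito_frac[removed],
        }
    )
    kept = counts.subset_cells(~removed)
    if kept.n_cells == 0:
        logger.warning("all %d cells removed by QC", counts.n_cells)
    return kept, report


def filter_genes(
    counts: CountMatrix, thresholds: QCThresholds = QCThresholds()
) -> CountMatrix:
    """Keep genes detected (count > 0) in more than ``min_cells_per_gene`` cells."""
    if counts.n_cells == 0:
        raise FormatError("cannot filter genes of an empty matrix")
    detected_in = np.asarray((counts.values > 0).sum(axis=0)).ravel()
    return counts.subset_genes(detected_in > thresholds.min_cells_per_gene)


def normalize_counts(counts: CountMatrix) -> ExpressionMatrix:
    """Scale each cell to the median per-cell total, then ln(1 + x)."""
    total = np.asarray(counts.values.sum(axis=1)).ravel().astype(float)
    if np.any(total == 0):
        bad = counts.cell_ids[int(np.argmax(total == 0))]
        raise FormatError(f"cell {bad!r} has zero total counts; filter first")
    median = float(np.median(total))
    mat = counts.values.astype(float).tocsr(copy=True)
    scale = median / total
    mat = mat.multiply(scale[:, None]).tocsr()
    mat.data = np.log1p(mat.data)
    return ExpressionMatrix(mat, counts.cell_ids, counts.gene_ids)


# ---------------------------------------------------------------------------
# exact 1-D two-means
# ---------------------------------------------------------------------------

def two_means_split(values: np.ndarray) -> float | None:
    """Optimal 1-D two-means threshold, or None for a degenerate input.

    Scans every boundary between distinct sorted values and returns the
    midpoint of the boundary minimizing the within-cluster sum of squares.
    Values strictly above the returned threshold belong to the higher-mean
    component. All-identical input (no valid split) returns None.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2 or v[0] == v[-1]:
        return None
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    k = np.arange(1, n)  # left cluster = v[:k]
    left_ss = csq[k - 1] - csum[k - 1] ** 2 / k
    right_sum = csum[-1] - csum[k - 1]
    right_sq = csq[-1] - csq[k - 1]
    right_ss = right_sq - right_sum**2 / (n - k)
    cost = left_ss + right_ss
    # only boundaries between distinct values are admissible
    valid = v[k] > v[k - 1]
    cost[~valid] = np.inf
    best = int(np.argmin(cost))
    return float((v[best] + v[best + 1]) / 2)


def kmeans_demux(
    hto: pd.DataFrame, tag_to_sample: Dict[str, str] | None = None
) -> pd.DataFrame:
    """Demultiplex droplets from hashtag counts.

    ``hto`` is a droplets x tags table of non-negative integer counts
    (droplet ids in the index). Per tag, ln(1+count) values are split by the
    exact two-means; droplets in the higher-mean component are positive for
    that tag. Returns a table with columns cell_id, call, n_positive,
    positive_tags plus per-tag background/positive component means.
    """
    if hto.shape[0] < 2 or hto.shape[1] < 1:
        raise FormatError("demultiplexing needs >= 2 droplets and >= 1 tag")
    counts = hto.to_numpy()
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise FormatError("HTO counts must be non-negative integers")

    logged = np.log1p(counts.astype(float))
    positive = np.zeros(hto.shape, dtype=bool)
    comp_means = {}
    for j, tag in enumerate(hto.columns):
        thr = two_means_split(logged[:, j])
        if thr is None:
            logger.info("tag %s has no positive component (degenerate split)", tag)
            comp_means[tag] = (float(logged[:, j].mean()), np.nan)
            continue
        pos = logged[:, j] > thr
        positive[:, j] = pos
        comp_means[tag] = (float(logged[~pos, j].mean()), float(logged[pos, j].mean()))

    tags = list(hto.columns)
    calls, pos_tags = [], []
    for i in range(hto.shape[0]):
        hits = [tags[j] for j in np.flatnonzero(positive[i])]
        if len(hits) == 0:
            calls.append("negative")
        elif len(hits) == 1:
            tag = hits[0]
            calls.append(tag_to_sample.get(tag, tag) if tag_to_sample else tag)
        else:
            calls.append("doublet")
        pos_tags.append(",".join(hits))

    out = pd.DataFrame(
        {
            "cell_id": list(hto.index),
            "call": calls,
            "n_positive": positive.sum(axis=1),
            "positive_tags": pos_tags,
        }
    )
    out.attrs["component_means"] = comp_means
    return out
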