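"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when on-disk data or a container violates its invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


class ExpressionMatrix:
    """Cells x genes expression values with aligned identifier vectors.

    ``values`` is kept as a CSR sparse matrix; rows are cells, columns are
    genes (the convention of a cells-by-genes counts matrix).
    """

    def __init__(self, values, cell_ids: Sequence[str], gene_ids: Sequence[str]):
        values = sp.csr_matrix(values)
        cell_ids = [str(c) for c in cell_ids]
        gene_ids = [str(g) for g in gene_ids]
        if values.shape != (len(cell_ids), len(gene_ids)):
            raise FormatError(
                f"matrix shape {values.shape} does not match "
                f"{len(cell_ids)} cell ids x {len(gene_ids)} gene ids"
            )
        _check_unique(cell_ids, "cell")
        _check_unique(gene_ids, "gene")
        self.values = values
        self.cell_ids: List[str] = cell_ids
        self.gene_ids: List[str] = gene_ids

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return type(self)(
            self.values[idx],
            [self.cell_ids[i] for i in idx],
            self.gene_ids,
        )

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return type(self)(
            self.values[:, idx],
            self.cell_ids,
            [self.gene_ids[i] for i in idx],
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.cell_ids, columns=self.gene_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.cell_ids == other.cell_ids
            and self.gene_ids == other.gene_ids
            and self.shape == other.shape
            and (self.values != other.values).nnz == 0
        )

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.n_cells} cells x {self.n_genes} genes>"


class CountMatrix(ExpressionMatrix):
    """Raw UMI counts: entries must be non-negative integers."""

    def __init__(self, values, cell_ids, gene_ids):
        super().__init__(values, cell_ids, gene_ids)
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                j = int(np.argmax(data < 0))
                raise FormatError(f"negative count entry: {data[j]!r}")
            if not np.allclose(data, np.round(data)):
                j = int(np.argmax(~np.isclose(data, np.round(data))))
                raise FormatError(f"non-integer count entry: {data[j]!r}")
        self.values = self.values.astype(np.int64)
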