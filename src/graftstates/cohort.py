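"""Single-cell count cohorts and log-normalization.

A :class:`CellCohort` holds a sparse cells x genes count matrix together
with the per-cell cluster / sample / group labels that every downstream
stage (differential expression, marker selection) conditions on.
Clustering itself is taken as given: the labels are inputs, not outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CellCohort", "LogNormMatrix", "lognormalize"]


@dataclass
class CellCohort:
    """Sparse nonnegative-integer counts with per-cell labels.

    Parameters
    ----------
    counts
        ``cells x genes`` sparse matrix of raw counts.
    genes, cells
        Unique identifiers for columns and rows.
    obs
        Per-cell metadata indexed like ``cells`` with columns
        ``cluster``, ``sample`` and ``group``.
    """

    counts: sp.spmatrix
    genes: pd.Index
    cells: pd.Index
    obs: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if not self.genes.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.cells.is_unique:
            raise ValueError("cell ids must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        missing = {"cluster", "sample", "group"} - set(self.obs.columns)
        if missing:
            raise ValueError(f"obs is missing label columns: {sorted(missing)}")
        if not self.obs.index.equals(self.cells):
            self.obs = self.obs.reindex(self.cells)
            if self.obs[["cluster", "sample", "group"]].isna().any().any():
                raise ValueError("every cell needs cluster, sample and group labels")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def cells_in_cluster(self, cluster: str) -> pd.Index:
        return self.cells[(self.obs["cluster"] == cluster).to_numpy()]

    def cell_positions(self, cell_ids) -> np.ndarray:
        """Integer row positions for a set of cell ids (order preserved)."""
        idx = self.cells.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            unknown = list(pd.Index(cell_ids)[idx < 0][:5])
            raise KeyError(f"unknown cell ids: {unknown}")
        return idx


@dataclass
class LogNormMatrix:
    """Natural-log of 1 + depth-scaled counts; sparse zeros preserved."""

    values: sp.spmatrix
    genes: pd.Index
    cells: pd.Index
    scale: float = 1e4
    obs: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)

    def dense(self, cell_positions=None, gene_positions=None) -> np.ndarray:
        v = self.values
        if cell_positions is not None:
            v = v[cell_positions]
        if gene_positions is not None:
            v = v[:, gene_positions]
        return np.asarray(v.todense())

    def cell_positions(self, cell_ids) -> np.ndarray:
        idx = self.cells.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            unknown = list(pd.Index(cell_ids)[idx < 0][:5])
            raise KeyError(f"unknown cell ids: {unknown}")
        return idx


def lognormalize(cohort: CellCohort, scale: float = 1e4) -> LogNormMatrix:
    """Depth-normalize and log-transform counts.

    ``value[c, g] = ln(1 + scale * count[c, g] / total[c])``.  Cells with
    zero total count are rejected (their normalization is undefined).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = np.asarray(cohort.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = list(cohort.cells[totals == 0][:10])
        raise ValueError(f"cells with zero total count: {bad}")
    mat = sp.csr_matrix(cohort.counts, dtype=np.float64, copy=True)
    row_scale = scale / totals
    # scale each row, then log1p the stored (nonzero) entries only
    mat.data *= np.repeat(row_scale, np.diff(mat.indptr))
    np.log1p(mat.data, out=mat.data)
    return LogNormMatrix(
        values=mat, genes=cohort.genes, cells=cohort.cells, scale=scale, obs=cohort.obs
    )
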