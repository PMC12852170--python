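"""Marker-gene selection for an injured target population (TP).

Four steps produce a highly specific marker set for one cluster:

1. candidate generation — differential expression of the TP against all
   other cells, keeping upregulated genes under the standard filters;
2. adjacent filter — keep genes whose mean expression in the TP strictly
   exceeds the mean in the adjacent injury population of the same cell
   type (e.g. the h1 state when targeting h2);
3. neighborhood construction — k-cell neighborhoods of nearest neighbors
   (seed included) around every cell outside the TP, in a PCA embedding
   of log-normalized expression, discarding neighborhoods that overlap
   the TP;
4. specificity filter — keep genes whose TP mean exceeds ``fold`` times
   the largest mean across all retained neighborhoods.

Means are taken on ``expm1``-back-transformed normalized values, the same
convention as the DE fold-changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .cohort import CellCohort, LogNormMatrix, lognormalize
from .dge import wilcoxon_de, apply_de_filters

__all__ = [
    "MarkerQuery",
    "NeighborhoodSet",
    "MarkerSet",
    "candidate_markers",
    "adjacent_filter",
    "build_neighborhoods",
    "neighborhood_specificity_filter",
    "select_markers",
]


@dataclass
class MarkerQuery:
    """Parameters of one marker-selection run."""

    target: str
    adjacent: str
    fold_threshold: float = 1.25
    k: int = 100
    n_pcs: int = 30
    min_abs_log2fc: float = 1.0
    max_padj: float = 0.05
    min_frac: float = 0.10
    #: "max" compares the TP mean against the largest neighborhood mean
    #: (strictest reading); "mean" against the mean of neighborhood means.
    neighborhood_reference: str = "max"

    def __post_init__(self) -> None:
        if self.target == self.adjacent:
            raise ValueError("target and adjacent clusters must differ")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.fold_threshold <= 1:
            raise ValueError("fold threshold must exceed 1")
        if self.neighborhood_reference not in {"max", "mean"}:
            raise ValueError("neighborhood_reference must be 'max' or 'mean'")


@dataclass
class NeighborhoodSet:
    """k-nearest-neighbor neighborhoods around every non-TP seed cell.

    ``members[i]`` holds the row positions (into the cohort's cell axis)
    of the k members of the neighborhood seeded at ``seed_positions[i]``;
    ``overlaps_tp[i]`` is True when any member lies in the TP.
    """

    seed_positions: np.ndarray
    members: np.ndarray  # (n_seeds, k) int
    overlaps_tp: np.ndarray  # (n_seeds,) bool
    k: int
    embedding: np.ndarray = field(repr=False, default=None)

    @property
    def retained(self) -> np.ndarray:
        """Member rows of the neighborhoods that do not touch the TP."""
        return self.members[~self.overlaps_tp]


@dataclass
class MarkerSet:
    """A named marker gene set with its selection audit trail."""

    name: str
    genes: list[str]
    audit: pd.DataFrame
    fold_threshold: float
    k: int

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def _mean_linear(norm: LogNormMatrix, positions: np.ndarray, gene_pos: np.ndarray):
    vals = norm.dense(positions, gene_pos)
    return np.expm1(vals).mean(axis=0)


def candidate_markers(
    query: MarkerQuery, cohort: CellCohort, norm: LogNormMatrix | None = None
) -> list[str]:
    """Step 1: genes upregulated in the TP versus all other cells."""
    if norm is None:
        norm = lognormalize(cohort)
    tp_cells = cohort.cells_in_cluster(query.target)
    if len(tp_cells) == 0:
        raise ValueError(f"target population {query.target!r} has no cells")
    rest = cohort.cells.difference(tp_cells, sort=False)
    de = wilcoxon_de(norm, tp_cells, rest, group_a=query.target, group_b="rest")
    table = apply_de_filters(
        de,
        min_abs_log2fc=query.min_abs_log2fc,
        max_padj=query.max_padj,
        min_frac=query.min_frac,
    )
    return list(table.index[table["direction"] > 0])


def adjacent_filter(
    genes: list[str],
    query: MarkerQuery,
    cohort: CellCohort,
    norm: LogNormMatrix,
) -> list[str]:
    """Step 2: require strictly higher TP mean than the adjacent cluster."""
    if not genes:
        return []
    adj_cells = cohort.cells_in_cluster(query.adjacent)
    if len(adj_cells) == 0:
        raise ValueError(f"adjacent population {query.adjacent!r} has no cells")
    tp_pos = cohort.cell_positions(cohort.cells_in_cluster(query.target))
    adj_pos = cohort.cell_positions(adj_cells)
    gene_pos = norm.genes.get_indexer(pd.Index(genes))
    tp_mean = _mean_linear(norm, tp_pos, gene_pos)
    adj_mean = _mean_linear(norm, adj_pos, gene_pos)
    return [g for g, t, a in zip(genes, tp_mean, adj_mean) if t > a]


def pca_embedding(norm: LogNormMatrix, n_pcs: int, random_state: int = 0) -> np.ndarray:
    """PCA of the dense log-normalized matrix (deterministic)."""
    dense = norm.dense()
    n_pcs = min(n_pcs, min(dense.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=random_state)
    return pca.fit_transform(dense)


def build_neighborhoods(
    query: MarkerQuery,
    cohort: CellCohort,
    norm: LogNormMatrix,
    embedding: np.ndarray | None = None,
) -> NeighborhoodSet:
    """Step 3: k-cell neighborhoods around each non-TP seed.

    Neighborhoods are the seed's ``k`` nearest cells (seed included,
    Euclidean distance in the embedding, distance ties broken by
    ascending cell position) drawn from *all* cells, so a neighborhood
    can reach into the TP — those are flagged and later excluded.
    """
    n = cohort.n_cells
    if n < query.k:
        raise ValueError(f"cohort has {n} cells, fewer than k={query.k}")
    if embedding is None:
        embedding = pca_embedding(norm, query.n_pcs)
    tp_mask = (cohort.obs["cluster"] == query.target).to_numpy()
    seeds = np.flatnonzero(~tp_mask)
    if seeds.size == 0:
        raise ValueError("no cells outside the target population")

    k = query.k
    members = np.empty((seeds.size, k), dtype=np.intp)
    cell_order = np.arange(n)
    sq_norms = (embedding**2).sum(axis=1)
    chunk = max(1, int(2e7 // n))
    for start in range(0, seeds.size, chunk):
        sub = seeds[start : start + chunk]
        d2 = (
            sq_norms[sub][:, None]
            - 2.0 * embedding[sub] @ embedding.T
            + sq_norms[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(sub.size), sub] = 0.0  # exact zero for the seed itself
        for i in range(sub.size):
            order = np.lexsort((cell_order, d2[i]))
            members[start + i] = order[:k]
    overlaps = tp_mask[members].any(axis=1)
    return NeighborhoodSet(
        seed_positions=seeds,
        members=members,
        overlaps_tp=overlaps,
        k=k,
        embedding=embedding,
    )


def neighborhood_specificity_filter(
    genes: list[str],
    neighborhoods: NeighborhoodSet,
    query: MarkerQuery,
    cohort: CellCohort,
    norm: LogNormMatrix,
    set_name: str | None = None,
) -> MarkerSet:
    """Step 4: TP mean must exceed ``fold`` x every neighborhood mean."""
    retained = neighborhoods.members[~neighborhoods.overlaps_tp]
    if retained.shape[0] == 0:
        raise ValueError(
            "every neighborhood overlaps the target population; "
            "consider a smaller k"
        )
    name = set_name or query.target
    gene_pos = norm.genes.get_indexer(pd.Index(genes))
    if len(genes) == 0:
        audit = pd.DataFrame(
            columns=["tp_mean", "adjacent_mean", "max_neighborhood_mean", "ratio"]
        )
        return MarkerSet(name, [], audit, query.fold_threshold, query.k)

    tp_pos = cohort.cell_positions(cohort.cells_in_cluster(query.target))
    adj_pos = cohort.cell_positions(cohort.cells_in_cluster(query.adjacent))
    tp_mean = _mean_linear(norm, tp_pos, gene_pos)
    adj_mean = _mean_linear(norm, adj_pos, gene_pos)

    expr = np.expm1(norm.dense(gene_positions=gene_pos))  # cells x genes(candidates)
    n_neigh, k = retained.shape
    rows = np.repeat(np.arange(n_neigh), k)
    indicator = sp.csr_matrix(
        (np.full(rows.size, 1.0 / k), (rows, retained.ravel())),
        shape=(n_neigh, expr.shape[0]),
    )
    neigh_means = indicator @ expr  # neighborhoods x genes
    if query.neighborhood_reference == "max":
        reference = neigh_means.max(axis=0)
    else:
        reference = neigh_means.mean(axis=0)

    with np.errstate(divide="ignore"):
        ratio = np.where(reference > 0, tp_mean / reference, np.inf)
    keep = tp_mean > query.fold_threshold * reference

    audit = pd.DataFrame(
        {
            "tp_mean": tp_mean,
            "adjacent_mean": adj_mean,
            "max_neighborhood_mean": reference,
            "ratio": ratio,
        },
        index=pd.Index(genes, name="gene"),
    )
    kept = audit.loc[keep].copy()
    order = np.lexsort((kept.index.to_numpy(), -kept["ratio"].to_numpy()))
    kept = kept.iloc[order]
    return MarkerSet(name, list(kept.index), kept, query.fold_threshold, query.k)


def select_markers(
    cohort: CellCohort,
    query: MarkerQuery,
    norm: LogNormMatrix | None = None,
    set_name: str | None = None,
) -> MarkerSet:
    """Run the full four-step marker-selection pipeline."""
    if norm is None:
        norm = lognormalize(cohort)
    candidates = candidate_markers(query, cohort, norm)
    survivors = adjacent_filter(candidates, query, cohort, norm)
    neighborhoods = build_neighborhoods(query, cohort, norm)
    return neighborhood_specificity_filter(
        survivors, neighborhoods, query, cohort, norm, set_name=set_name
    )
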