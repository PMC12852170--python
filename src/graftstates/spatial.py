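"""Spatial co-occurrence of cell types in segmented-cell tables.

Works on centroid tables (id, x/y in micrometres, cell-type label) from
segmentation-based spatial transcriptomics.  The co-occurrence ratio of
a query type B around an anchor type A at distance d is the fraction of
B cells among all cells lying within <= d of any anchor (a cell's own
anchor identity never pairs it with itself), divided by B's marginal
fraction in the sample; 1 under spatial randomness.  Cells within
25 micrometres are treated as direct neighbors, and enrichment or
depletion across samples is tested with a one-sample t-test of the
per-sample ratios against 1 with BH correction across type pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .dge import benjamini_hochberg

__all__ = [
    "SpatialSample",
    "CoOccurrenceCurve",
    "NeighborIndex",
    "neighbor_index",
    "cooccurrence_curve",
    "ratio_at",
    "direct_neighbor_test",
    "DIRECT_NEIGHBOR_UM",
]

#: centroid distance under which two cells count as direct neighbors
DIRECT_NEIGHBOR_UM = 25.0


@dataclass
class SpatialSample:
    """Segmented cells of one tissue section.

    ``cells``: DataFrame with columns ``cell_id``, ``x_um``, ``y_um``,
    ``cell_type``; plus the section's ``sample_id`` and ``group``.
    """

    cells: pd.DataFrame
    sample_id: str
    group: str

    def __post_init__(self) -> None:
        required = {"cell_id", "x_um", "y_um", "cell_type"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells table missing columns: {sorted(missing)}")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell ids must be unique within a sample")
        xy = self.cells[["x_um", "y_um"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValueError("coordinates must be finite")
        if (self.cells["cell_type"].astype(str) == "").any():
            raise ValueError("cell-type labels must be non-empty")
        self.cells = self.cells.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def coordinates(self) -> np.ndarray:
        return self.cells[["x_um", "y_um"]].to_numpy(float)

    def type_counts(self) -> pd.Series:
        return self.cells["cell_type"].value_counts()


@dataclass
class CoOccurrenceCurve:
    anchor: str
    query: str
    sample_id: str
    grid: np.ndarray
    ratio: np.ndarray  # NaN where no cell lies near any anchor

    def at(self, d: float) -> float:
        i = np.flatnonzero(np.isclose(self.grid, d))
        if i.size == 0:
            raise KeyError(f"distance {d} not on the grid")
        return float(self.ratio[i[0]])


class NeighborIndex:
    """Fixed-radius neighbor queries, deterministic (id-ordered) output."""

    def __init__(self, sample: SpatialSample, radius: float):
        if radius <= 0:
            raise ValueError("radius must be positive")
        self.sample = sample
        self.radius = float(radius)
        self._xy = sample.coordinates()
        self._tree = cKDTree(self._xy)
        self._ids = sample.cells["cell_id"].to_numpy()
        self._row_of = {cid: i for i, cid in enumerate(self._ids)}

    def neighbors(self, cell_id) -> list:
        """Ids of all cells within <= radius of ``cell_id`` (self excluded)."""
        row = self._row_of[cell_id]
        hits = self._tree.query_ball_point(self._xy[row], r=self.radius)
        return sorted(self._ids[i] for i in hits if i != row)

    def all_neighbors(self) -> dict:
        out = {}
        for lists, row in zip(
            self._tree.query_ball_point(self._xy, r=self.radius), range(len(self._ids))
        ):
            out[self._ids[row]] = sorted(
                self._ids[i] for i in lists if i != row
            )
        return out


def neighbor_index(sample: SpatialSample, radius: float) -> NeighborIndex:
    return NeighborIndex(sample, radius)


def _nearest_anchor_distance(sample: SpatialSample, anchor: str) -> np.ndarray:
    """Per cell, distance to the nearest anchor cell other than itself."""
    types = sample.cells["cell_type"].to_numpy()
    anchor_rows = np.flatnonzero(types == anchor)
    if anchor_rows.size == 0:
        raise ValueError(f"no cells of anchor type {anchor!r}")
    xy = sample.coordinates()
    tree = cKDTree(xy[anchor_rows])
    dist = np.empty(len(xy))
    non_anchor = np.flatnonzero(types != anchor)
    if non_anchor.size:
        dist[non_anchor], _ = tree.query(xy[non_anchor], k=1)
    if anchor_rows.size == 1:
        dist[anchor_rows] = np.inf  # a lone anchor has no co-anchor
    else:
        d2, _ = tree.query(xy[anchor_rows], k=2)
        dist[anchor_rows] = d2[:, 1]
    return dist


def cooccurrence_curve(
    sample: SpatialSample,
    anchor: str,
    query: str,
    grid,
    cumulative: bool = True,
    count_anchors: bool = True,
) -> CoOccurrenceCurve:
    """Co-occurrence ratio of ``query`` around ``anchor`` along ``grid``.

    ``cumulative=True`` counts cells within <= d of any anchor;
    ``cumulative=False`` uses the annulus (previous grid point, d]
    of nearest-anchor distance instead.  ``count_anchors=False``
    removes the anchor type itself from both the neighbor pool and the
    marginal, instead of counting anchors as potential neighbors of
    other anchors.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or (grid <= 0).any():
        raise ValueError("grid must be positive")
    if (np.diff(grid) <= 0).any():
        raise ValueError("grid must be strictly increasing")
    dist = _nearest_anchor_distance(sample, anchor)
    types = sample.cells["cell_type"].to_numpy()
    is_query = types == query
    eligible = np.ones(types.size, bool) if count_anchors else types != anchor
    marginal = is_query[eligible].mean() if eligible.any() else 0.0
    ratio = np.full(grid.size, np.nan)
    lower = 0.0
    for j, d in enumerate(grid):
        near = dist <= d if cumulative else (dist > lower) & (dist <= d)
        near = near & eligible
        lower = d
        n_near = int(near.sum())
        if n_near == 0:
            continue
        if marginal == 0:
            ratio[j] = 0.0
        else:
            ratio[j] = (is_query[near].mean()) / marginal
    return CoOccurrenceCurve(anchor, query, sample.sample_id, grid, ratio)


def ratio_at(
    sample: SpatialSample, anchor: str, query: str, threshold: float = DIRECT_NEIGHBOR_UM
) -> float:
    """Direct-neighbor co-occurrence ratio at a single distance."""
    curve = cooccurrence_curve(sample, anchor, query, [threshold])
    return float(curve.ratio[0])


def _one_sample_t(ratios: np.ndarray) -> tuple[float, float]:
    mean = ratios.mean()
    sd = ratios.std(ddof=1)
    if sd == 0:
        if np.isclose(mean, 1.0):
            return 0.0, 1.0
        return float(np.sign(mean - 1.0) * np.inf), 0.0
    t, p = stats.ttest_1samp(ratios, popmean=1.0)
    return float(t), float(p)


def direct_neighbor_test(
    samples: list[SpatialSample],
    pairs: list[tuple[str, str]],
    threshold: float = DIRECT_NEIGHBOR_UM,
    group: str | None = "allogeneic",
    cumulative: bool = True,
) -> pd.DataFrame:
    """Test direct-neighbor enrichment/depletion of type pairs.

    Per (anchor, query) pair, the per-sample ratio at <= ``threshold`` is
    compared with 1 by a two-sided one-sample t-test across the samples
    of ``group`` (``None`` = all samples); BH correction spans all pairs
    tested in this call.  Pairs with fewer than 2 finite per-sample
    ratios are reported untested with a reason.
    """
    if group is not None:
        samples = [s for s in samples if s.group == group]
    rows = []
    for anchor, query in pairs:
        ratios = []
        for s in samples:
            if (s.cells["cell_type"] == anchor).sum() == 0:
                continue
            # a single grid point makes the first annulus (0, d] coincide
            # with the cumulative ball, so both modes share this call
            curve = cooccurrence_curve(s, anchor, query, [threshold])
            r = curve.ratio[-1]
            if np.isfinite(r):
                ratios.append(r)
        ratios = np.asarray(ratios, dtype=float)
        row = {
            "anchor": anchor,
            "query": query,
            "n_samples": ratios.size,
            "mean_ratio": ratios.mean() if ratios.size else np.nan,
        }
        if ratios.size < 2:
            row.update(t=np.nan, p=np.nan, tested=False,
                       reason="fewer than 2 samples with finite ratio")
        else:
            t, p = _one_sample_t(ratios)
            row.update(t=t, p=p, tested=True, reason="")
        rows.append(row)
    result = pd.DataFrame(rows)
    result["padj"] = np.nan
    tested = result["tested"].to_numpy(bool)
    if tested.any():
        result.loc[tested, "padj"] = benjamini_hochberg(
            result.loc[tested, "p"].to_numpy()
        )
    result["direction"] = np.where(
        result["mean_ratio"] > 1, "enrichment",
        np.where(result["mean_ratio"] < 1, "depletion", "none"),
    )
    return result
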