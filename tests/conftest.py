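"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own code paths: rank-sum
p-values are obtained by exhaustive enumeration of pairwise-comparison
U statistics, BH by a quadratic search over ranks, Kaplan-Meier and
log-rank by explicit risk-set bookkeeping, and spatial / neighborhood
quantities by O(n^2) distance matrices with explicit set logic.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from graftstates import CellCohort, SpatialSample


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def bh_oracle(p):
    """Quadratic-time BH step-up: adj_i = min over ranks >= rank(i)."""
    p = np.asarray(p, float)
    m = p.size
    order = sorted(range(m), key=lambda i: (p[i], i))
    adj = np.empty(m)
    for pos, i in enumerate(order):
        adj[i] = min(1.0, min(p[order[j]] * m / (j + 1) for j in range(pos, m)))
    return adj


def _u_stat(a, b):
    return sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
    )


def wilcoxon_perm_oracle(xa, xb):
    """Two-sided p by full enumeration of group assignments."""
    pooled = list(xa) + list(xb)
    na, n = len(xa), len(xa) + len(xb)
    mu = na * len(xb) / 2.0
    obs = abs(_u_stat(xa, xb) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), na):
        chosen = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(n) if i not in chosen]
        total += 1
        if abs(_u_stat(a, b) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def km_oracle(times, events):
    """Hand product-limit estimate: list of (time, survival)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = []
    s = 1.0
    for t in sorted(set(times)):
        at_risk = int((times >= t).sum())
        d = int(events[times == t].sum())
        if d:
            s *= 1.0 - d / at_risk
        out.append((t, s))
    return out


def logrank_oracle(ta, ea, tb, eb):
    """Hand log-rank: chi-square from summed O-E and hypergeometric V."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, int), np.asarray(eb, int)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(events[times == t].sum())
        d_a = int(events[(times == t) & in_a].sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    from scipy.stats import chi2

    stat = o_minus_e**2 / var
    return stat, float(chi2.sf(stat, 1))


def knn_oracle(embedding, seed_idx, k):
    """Seed's k nearest cells by explicit distances, ties by index."""
    d = np.sqrt(((embedding - embedding[seed_idx]) ** 2).sum(axis=1))
    d[seed_idx] = 0.0
    order = sorted(range(len(d)), key=lambda i: (d[i], i))
    return order[:k]


def spatial_curve_oracle(sample: SpatialSample, anchor, query, grid):
    """Co-occurrence ratios by O(n^2) pair enumeration and set logic."""
    xy = sample.coordinates()
    types = sample.cells["cell_type"].to_numpy()
    n = len(types)
    dist = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    anchors = np.flatnonzero(types == anchor)
    marginal = (types == query).mean()
    out = []
    for d in grid:
        near = set()
        for i in range(n):
            for j in anchors:
                if j != i and dist[i, j] <= d:
                    near.add(i)
                    break
        if not near:
            out.append(np.nan)
            continue
        n_query = sum(types[i] == query for i in near)
        out.append((n_query / len(near)) / marginal if marginal else 0.0)
    return np.asarray(out)


def neighbor_sets_oracle(sample: SpatialSample, radius):
    """Radius-neighbor ids per cell by O(n^2) enumeration."""
    xy = sample.coordinates()
    ids = sample.cells["cell_id"].to_numpy()
    n = len(ids)
    out = {}
    for i in range(n):
        hits = []
        for j in range(n):
            if j == i:
                continue
            if np.hypot(*(xy[i] - xy[j])) <= radius:
                hits.append(ids[j])
        out[ids[i]] = sorted(hits)
    return out


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

def make_cohort(
    rng: np.random.Generator,
    n_cells: int = 60,
    n_genes: int = 30,
    clusters=("A", "B", "C"),
) -> CellCohort:
    """A small random cohort with Poisson counts and random labels."""
    counts = rng.poisson(2.0, size=(n_cells, n_genes))
    counts[rng.random(counts.shape) < 0.4] = 0
    counts[:, 0] += 1  # keep every cell's depth positive
    genes = pd.Index([f"g{i:03d}" for i in range(n_genes)])
    cells = pd.Index([f"c{i:03d}" for i in range(n_cells)])
    obs = pd.DataFrame(
        {
            "cluster": rng.choice(clusters, size=n_cells),
            "sample": rng.choice(["s1", "s2"], size=n_cells),
            "group": rng.choice(["syngeneic", "allogeneic"], size=n_cells),
        },
        index=cells,
    )
    return CellCohort(counts=sp.csr_matrix(counts), genes=genes, cells=cells, obs=obs)


def make_spatial(
    rng: np.random.Generator,
    n_cells: int = 300,
    size: float = 400.0,
    types=("injury", "macrophage", "other"),
    probs=(0.2, 0.3, 0.5),
    sample_id: str = "s1",
    group: str = "allogeneic",
) -> SpatialSample:
    xy = rng.uniform(0, size, size=(n_cells, 2))
    labels = rng.choice(types, size=n_cells, p=probs)
    cells = pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_c{i:05d}" for i in range(n_cells)],
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "cell_type": labels,
        }
    )
    return SpatialSample(cells=cells, sample_id=sample_id, group=group)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort(rng):
    return make_cohort(rng)
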