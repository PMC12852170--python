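"""Per-gene differential expression between two cell groups.

The statistic is the two-sided Wilcoxon rank-sum test on log-normalized
values, with exact enumeration of the null for small groups and a
tie-corrected normal approximation otherwise.  Effect size is the log2
fold-change of mean back-transformed (``expm1``) normalized expression
with a pseudocount of 1, and significance filtering follows the
convention used for allograft snRNA-seq: ``|log2FC| > 1``, BH-adjusted
``p < 0.05`` and expression in at least 10% of cells of the upregulated
group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LogNormMatrix

__all__ = [
    "DEResult",
    "benjamini_hochberg",
    "wilcoxon_de",
    "apply_de_filters",
    "wilcoxon_rank_sum_p",
]

#: pseudocount added to group means before the log2 ratio
PSEUDOCOUNT = 1.0

#: largest number of group assignments enumerated by the exact test
_EXACT_MAX_ASSIGNMENTS = 20_000
_EXACT_MAX_MIN_GROUP = 8


@dataclass
class DEResult:
    """Per-gene differential-expression table for one A-vs-B contrast.

    ``table`` columns: ``log2fc`` (A over B), ``p``, ``padj``, ``frac_a``,
    ``frac_b`` (fractions of expressing cells), ``direction`` (+1 up in A,
    -1 up in B, 0 flat); indexed by gene id.
    """

    table: pd.DataFrame
    group_a: str = "A"
    group_b: str = "B"

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Monotone-enforced; invariant to input permutation (same values map to
    the same adjusted values regardless of position).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _exact_rank_sum_p(ranks: np.ndarray, n_a: int) -> float:
    """Two-sided exact p by enumerating all assignments of ranks to A."""
    n = ranks.size
    mu = n_a * (n + 1) / 2.0
    r_obs = ranks[:n_a].sum()
    dev = abs(r_obs - mu)
    idx = np.fromiter(
        (i for c in combinations(range(n), n_a) for i in c), dtype=np.intp
    ).reshape(-1, n_a)
    sums = ranks[idx].sum(axis=1)
    return float(np.mean(np.abs(sums - mu) >= dev - 1e-9))


def wilcoxon_rank_sum_p(x_a: np.ndarray, x_b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one gene.

    Exact (full enumeration over assignments, tie structure respected)
    when the smaller group has <= 8 members and the enumeration stays
    small; tie-corrected normal approximation without continuity
    correction otherwise.
    """
    n_a, n_b = len(x_a), len(x_b)
    n = n_a + n_b
    pooled = np.concatenate([x_a, x_b])
    ranks = stats.rankdata(pooled)
    m = min(n_a, n_b)
    if m <= _EXACT_MAX_MIN_GROUP and comb(n, m) <= _EXACT_MAX_ASSIGNMENTS:
        # enumerate over the smaller side; deviation of the rank sum is
        # symmetric, so either side gives the same two-sided p
        if n_a <= n_b:
            return _exact_rank_sum_p(ranks, n_a)
        return _exact_rank_sum_p(np.concatenate([ranks[n_a:], ranks[:n_a]]), n_b)
    r_a = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (r_a - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_de(
    norm: LogNormMatrix,
    cells_a,
    cells_b,
    group_a: str = "A",
    group_b: str = "B",
) -> DEResult:
    """Wilcoxon rank-sum DE of group A vs group B on normalized values.

    The BH family is all genes tested in this one call.
    """
    pos_a = norm.cell_positions(cells_a)
    pos_b = norm.cell_positions(cells_b)
    if pos_a.size == 0 or pos_b.size == 0:
        raise ValueError("both cell groups must be non-empty")
    if np.intersect1d(pos_a, pos_b).size:
        raise ValueError("cell groups overlap")

    vals_a = norm.dense(pos_a)
    vals_b = norm.dense(pos_b)

    frac_a = (vals_a > 0).mean(axis=0)
    frac_b = (vals_b > 0).mean(axis=0)
    mean_lin_a = np.expm1(vals_a).mean(axis=0)
    mean_lin_b = np.expm1(vals_b).mean(axis=0)
    log2fc = np.log2((mean_lin_a + PSEUDOCOUNT) / (mean_lin_b + PSEUDOCOUNT))

    n_genes = vals_a.shape[1]
    p = np.ones(n_genes)
    for g in range(n_genes):
        xa, xb = vals_a[:, g], vals_b[:, g]
        if not (xa.any() or xb.any()):
            continue  # all-zero gene: p = 1, log2fc already 0
        p[g] = wilcoxon_rank_sum_p(xa, xb)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "padj": benjamini_hochberg(p),
            "frac_a": frac_a,
            "frac_b": frac_b,
            "direction": np.sign(log2fc).astype(int),
        },
        index=norm.genes,
    )
    return DEResult(table=table, group_a=group_a, group_b=group_b)


def apply_de_filters(
    de: DEResult,
    min_abs_log2fc: float = 1.0,
    max_padj: float = 0.05,
    min_frac: float = 0.10,
    frac_group: str = "auto",
) -> pd.DataFrame:
    """Significance / effect-size / expression filtering of a DE table.

    ``frac_group`` selects which expressing-cell fraction must reach
    ``min_frac``: ``"auto"`` uses the upregulated group per gene (A for
    up, B for down), ``"group_a"`` / ``"group_b"`` fix one side and
    ``"either"`` accepts both.  Returns the passing genes ordered by
    descending ``|log2fc|`` (gene id as tie-break) with their direction.
    """
    if frac_group not in {"auto", "group_a", "group_b", "either"}:
        raise ValueError(f"unknown frac_group: {frac_group!r}")
    t = de.table
    if frac_group == "group_a":
        frac_ok = t["frac_a"] >= min_frac
    elif frac_group == "group_b":
        frac_ok = t["frac_b"] >= min_frac
    elif frac_group == "either":
        frac_ok = (t["frac_a"] >= min_frac) | (t["frac_b"] >= min_frac)
    else:
        frac_ok = np.where(t["log2fc"] >= 0, t["frac_a"], t["frac_b"]) >= min_frac
    keep = (t["log2fc"].abs() > min_abs_log2fc) & (t["padj"] < max_padj) & frac_ok
    out = t.loc[keep, ["log2fc", "padj", "direction"]].copy()
    # deterministic: descending |log2fc|, ascending gene id on ties
    abs_fc = out["log2fc"].abs().to_numpy()
    out = out.iloc[np.lexsort((out.index.to_numpy(), -abs_fc))]
    return out


def upregulated_genes(de: DEResult, **filters) -> list[str]:
    """Genes significantly up in group A under the standard filters."""
    table = apply_de_filters(de, **filters)
    return list(table.index[table["direction"] > 0])
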