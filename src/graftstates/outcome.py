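"""Outcome statistics: survival, composition and concordance.

Covers the downstream statistics of the injury-score analysis: Kaplan-
Meier estimation and log-rank testing of graft loss (administratively
censored at a 3-year horizon), median-split survival stratification of
gene-set scores with BH-adjusted false discovery rates across sets,
two-group composition comparisons (plain and arcsin-transformed
empirical-Bayes moderated t-tests) and Spearman concordance of log2
fold-changes between differential-expression runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .dge import DEResult, benjamini_hochberg
from .scoring import BulkCohort, GeneSetScore

__all__ = [
    "SurvivalResult",
    "CompositionTable",
    "ConcordanceResult",
    "apply_horizon",
    "kaplan_meier",
    "logrank_test",
    "survival_by_score",
    "composition_ttests",
    "arcsin_moderated_ttest",
    "log2fc_concordance",
]

GRAFT_LOSS_HORIZON_MONTHS = 36.0


def apply_horizon(times, events, horizon: float):
    """Administratively censor all follow-up beyond ``horizon``."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    over = times > horizon
    return np.where(over, horizon, times), np.where(over, 0, events)


def kaplan_meier(times, events, horizon: float | None = None) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct observed time with columns ``time``,
    ``at_risk``, ``events``, ``censored`` and ``survival``.  At tied
    times events are processed before censorings (both counted at risk).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    if horizon is not None:
        times, events = apply_horizon(times, events, horizon)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    table = table[table["removed"] > 0]  # keep distinct observed times only
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(float),
            "at_risk": table["at_risk"].to_numpy(int),
            "events": table["observed"].to_numpy(int),
            "censored": table["censored"].to_numpy(int),
            "survival": surv.reindex(table.index).to_numpy(float),
        }
    ).reset_index(drop=True)
    return out


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test -> (chi-square statistic, p-value)."""
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    events_a = np.asarray(events_a, int)
    events_b = np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, p


@dataclass
class SurvivalResult:
    """Median-split survival analysis across gene sets."""

    tests: pd.DataFrame  # per set: n_above, n_below, events, chi2, p, fdr
    km_curves: dict = field(default_factory=dict)  # (set, diagnosis, stratum) -> KM df
    letters: dict = field(default_factory=dict)  # set -> {stratum label: letters}
    diagnoses: tuple = ()


def _compact_letters(labels: list[str], different: set[frozenset]) -> dict:
    """Greedy compact-letter display: strata sharing a letter are not
    significantly different."""
    letter_groups: list[set] = []
    for lab in labels:
        placed = False
        for grp in letter_groups:
            if all(frozenset((lab, other)) not in different for other in grp):
                grp.add(lab)
                placed = True
        if not placed:
            letter_groups.append({lab})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, grp in zip(alphabet, letter_groups):
        for lab in labels:
            if lab in grp:
                out[lab] += letter
    return out


def survival_by_score(
    cohort: BulkCohort,
    scores: GeneSetScore,
    sets: list[str] | None = None,
    diagnoses: tuple[str, str] = ("TCMR", "NR"),
    horizon: float | None = GRAFT_LOSS_HORIZON_MONTHS,
    alpha: float = 0.05,
    letters: bool = True,
) -> SurvivalResult:
    """Median-split survival stratification of gene-set scores.

    Uses the first biopsy per patient; the median of each set's score is
    taken over that full first-biopsy cohort (all diagnoses jointly) and
    strata are formed by crossing diagnosis with above/below-median.
    Per set, above-vs-below survival is compared within the *first*
    diagnosis of ``diagnoses`` by a log-rank test, with BH adjustment
    across sets giving the fdr; KM curves and a compact-letter grouping
    of all strata (pairwise log-rank, BH at ``alpha`` within each set)
    are attached.
    """
    if sets is None:
        sets = list(scores.values.columns)
    first = cohort.first_biopsies()
    times, events = first["time_months"].to_numpy(float), first["event"].to_numpy(int)
    if horizon is not None:
        times, events = apply_horizon(times, events, horizon)
    surv = pd.DataFrame(
        {"time": times, "event": events, "diagnosis": first["diagnosis"]},
        index=first.index,
    )
    primary = diagnoses[0]
    rows, km_curves, letter_map = [], {}, {}
    for set_name in sets:
        s = scores.for_set(set_name).loc[first.index]
        med = float(np.median(s.to_numpy()))
        stratum = pd.Series(np.where(s > med, "above", "below"), index=s.index)
        sub = surv.loc[surv["diagnosis"] == primary]
        above = sub[stratum.loc[sub.index] == "above"]
        below = sub[stratum.loc[sub.index] == "below"]
        row = {
            "set": set_name,
            "diagnosis": primary,
            "n_above": len(above),
            "n_below": len(below),
            "events": int(sub["event"].sum()),
        }
        if len(above) == 0 or len(below) == 0:
            row.update(chi2=np.nan, p=np.nan, tested=False)
        else:
            chi2, p = logrank_test(
                above["time"], above["event"], below["time"], below["event"]
            )
            row.update(chi2=chi2, p=p, tested=True)
        rows.append(row)

        if not letters:
            continue
        strata_tables = {}
        for diag in diagnoses:
            for strat in ("below", "above"):
                mask = (surv["diagnosis"] == diag) & (stratum.loc[surv.index] == strat)
                label = f"{diag}:{strat}"
                if mask.sum() == 0:
                    continue
                grp = surv.loc[mask]
                strata_tables[label] = grp
                km_curves[(set_name, diag, strat)] = kaplan_meier(
                    grp["time"], grp["event"]
                )
        # compact letters from pairwise log-rank among the populated strata
        labels = list(strata_tables)
        pair_p, pair_keys = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = strata_tables[labels[i]], strata_tables[labels[j]]
                _, p_ij = logrank_test(a["time"], a["event"], b["time"], b["event"])
                pair_p.append(p_ij)
                pair_keys.append(frozenset((labels[i], labels[j])))
        different = set()
        if pair_p:
            padj = benjamini_hochberg(np.asarray(pair_p))
            different = {k for k, q in zip(pair_keys, padj) if q < alpha}
        letter_map[set_name] = _compact_letters(labels, different)

    tests = pd.DataFrame(rows).set_index("set")
    tested = tests["tested"].to_numpy(bool)
    tests["fdr"] = np.nan
    if tested.any():
        tests.loc[tested, "fdr"] = benjamini_hochberg(
            tests.loc[tested, "p"].to_numpy()
        )
    return SurvivalResult(
        tests=tests, km_curves=km_curves, letters=letter_map, diagnoses=diagnoses
    )


@dataclass
class CompositionTable:
    """Per-sample cell-type proportions (rows sum to 1)."""

    proportions: pd.DataFrame  # samples x cell types

    def __post_init__(self) -> None:
        vals = self.proportions.to_numpy(float)
        if (vals < -1e-12).any():
            raise ValueError("proportions must be nonnegative")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-sample proportions must sum to 1")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CompositionTable":
        total = counts.sum(axis=1)
        return cls(counts.div(total, axis=0))


def composition_ttests(
    table: CompositionTable, groups: pd.Series, equal_var: bool = True
) -> pd.DataFrame:
    """Two-sample t-test per cell type, BH across types.

    Student's (pooled-variance) t by default; ``equal_var=False`` gives
    Welch's t.
    """
    props = table.proportions
    groups = groups.loc[props.index]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    a = props.loc[groups == levels[0]]
    b = props.loc[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for ct in props.columns:
        xa, xb = a[ct].to_numpy(), b[ct].to_numpy()
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            rows.append({"cell_type": ct, "t": 0.0, "p": 1.0, "degenerate": True})
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        rows.append({"cell_type": ct, "t": float(t), "p": float(p),
                     "degenerate": False})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["padj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def arcsin_moderated_ttest(
    table: CompositionTable,
    groups: pd.Series,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Arcsine-square-root transformed, variance-moderated t-tests.

    Proportions are transformed ``y = arcsin(sqrt(p))`` (variance-
    stabilizing for proportions), then each cell type is compared
    between the two groups with an empirical-Bayes moderated t: the
    per-type pooled variance is shrunk toward a prior variance whose
    magnitude ``s0^2`` and weight ``d0`` (prior degrees of freedom) are
    estimated across cell types by the method of moments on the
    F-distributed variance ratios.  ``prior_df=0`` disables shrinkage
    (ordinary t on transformed values); ``prior_df=inf`` uses the prior
    variance alone.
    """
    props = table.proportions
    vals = props.to_numpy(float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("proportions must lie in [0, 1]")
    y = pd.DataFrame(np.arcsin(np.sqrt(vals)), index=props.index,
                     columns=props.columns)
    groups = groups.loc[y.index]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    a = y.loc[groups == levels[0]].to_numpy()
    b = y.loc[groups == levels[1]].to_numpy()
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    d = n1 + n2 - 2
    diff = a.mean(axis=0) - b.mean(axis=0)
    ss = a.var(axis=0, ddof=1) * (n1 - 1) + b.var(axis=0, ddof=1) * (n2 - 1)
    s2 = ss / d

    if prior_df is None:
        d0, s0_sq = _moment_prior(s2, d)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.mean(s2))

    if d0 == 0:
        s2_post, df_post = s2, d
    elif np.isinf(d0):
        s2_post, df_post = np.full_like(s2, s0_sq), np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_post = d + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_post)
    p = np.where(se > 0, np.minimum(p, 1.0), 1.0)
    out = pd.DataFrame(
        {"t": t, "p": p, "s2": s2, "s2_posterior": s2_post},
        index=props.columns,
    )
    out["padj"] = benjamini_hochberg(out["p"].to_numpy())
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


def _moment_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2): marginally s2/s0^2 ~ F(d, d0)."""
    mean = float(np.mean(s2))
    if mean <= 0 or s2.size < 2:
        return np.inf, max(mean, 0.0)
    cv2 = float(np.var(s2, ddof=1)) / mean**2
    denom = cv2 * d - 2.0
    if denom <= 0:
        return np.inf, mean  # no excess variability: total shrinkage
    d0 = (4.0 * cv2 * d + 2.0 * d - 4.0) / denom
    if d0 <= 4.0:
        d0 = 4.0 + 1e-6  # keep the F moments finite
    s0_sq = mean * (d0 - 2.0) / d0
    return d0, s0_sq


@dataclass
class ConcordanceResult:
    rho: float
    p: float
    n_genes: int
    reference: str = "A"


def log2fc_concordance(
    de_a: DEResult, de_b: DEResult, top_n: int = 500
) -> ConcordanceResult:
    """Spearman concordance of log2FCs on A's top changed genes.

    Takes the union of the ``top_n`` most increased and ``top_n`` most
    decreased genes of dataset A (the reference), intersects with B's
    gene namespace, and correlates the paired log2 fold-changes.
    """
    ta, tb = de_a.table, de_b.table
    ordered = ta["log2fc"].sort_values(kind="stable")
    top_down = ordered.index[:top_n]
    top_up = ordered.index[-top_n:]
    selected = top_up.union(top_down)
    shared = selected.intersection(tb.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need at least 10")
    rho, p = stats.spearmanr(
        ta.loc[shared, "log2fc"].to_numpy(), tb.loc[shared, "log2fc"].to_numpy()
    )
    return ConcordanceResult(rho=float(rho), p=float(p), n_genes=len(shared))
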