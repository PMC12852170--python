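"""Gene-set scoring of bulk transcriptomes against marker sets.

A sample's score for a marker set is the log2 geometric mean of the
set's genes (equivalently the arithmetic mean of log2 expression),
normalized so that the mean score across the control (nephrectomy)
samples is exactly zero.  Scores therefore read as log2-fold expression
of the injury signature relative to non-rejecting control tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerSet

__all__ = [
    "BulkCohort",
    "GeneSetScore",
    "score_samples",
    "median_stratify",
    "probe_collapse",
    "longitudinal_trajectories",
]

logger = logging.getLogger(__name__)

DIAGNOSES = ("NR", "TCMR", "ABMR", "Mixed")


@dataclass
class BulkCohort:
    """Log2-scale expression with clinical outcome and control samples.

    ``expression``: genes x samples (log2 intensities, finite).
    ``clinical``: indexed by sample id with columns ``patient_id``,
    ``diagnosis``, ``time_months``, ``event``, ``biopsy_index``.
    ``controls``: sample ids of the control (nephrectomy) biopsies;
    controls need no clinical row.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    controls: list[str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.expression.to_numpy()).all():
            raise ValueError("expression must be finite (log2 scale)")
        missing = set(self.controls) - set(self.expression.columns)
        if missing:
            raise ValueError(f"controls absent from expression: {sorted(missing)}")
        missing_cols = {
            "patient_id",
            "diagnosis",
            "time_months",
            "event",
            "biopsy_index",
        } - set(self.clinical.columns)
        if missing_cols:
            raise ValueError(f"clinical table missing columns: {sorted(missing_cols)}")
        absent = set(self.clinical.index) - set(self.expression.columns)
        if absent:
            raise ValueError(f"clinical samples absent from expression: {sorted(absent)[:5]}")
        if (self.clinical["time_months"] < 0).any():
            raise ValueError("times must be nonnegative")

    @property
    def case_samples(self) -> pd.Index:
        return self.clinical.index

    def first_biopsies(self) -> pd.DataFrame:
        """One row per patient: the earliest biopsy by ``biopsy_index``."""
        cl = self.clinical.sort_values("biopsy_index", kind="stable")
        return cl.loc[~cl["patient_id"].duplicated(keep="first")]


@dataclass
class GeneSetScore:
    """Per-(sample, set) control-normalized scores, log2 units."""

    values: pd.DataFrame  # samples x sets
    coverage: dict[str, float] = field(default_factory=dict)

    def for_set(self, set_name: str) -> pd.Series:
        return self.values[set_name]


def _set_genes(marker_set) -> tuple[str, list[str]]:
    if isinstance(marker_set, MarkerSet):
        return marker_set.name, list(marker_set.genes)
    name, genes = marker_set  # (name, iterable) pairs also accepted
    return name, list(genes)


def score_samples(
    cohort: BulkCohort,
    sets,
    min_coverage: float = 0.5,
) -> GeneSetScore:
    """Score every expression sample against each marker set.

    Per set: raw score = mean log2 expression over the set's matched
    genes (duplicated gene entries dropped); final score = raw score
    minus the mean raw score of the control samples.  A set matching
    fewer than ``min_coverage`` of its genes is refused; coverage is
    always reported.
    """
    if not cohort.controls:
        raise ValueError("at least one control sample is required")
    scores = {}
    coverage = {}
    for marker_set in sets:
        name, genes = _set_genes(marker_set)
        if not genes:
            raise ValueError(f"marker set {name!r} is empty")
        genes = list(dict.fromkeys(genes))  # de-duplicate, keep order
        present = [g for g in genes if g in cohort.expression.index]
        cov = len(present) / len(genes)
        coverage[name] = cov
        if not present:
            raise ValueError(f"marker set {name!r} matches no expression genes")
        if cov < min_coverage:
            raise ValueError(
                f"marker set {name!r} covers only {cov:.0%} of its genes "
                f"(minimum {min_coverage:.0%})"
            )
        if cov < 1.0:
            logger.info("set %s: %d/%d genes matched", name, len(present), len(genes))
        raw = cohort.expression.loc[present].mean(axis=0)
        scores[name] = raw - raw.loc[cohort.controls].mean()
    return GeneSetScore(values=pd.DataFrame(scores), coverage=coverage)


def median_stratify(
    scores: GeneSetScore,
    cohort: BulkCohort,
    set_name: str,
    samples: pd.Index | None = None,
) -> pd.Series:
    """Split samples at the median score of the full (non-control) cohort.

    Strictly above the median -> ``"above"``; at or below -> ``"below"``
    (ties at the median deliberately go below).  The median is always
    computed over the full population passed in ``samples`` (default:
    every non-control scored sample), even when survival is later
    examined within a single diagnosis.
    """
    s = scores.for_set(set_name)
    if samples is None:
        samples = s.index.difference(pd.Index(cohort.controls), sort=False)
    s = s.loc[samples]
    if len(s) < 2:
        raise ValueError("need at least two scored samples to stratify")
    med = float(np.median(s.to_numpy()))
    return pd.Series(np.where(s > med, "above", "below"), index=s.index, name=set_name)


def probe_collapse(expression: pd.DataFrame, probe_to_gene) -> pd.DataFrame:
    """Collapse a probes x samples table to genes x samples by mean.

    ``probe_to_gene`` maps probe id -> gene id or list of gene ids; a
    probe mapped to several genes contributes to each (with a warning).
    Unmapped probes are dropped with a logged count.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    pairs = []
    multi = 0
    for probe, gene in probe_to_gene.items():
        targets = [gene] if isinstance(gene, str) else list(gene)
        if len(targets) > 1:
            multi += 1
        pairs.extend((probe, t) for t in targets)
    mapping = pd.DataFrame(pairs, columns=["probe", "gene"])
    mapping = mapping[mapping["probe"].isin(expression.index)]
    dropped = len(set(expression.index) - set(mapping["probe"]))
    if dropped:
        logger.info("dropping %d unmapped probes", dropped)
    if multi:
        logger.warning("%d probes map to multiple genes; counted in each", multi)
    stacked = expression.loc[mapping["probe"]].set_index(mapping["gene"].to_numpy())
    return stacked.groupby(level=0, sort=True).mean()


def longitudinal_trajectories(
    scores: GeneSetScore,
    cohort: BulkCohort,
    sets: list[str] | None = None,
    index_diagnosis: str = "TCMR",
    resolution_diagnosis: str = "NR",
) -> pd.DataFrame:
    """Score series over repeat biopsies after an index diagnosis.

    Selects patients with >= 2 biopsies whose first biopsy carries
    ``index_diagnosis`` and whose final biopsy has resolved to
    ``resolution_diagnosis``; returns a long table (patient_id, sample,
    biopsy_index, diagnosis, set, score) ordered by biopsy sequence.
    An empty selection returns an empty table.
    """
    if sets is None:
        sets = list(scores.values.columns)
    cl = cohort.clinical.sort_values("biopsy_index", kind="stable")
    rows = []
    for patient, sub in cl.groupby("patient_id", sort=True):
        if len(sub) < 2:
            continue
        if sub["diagnosis"].iloc[0] != index_diagnosis:
            continue
        if sub["diagnosis"].iloc[-1] != resolution_diagnosis:
            continue
        for sample, rec in sub.iterrows():
            for set_name in sets:
                rows.append(
                    {
                        "patient_id": patient,
                        "sample": sample,
                        "biopsy_index": rec["biopsy_index"],
                        "diagnosis": rec["diagnosis"],
                        "set": set_name,
                        "score": scores.values.at[sample, set_name],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "sample", "biopsy_index", "diagnosis", "set", "score"],
    )
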