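"""Synthetic cohorts with planted, recoverable structure.

Three generators emulate the three data classes of the injury-state
analysis, each with ground truth recorded so recovery can be scored:

* :func:`simulate_cell_cohort` — clustered negative-binomial snRNA-seq
  counts with planted marker genes per population;
* :func:`simulate_spatial_sample` — segmented-cell point patterns with
  tunable co-localization (or depletion) of type pairs, calibrated so
  that the expected direct-neighbor co-occurrence ratio at the niche
  radius equals the requested value;
* :func:`simulate_bulk_cohort` — log2 microarray-like bulk expression
  whose marker genes are shifted by per-sample latent injury scores,
  with graft-loss times whose log-hazard is linear in those scores.

All randomness flows from one root seed through named substreams, so
each generator is reproducible independently of the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from ._rng import substream
from .cohort import CellCohort
from .scoring import BulkCohort
from .spatial import SpatialSample

__all__ = [
    "Population",
    "SpatialConfig",
    "HazardModel",
    "BulkConfig",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cell_cohort",
    "simulate_spatial_sample",
    "simulate_bulk_cohort",
    "beta_for_median_split_hr",
    "calibrate_baseline_rate",
    "default_config",
]

logger = logging.getLogger(__name__)

ROLES = {"healthy", "target_injury", "adjacent_injury", "leukocyte", "other"}


@dataclass
class Population:
    name: str
    proportion: float
    role: str = "other"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not 0 <= self.proportion <= 1:
            raise ValueError("proportion must lie in [0, 1]")


@dataclass
class SpatialConfig:
    """Point-pattern parameters for one tissue section.

    ``enrichment`` maps (anchor type, query type) -> target ratio rho of
    the direct-neighbor co-occurrence at ``niche_radius_um`` (rho > 1
    co-localization, rho < 1 depletion, 1 = complete spatial
    randomness).  A query type may appear in at most one pair.
    """

    field_size_um: float = 1000.0
    density_per_um2: float = 0.005
    niche_radius_um: float = 25.0
    enrichment: dict = field(default_factory=dict)
    #: section composition; None reuses the cohort population proportions
    #: (tissue sections typically differ from dissociated-nuclei fractions)
    type_proportions: dict | None = None

    def __post_init__(self) -> None:
        if self.type_proportions is not None:
            total = sum(self.type_proportions.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"spatial type proportions sum to {total}, not 1")
        for (a, b), rho in self.enrichment.items():
            if rho < 0:
                raise ValueError(f"enrichment ratio for ({a}, {b}) must be >= 0")
        queries = [b for (_, b) in self.enrichment]
        if len(queries) != len(set(queries)):
            raise ValueError("a query type may appear in at most one enrichment pair")


@dataclass
class HazardModel:
    """Exponential graft-loss model: log-hazard linear in the scores."""

    baseline_rate: float = 0.012  # events per month at score 0
    beta: dict = field(default_factory=dict)  # set name -> log-hazard slope
    censor_horizon_months: float = 36.0
    dropout_fraction: float = 0.0  # uniform early censoring, 0 = admin only


@dataclass
class BulkConfig:
    n_samples: int = 300
    n_controls: int = 4
    #: set name -> diagnosis -> mean latent score (log2 units over control)
    score_effects: dict = field(default_factory=dict)
    score_sd: float = 0.5
    noise_sd: float = 0.15  # residual log2 noise, microarray-like technical CV
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    diagnosis_probs: dict = field(
        default_factory=lambda: {"NR": 0.59, "ABMR": 0.28, "TCMR": 0.09, "Mixed": 0.04}
    )
    hazard: HazardModel = field(default_factory=HazardModel)
    #: longitudinal sub-cohort: patients whose first biopsy is TCMR and
    #: whose later biopsies resolve to NR while the score persists
    n_longitudinal: int = 0
    longitudinal_biopsies: int = 3
    persistence_score: float = 1.5


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 2000
    n_cells: int = 5000
    populations: list = field(default_factory=list)
    #: population name -> list of (gene index, linear fold-change >= 1)
    planted_markers: dict = field(default_factory=dict)
    nb_dispersion: float = 2.0
    library_size_range: tuple = (2000, 10000)
    n_samples_per_group: int = 3
    group_names: tuple = ("syngeneic", "allogeneic")
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    bulk: BulkConfig = field(default_factory=BulkConfig)

    def __post_init__(self) -> None:
        if self.populations:
            total = sum(p.proportion for p in self.populations)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"population proportions sum to {total}, not 1")
        names = {p.name for p in self.populations}
        for pop, marks in self.planted_markers.items():
            if pop not in names:
                raise ValueError(f"planted markers reference unknown population {pop!r}")
            for gene_idx, fold in marks:
                if not 0 <= gene_idx < self.n_genes:
                    raise ValueError(f"planted gene index {gene_idx} out of range")
                if fold < 1:
                    raise ValueError("planted fold-changes must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid library size range")


@dataclass
class GroundTruth:
    """Planted structure recorded alongside each simulated object."""

    marker_genes: dict = field(default_factory=dict)  # population -> {gene: fold}
    spatial_ratios: dict = field(default_factory=dict)  # (anchor, query) -> rho
    sample_scores: pd.DataFrame | None = None  # samples x sets latent scores
    hazard_beta: dict = field(default_factory=dict)

    def exclusive_markers(self, population: str) -> list:
        """Planted markers of ``population`` not planted in any other."""
        own = set(self.marker_genes.get(population, {}))
        for other, genes in self.marker_genes.items():
            if other != population:
                own -= set(genes)
        return sorted(own)

    def to_dict(self) -> dict:
        out = {
            "marker_genes": {p: dict(g) for p, g in self.marker_genes.items()},
            "spatial_ratios": {f"{a}|{b}": r for (a, b), r in self.spatial_ratios.items()},
            "hazard_beta": dict(self.hazard_beta),
        }
        if self.sample_scores is not None:
            out["sample_scores"] = {
                c: self.sample_scores[c].to_dict() for c in self.sample_scores
            }
        return out


def _gene_names(n: int) -> pd.Index:
    return pd.Index([f"gene{i:04d}" for i in range(n)], name="gene")


def _allocate(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n cells to populations."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def simulate_cell_cohort(config: SimulationConfig) -> tuple[CellCohort, GroundTruth]:
    """Negative-binomial snRNA-seq counts with planted markers.

    Gene baseline means are drawn once (lognormal, shared across
    populations); a planted marker multiplies its gene's mean by the
    fold-change only inside its population.  Per-cell library sizes are
    log-uniform over the configured range; counts are negative binomial
    with one shared dispersion.
    """
    if not config.populations:
        raise ValueError("config defines no populations")
    rng = substream(config.seed, "cells")
    n_genes, n_cells = config.n_genes, config.n_cells
    genes = _gene_names(n_genes)

    props = np.array([p.proportion for p in config.populations])
    counts_per_pop = _allocate(n_cells, props)
    for pop, n_pop in zip(config.populations, counts_per_pop):
        if n_pop == 0 and config.planted_markers.get(pop.name):
            raise ValueError(
                f"population {pop.name!r} has planted markers but zero cells"
            )

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_cells))

    labels = np.repeat([p.name for p in config.populations], counts_per_pop)
    theta = config.nb_dispersion
    blocks = []
    start = 0
    truth_markers: dict = {}
    for pop, n_pop in zip(config.populations, counts_per_pop):
        fold = np.ones(n_genes)
        for gene_idx, fc in config.planted_markers.get(pop.name, []):
            fold[gene_idx] = fc
        truth_markers[pop.name] = {
            genes[gi]: fc for gi, fc in config.planted_markers.get(pop.name, []) if fc > 1
        }
        if n_pop == 0:
            continue
        w = base * fold
        p_gene = w / w.sum()
        mu = lib[start : start + n_pop, None] * p_gene[None, :]
        block = rng.negative_binomial(theta, theta / (theta + mu))
        blocks.append(sp.csr_matrix(block))
        start += n_pop
    counts = sp.vstack(blocks, format="csr")

    cells = pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell")
    n_samples = 2 * config.n_samples_per_group
    sample_ids = [
        f"{grp}{i + 1}"
        for grp in config.group_names
        for i in range(config.n_samples_per_group)
    ]
    sample_of_cell = rng.choice(n_samples, size=n_cells)
    obs = pd.DataFrame(
        {
            "cluster": labels,
            "sample": np.array(sample_ids)[sample_of_cell],
            "group": np.array(
                [config.group_names[0]] * config.n_samples_per_group
                + [config.group_names[1]] * config.n_samples_per_group
            )[sample_of_cell],
        },
        index=cells,
    )
    cohort = CellCohort(counts=counts, genes=genes, cells=cells, obs=obs)
    return cohort, GroundTruth(marker_genes=truth_markers)


def _disc_coverage(anchors: np.ndarray, radius: float, size: float,
                   rng: np.random.Generator, n_mc: int = 20000) -> float:
    """Monte-Carlo fraction of the field within ``radius`` of an anchor."""
    if anchors.shape[0] == 0:
        return 0.0
    pts = rng.uniform(0, size, size=(n_mc, 2))
    tree = cKDTree(anchors)
    d, _ = tree.query(pts, k=1)
    return float((d <= radius).mean())


def _near_prob_for_rho(rho: float, alpha: float, n: int, n_b: int) -> float:
    """Probability u that a query cell lies within the niche radius of an
    anchor, such that the expected co-occurrence ratio equals rho.

    Derived from ratio = N*u / ((N - N_B)*alpha + N_B*u).
    """
    if rho * n_b >= n:
        raise ValueError("enrichment ratio too large for the query abundance")
    u = rho * alpha * (n - n_b) / (n - rho * n_b)
    return float(np.clip(u, 0.0, 1.0))


def simulate_spatial_sample(
    config: SimulationConfig,
    sample_id: str,
    group: str = "allogeneic",
) -> tuple[SpatialSample, GroundTruth]:
    """A segmented-cell point pattern with planted co-localization.

    Background cells follow a homogeneous Poisson process with the
    configured density; for each (anchor, query) pair with rho > 1 a
    calibrated fraction of query cells is placed parent-offspring style
    inside the niche-radius disc of a random anchor, and for rho < 1
    query cells are thinned near anchors, so that the expected
    direct-neighbor co-occurrence ratio at the niche radius is rho.
    """
    if not config.populations:
        raise ValueError("config defines no populations")
    spatial = config.spatial
    size = spatial.field_size_um
    expected = spatial.density_per_um2 * size**2
    if expected < 100:
        raise ValueError(f"density x area gives only {expected:.0f} expected cells")
    rng = substream(config.seed, f"spatial:{sample_id}")

    n = int(rng.poisson(expected))
    if spatial.type_proportions is not None:
        type_names = list(spatial.type_proportions)
        props = np.array([spatial.type_proportions[t] for t in type_names])
    else:
        type_names = [p.name for p in config.populations]
        props = np.array([p.proportion for p in config.populations])
    counts = rng.multinomial(n, props)
    for name, c in zip(type_names, counts):
        if c == 0:
            logger.warning("sample %s: no cells of type %s generated", sample_id, name)

    query_of: dict[str, tuple[str, float]] = {
        b: (a, rho) for (a, b), rho in spatial.enrichment.items() if rho != 1.0
    }
    plain_types = [t for t in type_names if t not in query_of]

    positions: dict[str, np.ndarray] = {}
    for name, c in zip(type_names, counts):
        if name in plain_types:
            positions[name] = rng.uniform(0, size, size=(c, 2))

    r_niche = spatial.niche_radius_um
    for name, c in zip(type_names, counts):
        if name not in query_of or c == 0:
            if name in query_of and c == 0:
                positions[name] = np.empty((0, 2))
            continue
        anchor, rho = query_of[name]
        anchors = positions.get(anchor, np.empty((0, 2)))
        if anchors.shape[0] == 0:
            logger.warning(
                "sample %s: anchor %s absent, placing %s uniformly",
                sample_id, anchor, name,
            )
            positions[name] = rng.uniform(0, size, size=(c, 2))
            continue
        alpha = _disc_coverage(anchors, r_niche, size, rng)
        u = _near_prob_for_rho(rho, alpha, n, c)
        if rho >= 1.0:
            q = 0.0 if alpha >= 1.0 else (u - alpha) / (1.0 - alpha)
            q = float(np.clip(q, 0.0, 1.0))
            offspring = rng.random(c) < q
            pts = rng.uniform(0, size, size=(c, 2))
            n_off = int(offspring.sum())
            if n_off:
                pts[offspring] = _offspring_positions(
                    anchors, n_off, r_niche, size, rng
                )
            positions[name] = pts
        else:
            # thin near anchors: retention r inside the anchor discs
            if u >= 1.0 or alpha >= 1.0:
                retention = 1.0
            elif alpha == 0.0:
                retention = 1.0
            else:
                retention = (u * (1.0 - alpha)) / (alpha * (1.0 - u))
                retention = float(np.clip(retention, 0.0, 1.0))
            tree = cKDTree(anchors)
            kept = np.empty((0, 2))
            for _ in range(200):
                need = c - kept.shape[0]
                if need <= 0:
                    break
                cand = rng.uniform(0, size, size=(max(need * 2, 16), 2))
                d, _ = tree.query(cand, k=1)
                inside = d <= r_niche
                accept = ~inside | (rng.random(cand.shape[0]) < retention)
                kept = np.vstack([kept, cand[accept]])
            positions[name] = kept[:c]

    frames = []
    next_id = 0
    for name in type_names:
        pts = positions.get(name, np.empty((0, 2)))
        if pts.shape[0] == 0:
            continue
        ids = [f"{sample_id}_c{j:06d}" for j in range(next_id, next_id + pts.shape[0])]
        next_id += pts.shape[0]
        frames.append(
            pd.DataFrame(
                {"cell_id": ids, "x_um": pts[:, 0], "y_um": pts[:, 1],
                 "cell_type": name}
            )
        )
    cells = pd.concat(frames, ignore_index=True)
    sample = SpatialSample(cells=cells, sample_id=sample_id, group=group)
    truth = GroundTruth(spatial_ratios=dict(spatial.enrichment))
    return sample, truth


def _offspring_positions(
    anchors: np.ndarray, n: int, radius: float, size: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform points in the disc of a random anchor, clipped to the field
    by resampling within the disc."""
    out = np.empty((n, 2))
    parents = anchors[rng.integers(0, anchors.shape[0], size=n)]
    pending = np.arange(n)
    while pending.size:
        m = pending.size
        r = radius * np.sqrt(rng.random(m))
        phi = rng.uniform(0, 2 * np.pi, size=m)
        pts = parents[pending] + np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        ok = ((pts >= 0) & (pts <= size)).all(axis=1)
        out[pending[ok]] = pts[ok]
        pending = pending[~ok]
    return out


def beta_for_median_split_hr(hr: float, score_sd: float = 1.0) -> float:
    """Log-hazard slope giving hazard ratio ``hr`` between median-split
    halves of a normal score: the halves' means differ by
    2*sd*sqrt(2/pi) (mean of a half-normal on each side)."""
    gap = 2.0 * score_sd * np.sqrt(2.0 / np.pi)
    return float(np.log(hr) / gap)


@lru_cache(maxsize=64)
def calibrate_baseline_rate(
    target_event_fraction: float,
    beta: float,
    score_sd: float = 1.0,
    horizon: float = 36.0,
    n_mc: int = 200_000,
) -> float:
    """Baseline exponential rate giving the target event fraction under
    administrative censoring at ``horizon`` (Monte-Carlo + root find)."""
    rng = np.random.default_rng(12345)  # internal, fixed: a calibration table
    s = rng.normal(0.0, score_sd, size=n_mc)
    rel = np.exp(beta * s)

    def frac(rate: float) -> float:
        return float(np.mean(1.0 - np.exp(-rate * rel * horizon)))

    return float(brentq(lambda r: frac(r) - target_event_fraction, 1e-8, 10.0))


def simulate_bulk_cohort(
    config: SimulationConfig, marker_sets
) -> tuple[BulkCohort, GroundTruth]:
    """Bulk cohort whose expression and hazard carry planted scores.

    Per sample and marker set, a latent score s (log2 units over the
    control baseline) is drawn around the diagnosis-specific mean from
    ``bulk.score_effects`` (absent entries mean 0); every gene of the
    set is shifted by s on the log2 scale.  Graft-loss times are
    exponential with log-hazard = log(baseline) + sum beta_set * s_set,
    censored administratively at the horizon (plus optional uniform
    dropout).  Controls sit exactly at baseline (s = 0).
    """
    sets = []
    for ms in marker_sets:
        if hasattr(ms, "genes"):
            name, genes = ms.name, list(ms.genes)
        else:
            name, genes = ms[0], list(ms[1])
        if not genes:
            raise ValueError(f"marker set {name!r} is empty")
        sets.append((name, genes))
    if not sets:
        raise ValueError("at least one marker set is required")
    bulk = config.bulk
    if bulk.n_controls < 1:
        raise ValueError("need at least one control sample")
    rng = substream(config.seed, "bulk")

    marker_genes = [g for _, genes in sets for g in genes]
    gene_index = pd.Index(dict.fromkeys(marker_genes))
    n_background = max(config.n_genes - len(gene_index), 0)
    background = pd.Index([f"bg{i:04d}" for i in range(n_background)])
    genes = gene_index.append(background)

    diag_names = list(bulk.diagnosis_probs)
    diag_p = np.array([bulk.diagnosis_probs[d] for d in diag_names], dtype=float)
    diag_p = diag_p / diag_p.sum()

    n_cases = bulk.n_samples
    case_ids = [f"S{i:04d}" for i in range(n_cases)]
    control_ids = [f"NEPH{i}" for i in range(bulk.n_controls)]
    diagnoses = np.array(diag_names)[rng.choice(len(diag_names), size=n_cases, p=diag_p)]

    set_names = [name for name, _ in sets]
    score = pd.DataFrame(0.0, index=case_ids, columns=set_names)
    for name in set_names:
        effects = bulk.score_effects.get(name, {})
        mu = np.array([effects.get(d, 0.0) for d in diagnoses])
        score[name] = mu + rng.normal(0.0, bulk.score_sd, size=n_cases)

    # longitudinal patients: extra biopsies resolving TCMR -> NR with a
    # persistent score
    extra_rows = []
    extra_scores = []
    for i in range(bulk.n_longitudinal):
        pid = f"PL{i:03d}"
        for b in range(1, bulk.longitudinal_biopsies + 1):
            sid = f"{pid}_B{b}"
            diag = "TCMR" if b == 1 else "NR"
            extra_rows.append((sid, pid, diag, b))
            extra_scores.append(
                {name: bulk.persistence_score for name in set_names}
            )
    extra_ids = [r[0] for r in extra_rows]
    if extra_rows:
        score = pd.concat(
            [score, pd.DataFrame(extra_scores, index=extra_ids)]
        )

    all_case_ids = case_ids + extra_ids
    all_ids = all_case_ids + control_ids
    baseline = rng.normal(bulk.baseline_mean, bulk.baseline_sd, size=len(genes))
    expr = np.tile(baseline[:, None], (1, len(all_ids)))
    expr += rng.normal(0.0, bulk.noise_sd, size=expr.shape)
    for name, set_genes in sets:
        rows = genes.get_indexer(pd.Index(list(dict.fromkeys(set_genes))))
        s = score[name].reindex(all_case_ids).to_numpy()
        expr[np.ix_(rows, np.arange(len(all_case_ids)))] += s[None, :]
    expression = pd.DataFrame(expr, index=genes, columns=all_ids)

    hz = bulk.hazard
    lin = np.zeros(n_cases)
    for name in set_names:
        lin += hz.beta.get(name, 0.0) * score.loc[case_ids, name].to_numpy()
    rate = hz.baseline_rate * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)
    censor = np.full(n_cases, hz.censor_horizon_months)
    if hz.dropout_fraction > 0:
        drop = rng.random(n_cases) < hz.dropout_fraction
        censor = np.where(
            drop, rng.uniform(0, hz.censor_horizon_months, size=n_cases), censor
        )
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_cases)],
            "diagnosis": diagnoses,
            "time_months": time,
            "event": event,
            "biopsy_index": 1,
        },
        index=pd.Index(case_ids, name="sample"),
    )
    if extra_rows:
        # longitudinal patients: survival info attached to the first biopsy
        lt = rng.exponential(
            1.0
            / (
                hz.baseline_rate
                * np.exp(sum(hz.beta.get(n_, 0.0) for n_ in set_names)
                         * bulk.persistence_score)
            ),
            size=bulk.n_longitudinal,
        )
        extra_clin = pd.DataFrame(
            [
                {
                    "patient_id": pid,
                    "diagnosis": diag,
                    "time_months": min(lt[int(pid[2:])], hz.censor_horizon_months),
                    "event": int(lt[int(pid[2:])] <= hz.censor_horizon_months),
                    "biopsy_index": b,
                }
                for (sid, pid, diag, b) in extra_rows
            ],
            index=pd.Index(extra_ids, name="sample"),
        )
        clinical = pd.concat([clinical, extra_clin])

    cohort = BulkCohort(expression=expression, clinical=clinical,
                        controls=control_ids)
    truth = GroundTruth(sample_scores=score, hazard_beta=dict(hz.beta))
    return cohort, truth


def default_config(seed: int = 0) -> SimulationConfig:
    """The reference study design used throughout tests and examples.

    Eight populations emulating an allograft snRNA-seq experiment; the
    target injury state carries 20 exclusive 4x markers, its adjacent
    injury state has its own markers plus a handful shared with the
    target (planted in both at 4x, which the specificity filters must
    reject); spatial sections co-localize macrophages with the target
    injury state at ratio 2; the bulk cohort ties the target set's score
    to graft loss.
    """
    populations = [
        Population("PT Healthy", 0.30, "healthy"),
        Population("PT Injury 1", 0.10, "adjacent_injury"),
        Population("PT Injury 2", 0.08, "target_injury"),
        Population("TAL Healthy", 0.20, "healthy"),
        Population("TAL Injury", 0.08, "other"),
        Population("Macrophage", 0.10, "leukocyte"),
        Population("CD8 T", 0.08, "leukocyte"),
        Population("Fibroblast", 0.06, "other"),
    ]
    planted: dict = {}
    idx = 0

    def take(n):
        nonlocal idx
        block = list(range(idx, idx + n))
        idx += n
        return block

    tp_genes = take(20)
    shared = take(5)  # in both injury states: must NOT survive selection
    planted["PT Injury 2"] = [(g, 4.0) for g in tp_genes] + [(g, 4.0) for g in shared]
    planted["PT Injury 1"] = [(g, 4.0) for g in take(15)] + [
        (g, 4.0) for g in shared
    ]
    for pop in ("PT Healthy", "TAL Healthy", "TAL Injury", "Macrophage",
                "CD8 T", "Fibroblast"):
        planted[pop] = [(g, 4.0) for g in take(15)]

    beta = beta_for_median_split_hr(2.5, score_sd=1.0)
    return SimulationConfig(
        seed=seed,
        n_genes=2000,
        n_cells=5000,
        populations=populations,
        planted_markers=planted,
        nb_dispersion=2.0,
        library_size_range=(2000, 10000),
        spatial=SpatialConfig(
            field_size_um=2000.0,
            density_per_um2=0.005,
            niche_radius_um=25.0,
            enrichment={("PT Injury 2", "Macrophage"): 2.0},
            type_proportions={
                "PT Healthy": 0.45,
                "PT Injury 1": 0.05,
                "PT Injury 2": 0.02,
                "TAL Healthy": 0.25,
                "TAL Injury": 0.05,
                "Macrophage": 0.10,
                "CD8 T": 0.05,
                "Fibroblast": 0.03,
            },
        ),
        bulk=BulkConfig(
            n_samples=300,
            n_controls=4,
            # injury is elevated in rejection but overlaps NR heavily, and
            # ABMR carries injury too (injury signatures are not
            # rejection-type specific)
            score_effects={
                "PT Injury 2": {"TCMR": 0.75, "Mixed": 0.75, "ABMR": 0.5}
            },
            score_sd=1.0,
            hazard=HazardModel(
                baseline_rate=calibrate_baseline_rate(0.40, beta),
                beta={"PT Injury 2": beta},
            ),
        ),
    )
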