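"""Reproducible validation studies over the synthetic study designs.

Each function simulates the relevant data class under the reference
study conditions, runs the corresponding pipeline stage, and returns the
measured quantity together with the problem size.  They back both the
test suite and ``scripts/acceptance.py``, so the numbers reported there
are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from ._rng import substream
from .cohort import lognormalize
from .markers import MarkerQuery, select_markers
from .outcome import logrank_test, survival_by_score
from .pipeline import run_pipeline, small_config
from .scoring import score_samples
from .simulate import (
    BulkConfig,
    HazardModel,
    SimulationConfig,
    SpatialConfig,
    beta_for_median_split_hr,
    calibrate_baseline_rate,
    default_config,
    simulate_bulk_cohort,
    simulate_cell_cohort,
    simulate_spatial_sample,
)
from .spatial import direct_neighbor_test, ratio_at

__all__ = [
    "marker_recovery_study",
    "spatial_calibration_study",
    "csr_type_i_study",
    "scoring_study",
    "survival_power_study",
    "survival_null_study",
    "determinism_study",
]


def _derived_seeds(seed: int, n: int) -> np.ndarray:
    """n child seeds (< 2^31) deterministically derived from ``seed``."""
    return substream(seed, "study-seeds").integers(0, 2**31, size=n)


def marker_recovery_study(seed: int) -> dict:
    """Recovery of the planted exclusive markers of the target injury
    state from the reference 5,000-cell / 2,000-gene cohort."""
    config = default_config(seed)
    cohort, truth = simulate_cell_cohort(config)
    norm = lognormalize(cohort)
    query = MarkerQuery(target="PT Injury 2", adjacent="PT Injury 1")
    marker_set = select_markers(cohort, query, norm=norm)
    true_markers = set(truth.exclusive_markers("PT Injury 2"))
    selected = set(marker_set.genes)
    return {
        "n_true": len(true_markers),
        "n_selected": len(selected),
        "recovered": len(selected & true_markers),
        "false_positives": len(selected - true_markers),
        "sensitivity": len(selected & true_markers) / len(true_markers),
        "n_cells": cohort.n_cells,
        "marker_set": marker_set,
    }


def spatial_calibration_study(seed: int) -> dict:
    """Direct-neighbor ratio recovered from one planted rho=2 section."""
    config = default_config(seed)
    sample, truth = simulate_spatial_sample(config, "calibration")
    (pair, rho), = truth.spatial_ratios.items()
    ratio = ratio_at(sample, pair[0], pair[1], config.spatial.niche_radius_um)
    return {"ratio": ratio, "target": rho, "n_cells": sample.n_cells}


def _csr_config(seed: int) -> SimulationConfig:
    config = default_config(seed)
    spatial = replace(
        config.spatial,
        field_size_um=640.0,
        enrichment={},
    )
    return replace(config, spatial=spatial)


def csr_type_i_study(
    seed: int, n_replicates: int = 200, n_samples: int = 5, alpha: float = 0.05
) -> dict:
    """False-positive rate of the direct-neighbor test on CSR sections.

    Each replicate draws ``n_samples`` completely random ~2,000-cell
    sections and tests one (anchor, query) pair; under the null the
    rejection rate at ``alpha`` should sit at ``alpha``.
    """
    config = _csr_config(seed)
    pair = [("PT Healthy", "Macrophage")]
    rejections = 0
    ratios = []
    for rep in range(n_replicates):
        samples = [
            simulate_spatial_sample(config, f"rep{rep:03d}_s{i}")[0]
            for i in range(n_samples)
        ]
        result = direct_neighbor_test(samples, pair)
        ratios.extend(
            ratio_at(s, pair[0][0], pair[0][1], config.spatial.niche_radius_um)
            for s in samples
        )
        if result["tested"].iloc[0] and result["p"].iloc[0] < alpha:
            rejections += 1
    return {
        "type_i_error": rejections / n_replicates,
        "mean_ratio": float(np.mean(ratios)),
        "n_replicates": n_replicates,
    }


def _uniform_elevation_config(seed: int) -> SimulationConfig:
    """Every case sample carries exactly +1 log2 on the marker genes."""
    config = default_config(seed)
    bulk = replace(
        config.bulk,
        score_effects={"markers": {d: 1.0 for d in config.bulk.diagnosis_probs}},
        score_sd=0.0,
    )
    return replace(config, bulk=bulk)


def scoring_study(seed: int, n_marker_genes: int = 20) -> dict:
    """Control-mean-zero residual and recovery of a uniform 2x planted
    elevation (score should be 1.0 log2 units in every case sample)."""
    config = _uniform_elevation_config(seed)
    sets = [("markers", [f"gene{i:04d}" for i in range(n_marker_genes)])]
    cohort, _ = simulate_bulk_cohort(config, sets)
    scores = score_samples(cohort, sets)
    control_residual = float(
        scores.values.loc[cohort.controls].mean().abs().max()
    )
    case_scores = scores.values.drop(index=cohort.controls)["markers"]
    return {
        "control_mean_abs": control_residual,
        "mean_case_score": float(case_scores.mean()),
        "n_samples": len(case_scores),
    }


def _power_config(seed: int, hr: float = 2.5, event_fraction: float = 0.40,
                  n_samples: int = 300) -> SimulationConfig:
    beta = beta_for_median_split_hr(hr, score_sd=1.0)
    config = default_config(seed)
    bulk = BulkConfig(
        n_samples=n_samples,
        n_controls=4,
        score_effects={},
        score_sd=1.0,
        hazard=HazardModel(
            baseline_rate=calibrate_baseline_rate(event_fraction, beta),
            beta={"markers": beta},
        ),
    )
    return replace(config, n_genes=200, bulk=bulk)


def survival_power_study(seed: int, n_replicates: int = 100) -> dict:
    """Log-rank power for a hazard ratio of 2.5 between median-split
    strata at n=300 with ~40% events."""
    sets = [("markers", [f"gene{i:04d}" for i in range(20)])]
    seeds = _derived_seeds(seed, n_replicates)
    hits = 0
    event_fracs = []
    for child in seeds:
        config = _power_config(int(child))
        cohort, _ = simulate_bulk_cohort(config, sets)
        scores = score_samples(cohort, sets)
        s = scores.values.drop(index=cohort.controls)["markers"]
        med = float(np.median(s))
        cl = cohort.clinical
        above = cl.index[s.loc[cl.index] > med]
        below = cl.index[s.loc[cl.index] <= med]
        _, p = logrank_test(
            cl.loc[above, "time_months"], cl.loc[above, "event"],
            cl.loc[below, "time_months"], cl.loc[below, "event"],
        )
        event_fracs.append(cl["event"].mean())
        if p < 0.05:
            hits += 1
    return {
        "power": hits / n_replicates,
        "mean_event_fraction": float(np.mean(event_fracs)),
        "n_replicates": n_replicates,
    }


def survival_null_study(seed: int, n_cohorts: int = 200, n_sets: int = 5) -> dict:
    """Fraction of gene sets reaching fdr < 0.05 when no set is linked
    to the hazard (should not exceed the nominal rate by much)."""
    sets = [
        (f"set{k}", [f"gene{i:04d}" for i in range(20 * k, 20 * (k + 1))])
        for k in range(n_sets)
    ]
    seeds = _derived_seeds(seed, n_cohorts)
    flagged = 0
    total = 0
    for child in seeds:
        config = _power_config(int(child))
        config.bulk.hazard.beta = {}  # beta = 0: score unrelated to outcome
        cohort, _ = simulate_bulk_cohort(config, sets)
        scores = score_samples(cohort, sets)
        result = survival_by_score(cohort, scores, letters=False)
        fdr = result.tests.loc[result.tests["tested"], "fdr"]
        flagged += int((fdr < 0.05).sum())
        total += len(fdr)
    return {
        "fdr_positive_rate": flagged / total if total else float("nan"),
        "n_cohorts": n_cohorts,
        "n_tests": total,
    }


def determinism_study(seed: int, work_dir) -> dict:
    """Byte-identity of two full pipeline runs under one seed."""
    work = Path(work_dir)
    config = small_config(seed)
    run_pipeline(config, work / "run1")
    run_pipeline(config, work / "run2")
    files = sorted(
        p.relative_to(work / "run1")
        for p in (work / "run1").rglob("*")
        if p.is_file()
    )
    identical = bool(files) and all(
        (work / "run1" / f).read_bytes() == (work / "run2" / f).read_bytes()
        for f in files
    )
    return {"identical": identical, "n_files": len(files),
            "n_cells": config.n_cells}
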