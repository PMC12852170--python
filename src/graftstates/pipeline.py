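"""End-to-end pipeline: simulate -> DE -> markers -> score -> proximity
-> survival, with every stage's outputs written to disk.

The pipeline exists for two reasons: as a worked, reproducible example
of how the stages chain together, and as the surface on which full-run
determinism is verified (same seed, byte-identical output trees).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from . import io
from .cohort import lognormalize
from .dge import wilcoxon_de
from .markers import MarkerQuery, select_markers
from .outcome import survival_by_score
from .scoring import score_samples
from .simulate import (
    SimulationConfig,
    default_config,
    simulate_bulk_cohort,
    simulate_cell_cohort,
    simulate_spatial_sample,
)
from .spatial import DIRECT_NEIGHBOR_UM, direct_neighbor_test

__all__ = ["PipelineResult", "run_pipeline", "small_config"]


@dataclass
class PipelineResult:
    marker_set: object
    de_table: pd.DataFrame
    scores: pd.DataFrame
    proximity: pd.DataFrame
    survival: pd.DataFrame
    out_dir: Path


def small_config(seed: int = 0) -> SimulationConfig:
    """A reduced version of the reference design for quick full runs."""
    cfg = default_config(seed)
    spatial = replace(
        cfg.spatial, field_size_um=800.0, density_per_um2=0.005
    )
    bulk = replace(cfg.bulk, n_samples=200, n_longitudinal=6)
    return replace(cfg, n_cells=2000, n_genes=800, spatial=spatial, bulk=bulk)


def run_pipeline(
    config: SimulationConfig,
    out_dir,
    n_spatial_samples: int = 3,
    markers_k: int | None = None,
) -> PipelineResult:
    """Run every stage on one simulated study and write all outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- single-cell stage -------------------------------------------------
    cohort, truth = simulate_cell_cohort(config)
    io.write_cell_cohort(cohort, out / "cohort")
    io.write_ground_truth(truth, out / "cohort" / "ground_truth.json")
    norm = lognormalize(cohort)

    target = next(p.name for p in config.populations if p.role == "target_injury")
    adjacent = next(p.name for p in config.populations if p.role == "adjacent_injury")

    groups = list(config.group_names)
    cells_b = cohort.cells[(cohort.obs["group"] == groups[0]).to_numpy()]
    cells_a = cohort.cells[(cohort.obs["group"] == groups[1]).to_numpy()]
    de = wilcoxon_de(norm, cells_a, cells_b, group_a=groups[1], group_b=groups[0])
    de.table.rename_axis("gene").to_csv(out / "de_results.tsv", sep="\t")

    query = MarkerQuery(target=target, adjacent=adjacent)
    if markers_k is not None:
        query.k = markers_k
    marker_set = select_markers(cohort, query, norm=norm)
    io.write_gmt([marker_set], out / "markers.gmt")
    marker_set.audit.rename_axis("gene").to_csv(out / "marker_audit.tsv", sep="\t")

    # --- spatial stage -----------------------------------------------------
    samples = []
    for i in range(n_spatial_samples):
        sample, _ = simulate_spatial_sample(config, f"section{i + 1}")
        samples.append(sample)
    io.write_spatial_samples(samples, out / "cells.csv")
    pairs = list(config.spatial.enrichment) or [(target, "Macrophage")]
    proximity = direct_neighbor_test(samples, pairs, threshold=DIRECT_NEIGHBOR_UM)
    proximity.to_csv(out / "proximity_tests.tsv", sep="\t", index=False)

    # --- bulk stage --------------------------------------------------------
    bulk, bulk_truth = simulate_bulk_cohort(config, [marker_set])
    io.write_bulk_cohort(bulk, out / "bulk")
    scores = score_samples(bulk, [marker_set])
    scores.values.rename_axis("sample").to_csv(out / "scores.tsv", sep="\t")
    surv = survival_by_score(bulk, scores)
    surv.tests.to_csv(out / "survival.tsv", sep="\t")
    km_rows = []
    for (set_name, diag, stratum), curve in surv.km_curves.items():
        c = curve.copy()
        c.insert(0, "stratum", stratum)
        c.insert(0, "diagnosis", diag)
        c.insert(0, "set", set_name)
        km_rows.append(c)
    pd.concat(km_rows, ignore_index=True).to_csv(out / "km_curves.tsv", sep="\t",
                                                 index=False)
    return PipelineResult(
        marker_set=marker_set,
        de_table=de.table,
        scores=scores.values,
        proximity=proximity,
        survival=surv.tests,
        out_dir=out,
    )
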