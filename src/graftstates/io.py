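"""Readers and writers for the pipeline's on-disk formats.

Cell cohorts travel as a 10x-style MTX triplet (matrix.mtx genes x
cells, features.tsv, barcodes.tsv) plus a cells.csv metadata table;
spatial samples as a flat cells.csv; bulk cohorts as expression.tsv /
clinical.tsv / controls.txt; marker sets as GMT.  All result tables are
plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .cohort import CellCohort
from .markers import MarkerSet
from .scoring import BulkCohort
from .spatial import SpatialSample

__all__ = [
    "write_cell_cohort",
    "read_cell_cohort",
    "write_spatial_samples",
    "read_spatial_samples",
    "write_bulk_cohort",
    "read_bulk_cohort",
    "write_gmt",
    "read_gmt",
    "write_ground_truth",
]


def write_cell_cohort(cohort: CellCohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # 10x convention stores genes x cells
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(cohort.counts.T), field="integer")
    pd.Series(cohort.genes).to_csv(out / "features.tsv", sep="\t", index=False,
                                   header=False)
    pd.Series(cohort.cells).to_csv(out / "barcodes.tsv", sep="\t", index=False,
                                   header=False)
    cohort.obs.rename_axis("cell").to_csv(out / "cells.csv")


def read_cell_cohort(in_dir) -> CellCohort:
    src = Path(in_dir)
    counts = sp.csr_matrix(scipy.io.mmread(src / "matrix.mtx").T)
    genes = pd.read_csv(src / "features.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(src / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.read_csv(src / "cells.csv", index_col=0)
    obs.index.name = None
    return CellCohort(counts=counts, genes=pd.Index(genes), cells=pd.Index(cells),
                      obs=obs)


def write_spatial_samples(samples: list[SpatialSample], path) -> None:
    frames = []
    for s in samples:
        df = s.cells.copy()
        df["sample_id"] = s.sample_id
        df["group"] = s.group
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spatial_samples(path) -> list[SpatialSample]:
    table = pd.read_csv(path)
    samples = []
    for sid, sub in table.groupby("sample_id", sort=True):
        group = sub["group"].iloc[0]
        samples.append(
            SpatialSample(
                cells=sub[["cell_id", "x_um", "y_um", "cell_type"]].reset_index(
                    drop=True
                ),
                sample_id=str(sid),
                group=str(group),
            )
        )
    return samples


def write_bulk_cohort(cohort: BulkCohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.expression.rename_axis("gene").to_csv(out / "expression.tsv", sep="\t")
    cohort.clinical.rename_axis("sample").to_csv(out / "clinical.tsv", sep="\t")
    (out / "controls.txt").write_text("\n".join(cohort.controls) + "\n")


def read_bulk_cohort(in_dir) -> BulkCohort:
    src = Path(in_dir)
    expression = pd.read_csv(src / "expression.tsv", sep="\t", index_col=0)
    clinical = pd.read_csv(src / "clinical.tsv", sep="\t", index_col=0)
    controls = [
        line.strip()
        for line in (src / "controls.txt").read_text().splitlines()
        if line.strip()
    ]
    return BulkCohort(expression=expression, clinical=clinical, controls=controls)


def write_gmt(sets: list[MarkerSet], path, description: str = "") -> None:
    lines = []
    for s in sets:
        lines.append("\t".join([s.name, description or s.name, *s.genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path) -> list[tuple[str, list[str]]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        out.append((parts[0], parts[2:]))
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_ground_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True,
                                     default=_jsonable))
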