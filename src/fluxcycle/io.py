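"""Reading and writing the package's plain-text formats.

Velocity samples travel as TSV tables (cell_id, x, y, vx, vy; C locale) with
a JSON metadata sidecar; gridded fields are exported in long format
(x, y, field, value). A minimal expression-matrix filter reproduces the
standard "cells with too few detected genes / genes detected in too few
cells" preprocessing applied to single-cell TPM tables.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import StateGrid
from .systems import VelocitySampleSet

__all__ = [
    "read_state_velocity_table",
    "write_state_velocity_table",
    "export_grid_fields",
    "write_grn_edges",
    "write_action_path",
    "ExpressionMatrix",
    "FilterReport",
    "filter_cells_genes",
]

_REQUIRED = ("x", "y", "vx", "vy")


def read_state_velocity_table(path) -> VelocitySampleSet:
    """Read a TSV/CSV state-velocity table (header with x, y, vx, vy).

    Extra columns are preserved as an ``annotations`` DataFrame attached to
    the returned sample set; non-numeric or non-finite entries raise with
    the offending row number (0-based, excluding the header).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    num = df[list(_REQUIRED)].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1) | ~np.isfinite(num).all(axis=1)
    if bad.any():
        row = int(np.argmax(bad.values))
        raise ValueError(f"{path}: non-numeric or non-finite value in data row {row}")
    samples = VelocitySampleSet(
        positions=num[["x", "y"]].to_numpy(),
        velocities=num[["vx", "vy"]].to_numpy(),
        source=str(path),
    )
    extra = [c for c in df.columns if c not in _REQUIRED]
    samples.annotations = df[extra] if extra else None  # type: ignore[attr-defined]
    meta_path = path.with_suffix(path.suffix + ".json")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        samples.noise_sd = float(meta.get("noise_sd", 0.0))
        samples.seed = meta.get("seed")
        samples.source = meta.get("system_kind", samples.source)
    return samples


def write_state_velocity_table(samples: VelocitySampleSet, path, metadata: dict | None = None) -> Path:
    """Write a sample set as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "cell_id": [f"cell_{i}" for i in range(samples.n)],
        "x": samples.positions[:, 0],
        "y": samples.positions[:, 1],
        "vx": samples.velocities[:, 0],
        "vy": samples.velocities[:, 1],
    })
    ann = getattr(samples, "annotations", None)
    if ann is not None:
        for c in ann.columns:
            if c != "cell_id":
                df[c] = ann[c].to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "seed": samples.seed,
        "noise_sd": samples.noise_sd,
        "system_kind": samples.source,
        "n": samples.n,
    }
    if metadata:
        meta.update(metadata)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return path


def export_grid_fields(grid: StateGrid, fields: dict[str, np.ndarray], path) -> Path:
    """Export scalar grid fields in TSV long format (x, y, field, value)."""
    xx, yy = grid.meshgrid()
    frames = []
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape != (grid.ny, grid.nx):
            raise ValueError(f"field {name!r} has shape {arr.shape}, expected {(grid.ny, grid.nx)}")
        frames.append(pd.DataFrame({
            "x": xx.ravel(), "y": yy.ravel(),
            "field": name, "value": arr.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return Path(path)


def write_grn_edges(edges, path, graphml_path=None) -> Path:
    """Write inferred interactions as TSV (and optionally GraphML)."""
    df = pd.DataFrame([{
        "source": e.source, "target": e.target, "sign": e.sign,
        "mean_jacobian": e.mean_jacobian, "support": e.support,
    } for e in edges])
    df.to_csv(path, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        from .perturbation_grn import grn_to_graph

        nx.write_graphml(grn_to_graph(edges), graphml_path)
    return Path(path)


def write_action_path(path_obj, path) -> Path:
    """Write a least-action path as TSV (index, t, x, y)."""
    df = pd.DataFrame({
        "index": np.arange(len(path_obj.waypoints)),
        "t": path_obj.times,
        "x": path_obj.waypoints[:, 0],
        "y": path_obj.waypoints[:, 1],
    })
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


@dataclass
class ExpressionMatrix:
    """Genes x cells numeric matrix (TPM or counts) with unique ids."""

    values: pd.DataFrame     # index = gene ids, columns = cell ids

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique or not v.columns.is_unique:
            raise ValueError("gene and cell ids must be unique")
        if (v.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class FilterReport:
    n_cells_removed: int
    n_genes_removed: int
    n_cells_kept: int
    n_genes_kept: int


def filter_cells_genes(
    mat: ExpressionMatrix,
    min_genes_per_cell: int,
    min_cells_per_gene: int,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Two-stage detection filter: cells first, then genes.

    A gene is "detected" in a cell when its value is strictly positive.
    Cells with fewer than ``min_genes_per_cell`` detected genes are removed
    first; genes detected in fewer than ``min_cells_per_gene`` of the
    remaining cells are removed second. An empty result is returned with a
    warning rather than an error.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("thresholds must be >= 0")
    v = mat.values
    detected = v > 0
    keep_cells = detected.sum(axis=0) >= min_genes_per_cell
    v2 = v.loc[:, keep_cells]
    keep_genes = (v2 > 0).sum(axis=1) >= min_cells_per_gene
    v3 = v2.loc[keep_genes]
    report = FilterReport(
        n_cells_removed=int((~keep_cells).sum()),
        n_genes_removed=int((~keep_genes).sum()),
        n_cells_kept=v3.shape[1],
        n_genes_kept=v3.shape[0],
    )
    if v3.size == 0:
        import warnings

        warnings.warn("filtering removed everything", stacklevel=2)
    return ExpressionMatrix(v3), report
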