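"""Two-stage window-size analysis.

Stage one sweeps LSCTP maps over a list of primary window diameters (masks
harmonized to the largest diameter so every map covers the same vertices).
Stage two maps the local variability of each LSCTP map — the standard
deviation of mean_r within a second sliding window — and averages it per
primary diameter.  High local SD marks anatomical differentiation; the
primary diameter maximizing it is the natural window-size choice, reported
as an argmax alongside the full table (the final choice combines the table
with visual inspection of the maps).

Undefined SD cells (windows holding fewer than 2 included vertices) are
excluded from averages rather than zero-filled: zero-filling would bias the
selection toward large windows.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CohortThickness,
    ParameterError,
    TriangleMesh,
    VertexScalarMap,
)
from .core import LSCTPMap, harmonize_masks, lsctp_map
from .windowing import all_window_members

__all__ = ["lsctp_sweep", "local_sd_map", "mean_sd_table", "WindowSelectionTable",
           "default_diameter_schedule"]


def default_diameter_schedule() -> list:
    """The default primary-diameter schedule: 2..31 mm inclusive (30 maps)."""
    return [float(d) for d in range(2, 32)]


def lsctp_sweep(
    cohort: CohortThickness,
    mesh: TriangleMesh,
    diameters,
    *,
    min_members: int = 3,
    method: str = "pearson",
) -> list:
    """One LSCTP map per diameter, masks harmonized to the largest diameter."""
    diameters = [float(d) for d in diameters]
    if not diameters:
        raise ParameterError("need at least one diameter")
    if any(b <= a for a, b in zip(diameters, diameters[1:])):
        raise ParameterError("diameters must be sorted strictly ascending")
    maps = [
        lsctp_map(cohort, mesh, d, min_members=min_members, method=method)
        for d in diameters
    ]
    return harmonize_masks(maps)


def local_sd_map(lmap: LSCTPMap, mesh: TriangleMesh, sd_diameter: float) -> VertexScalarMap:
    """Per-vertex standard deviation of mean_r over the included window members.

    Vertices whose SD window holds fewer than 2 included members are marked
    undefined (NaN).  Population (divide-by-n) SD, matching the variance
    convention used elsewhere in the package.
    """
    if sd_diameter <= 0:
        raise ParameterError(f"sd window diameter must be > 0, got {sd_diameter}")
    if lmap.included.n_members < 1:
        raise ParameterError("LSCTP map has no included vertex")
    if lmap.n_vertices != mesh.n_vertices:
        raise ParameterError("map and mesh differ in vertex count")
    windows = all_window_members(mesh, sd_diameter)
    included = lmap.included.mask
    out = np.full(mesh.n_vertices, np.nan)
    for v in range(mesh.n_vertices):
        members = windows[v]
        members = members[included[members]]
        if members.size < 2:
            continue
        out[v] = np.std(lmap.mean_r[members])
    return VertexScalarMap(values=out, mesh_name=mesh.name, allow_nan=True)


@dataclass(eq=False)
class WindowSelectionTable:
    """Mean local SD per (primary diameter, SD diameter) plus the argmax
    primary diameter for each SD diameter."""

    table: pd.DataFrame   # rows = primary diameter, columns = sd diameter
    argmax: dict          # sd diameter -> primary diameter with highest mean SD

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# mean local SD of LSCTP (r scale) per primary window "
                     "diameter (rows, mm) and SD window diameter (columns, mm)\n")
            fh.write("# argmax per SD diameter: "
                     + ", ".join(f"{k:g} mm -> {v:g} mm" for k, v in self.argmax.items())
                     + "\n")
            self.table.to_csv(fh, sep="\t", na_rep="NA")


def mean_sd_table(sweep, mesh: TriangleMesh, sd_diameters) -> WindowSelectionTable:
    """Average the defined local-SD values of each map in a sweep.

    Cells with no defined SD value are NaN (flagged missing, never 0).
    """
    sweep = list(sweep)
    if not sweep:
        raise ParameterError("empty sweep")
    sd_diameters = [float(d) for d in sd_diameters]
    cells = {}
    for lmap in sweep:
        row = {}
        for sd_d in sd_diameters:
            if lmap.included.n_members < 1:
                row[sd_d] = np.nan
                continue
            sd = local_sd_map(lmap, mesh, sd_d).values
            defined = np.isfinite(sd)
            row[sd_d] = float(np.mean(sd[defined])) if defined.any() else np.nan
        cells[lmap.diameter] = row
    table = pd.DataFrame.from_dict(cells, orient="index").sort_index()
    table.index.name = "primary_diameter_mm"
    table.columns.name = "sd_diameter_mm"
    argmax = {
        sd_d: float(table[sd_d].idxmax())
        for sd_d in sd_diameters
        if table[sd_d].notna().any()
    }
    return WindowSelectionTable(table=table, argmax=argmax)
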