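"""ROI/network summaries of LSCTP maps.

Averages LSCTP per named parcel (e.g. the seven resting-state functional
networks, or histological area masks), computes the corresponding null ROI
means from Monte-Carlo replicate maps, and checks how stable the ROI rank
order is across window sizes.

ROI means are computed on the r scale (the scale LSCTP maps are plotted
on); vertices excluded by the map's inclusion mask are dropped from the
denominators, never zero-filled.  A z-scale option exists for statistical
follow-up.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ParameterError, TriangleMesh, VertexMask
from .core import LSCTPMap
from . import io as _io

__all__ = ["ParcellationMasks", "roi_mean_lsctp", "null_roi_means", "rank_by_window"]


@dataclass(eq=False)
class ParcellationMasks:
    """An ordered, uniquely named collection of vertex masks on one mesh."""

    masks: dict = field(default_factory=dict)  # name -> VertexMask

    def __post_init__(self):
        sizes = {m.n_vertices for m in self.masks.values()}
        if len(sizes) > 1:
            raise ParameterError("parcellation masks differ in vertex count")

    @classmethod
    def from_labels(cls, paths, n_vertices: int, names=None) -> "ParcellationMasks":
        """Load one FreeSurfer label (or plain index list) per ROI."""
        masks = {}
        for k, p in enumerate(paths):
            m = _io.read_label(p, n_vertices)
            name = names[k] if names else m.label
            if name in masks:
                raise ParameterError(f"duplicate ROI name {name!r}")
            masks[name] = m
        return cls(masks=masks)

    @classmethod
    def from_tsv(cls, path, n_vertices: int) -> "ParcellationMasks":
        """Load a (vertex, roi_name) two-column TSV."""
        table = pd.read_csv(path, sep="\t", comment="#",
                            names=["vertex", "roi"], header=None)
        masks = {}
        for name, grp in table.groupby("roi", sort=False):
            masks[str(name)] = VertexMask.from_indices(
                n_vertices, grp["vertex"].to_numpy(), label=str(name)
            )
        return cls(masks=masks)

    @property
    def names(self) -> list:
        return list(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    def __getitem__(self, name: str) -> VertexMask:
        return self.masks[name]


def roi_mean_lsctp(
    lmap: LSCTPMap, rois: ParcellationMasks, scale: str = "r"
) -> pd.DataFrame:
    """Mean LSCTP over (roi ∩ included) per ROI.

    Returns a DataFrame indexed by ROI name with columns ``mean`` and
    ``n_vertices``; an ROI with empty intersection gets NaN (flagged
    missing).  ``scale="z"`` averages on the Fisher-z scale instead.
    """
    if scale not in {"r", "z"}:
        raise ParameterError(f"scale must be 'r' or 'z', got {scale!r}")
    rows = {}
    for name in rois.names:
        m = rois[name]
        if m.n_vertices != lmap.n_vertices:
            raise ParameterError(f"ROI {name!r} does not match the map's mesh")
        joint = m.mask & lmap.included.mask
        n = int(joint.sum())
        if n == 0:
            rows[name] = {"mean": np.nan, "n_vertices": 0}
            continue
        vals = lmap.mean_r[joint]
        if scale == "z":
            vals = np.arctanh(np.clip(vals, -1 + 1e-7, 1 - 1e-7))
        rows[name] = {"mean": float(vals.mean()), "n_vertices": n}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "roi"
    return table


def null_roi_means(null_maps, rois: ParcellationMasks) -> pd.DataFrame:
    """Grand-mean null LSCTP per ROI from Monte-Carlo replicate maps.

    For each replicate map the per-ROI mean is taken; the replicate means
    are then averaged again per ROI (the "grand mean" — with R replicates
    and K ROIs this summarizes R*K cell means into K numbers).
    """
    null_maps = list(null_maps)
    if not null_maps:
        raise ParameterError("need at least one replicate map")
    per_rep = pd.concat(
        [roi_mean_lsctp(m, rois)["mean"] for m in null_maps], axis=1
    )
    out = pd.DataFrame(
        {
            "grand_mean": per_rep.mean(axis=1),
            "sd_across_replicates": per_rep.std(axis=1, ddof=1),
            "n_replicates": per_rep.notna().sum(axis=1),
        }
    )
    out.index.name = "roi"
    return out


def rank_by_window(tables: dict):
    """Rank ROIs (1 = highest mean) within each window diameter.

    ``tables`` maps diameter -> the output of :func:`roi_mean_lsctp` (or
    any object with a ``mean`` column / Series over a shared ROI set).
    Returns ``(rank_matrix, n_unstable)`` where ``rank_matrix`` has ROIs as
    rows and diameters as columns (ties get the shared average rank) and
    ``n_unstable`` counts ROIs whose rank varies across diameters.
    """
    if not tables:
        raise ParameterError("need at least one diameter table")
    series = {}
    roi_sets = set()
    for d, t in tables.items():
        s = t["mean"] if isinstance(t, pd.DataFrame) else pd.Series(t)
        series[float(d)] = s
        roi_sets.add(tuple(sorted(s.index)))
    if len(roi_sets) > 1:
        raise ParameterError("all diameters must cover the same ROI set")
    means = pd.DataFrame(series).sort_index(axis=1)
    ranks = means.rank(ascending=False, axis=0, method="average")
    unstable = int((ranks.nunique(axis=1) > 1).sum())
    ranks.index.name = "roi"
    ranks.columns.name = "diameter_mm"
    return ranks, unstable
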