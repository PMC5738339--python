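"""Monte-Carlo null distributions for LSCTP maps.

Pipeline (per replicate): each subject's thickness is spatially shuffled
within the gray-matter mask (an unrestricted uniform permutation of the
masked values, independent per subject); optionally each shuffled map is
then nearest-neighbor smoothed until its estimated FWHM matches that
subject's true-data FWHM (shuffling destroys the natural smoothness of the
data, and an unsmoothed null produces far too liberal thresholds); LSCTP
maps are computed at every requested window diameter; per-vertex null
values are pooled globally — across vertices and replicates — into one
empirical distribution per diameter, from which a single critical LSCTP
per window size is read off.

Pooling is global rather than per-vertex because one critical value per
window size is reported; per-vertex nulls at extreme tail probabilities
would need orders of magnitude more replicates.

Seed scheme: a splittable counter derivation (base_seed, replicate,
subject), so per-subject shuffles are independent and every run is exactly
reproducible from the base seed.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (
    CohortThickness,
    LSCTPError,
    ParameterError,
    TriangleMesh,
    VertexMask,
    VertexScalarMap,
)
from .core import LSCTPMap, lsctp_map
from .smoothness import map_smoothness, smooth_to_target
from .windowing import all_window_members, build_neighbor_graph

__all__ = [
    "NullDistribution",
    "CriticalThreshold",
    "NullSimulationError",
    "ResolutionWarning",
    "shuffle_within_mask",
    "simulate_null",
    "critical_value",
    "threshold_map",
    "thresholds_table",
]

logger = logging.getLogger(__name__)


class NullSimulationError(LSCTPError):
    """A Monte-Carlo replicate could not be completed."""


class ResolutionWarning(UserWarning):
    """The requested tail probability is beyond the empirical resolution."""


@dataclass(eq=False)
class NullDistribution:
    """Pooled null LSCTP values for one window diameter."""

    diameter: float
    null_values: np.ndarray
    n_replicates: int
    seeds: list
    smoothed: bool
    iterations_per_subject: list  # one list of per-subject N per replicate

    def __post_init__(self):
        self.null_values = np.asarray(self.null_values, dtype=np.float64)
        if self.null_values.size == 0:
            raise ParameterError("a null distribution may not be empty")
        if self.n_replicates < 1:
            raise ParameterError("need at least one replicate")
        if len(self.seeds) != self.n_replicates:
            raise ParameterError("one seed per replicate required")

    @property
    def n_values(self) -> int:
        return self.null_values.size


@dataclass(eq=False)
class CriticalThreshold:
    """An empirical upper-tail critical LSCTP value.

    ``resolvable`` is False when the requested p lies beyond the resolution
    of the finite null sample, in which case ``value`` is the maximum null
    value observed.
    """

    value: float
    p: float
    resolvable: bool = True


def _seed_sequence(base_seed, replicate: int, subject: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(base_seed, spawn_key=(replicate, subject))


def shuffle_within_mask(vmap: VertexScalarMap, mask: VertexMask, seed) -> VertexScalarMap:
    """Uniform random permutation of the masked values; the rest untouched."""
    if mask.n_members == 0:
        raise ParameterError("cannot shuffle within an empty mask")
    if mask.n_vertices != vmap.n_vertices:
        raise ParameterError("mask and map differ in vertex count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = vmap.values.copy()
    idx = mask.indices
    values[idx] = values[idx][rng.permutation(idx.size)]
    return VertexScalarMap(values=values, mesh_name=vmap.mesh_name,
                           subject_id=vmap.subject_id)


def simulate_null(
    cohort: CohortThickness,
    mesh: TriangleMesh,
    mask: VertexMask,
    diameters,
    n_replicates: int = 20,
    match_smoothness: bool = True,
    base_seed=0,
    max_smooth_iterations: int = 64,
    min_members: int = 3,
    return_maps: bool = False,
):
    """Run the full Monte-Carlo null pipeline.

    Returns a list of :class:`NullDistribution`, one per diameter (order of
    ``diameters``).  With ``return_maps=True`` a second value is returned:
    ``{diameter: [LSCTPMap per replicate]}`` for ROI-level null summaries.
    """
    diameters = [float(d) for d in diameters]
    if any(d <= 0 for d in diameters):
        raise ParameterError("window diameters must be > 0")
    if n_replicates < 1:
        raise ParameterError("need at least one replicate")
    if cohort.n_vertices != mesh.n_vertices or mask.n_vertices != mesh.n_vertices:
        raise ParameterError("cohort, mesh and mask must share one vertex count")
    graph = build_neighbor_graph(mesh)
    windows = {d: all_window_members(mesh, d) for d in diameters}
    true_fwhm = None
    if match_smoothness:
        true_fwhm = [
            map_smoothness(graph, VertexScalarMap(row), mask).fwhm
            for row in cohort.matrix
        ]
    pooled = {d: [] for d in diameters}
    maps_by_diameter = {d: [] for d in diameters}
    rep_seeds, iters_per_rep = [], []
    for rep in range(n_replicates):
        rep_seeds.append(int(_seed_sequence(base_seed, rep, 0).generate_state(1)[0]))
        shuffled = np.array(cohort.matrix)
        iterations = []
        for s in range(cohort.n_subjects):
            rng = np.random.default_rng(_seed_sequence(base_seed, rep, s))
            smap = shuffle_within_mask(
                VertexScalarMap(shuffled[s], subject_id=cohort.subject_ids[s]),
                mask, rng,
            )
            if match_smoothness:
                try:
                    smap, n_it = smooth_to_target(
                        graph, smap, true_fwhm[s], max_smooth_iterations, mask
                    )
                except LSCTPError as exc:
                    raise NullSimulationError(
                        f"replicate {rep}: smoothness matching failed for subject "
                        f"{cohort.subject_ids[s]!r}: {exc}"
                    ) from exc
            else:
                n_it = 0
            iterations.append(n_it)
            shuffled[s] = smap.values
        iters_per_rep.append(iterations)
        null_cohort = CohortThickness(matrix=shuffled,
                                      subject_ids=list(cohort.subject_ids))
        for d in diameters:
            nmap = lsctp_map(null_cohort, mesh, d, min_members=min_members,
                             windows=windows[d])
            pooled[d].append(nmap.mean_r[nmap.included.mask & mask.mask])
            if return_maps:
                maps_by_diameter[d].append(nmap)
        logger.info("null replicate %d/%d done (mean N=%.2f)",
                    rep + 1, n_replicates, float(np.mean(iterations)))
    nulls = [
        NullDistribution(
            diameter=d,
            null_values=np.concatenate(pooled[d]),
            n_replicates=n_replicates,
            seeds=rep_seeds,
            smoothed=match_smoothness,
            iterations_per_subject=iters_per_rep,
        )
        for d in diameters
    ]
    if return_maps:
        return nulls, maps_by_diameter
    return nulls


def critical_value(null: NullDistribution, p: float) -> CriticalThreshold:
    """Empirical one-sided upper-tail critical LSCTP value.

    Uses the plus-one permutation convention: the threshold is the smallest
    observed value t with (#{null > t} + 1) / (n + 1) <= p, which never
    yields an empirical p-value of exactly zero.  When p < 1/(n+1) the
    quantile is beyond the resolution of the null sample; the maximum null
    value is returned flagged as unresolvable (with a warning).
    """
    if not 0.0 < p < 1.0:
        raise ParameterError(f"tail probability must be in (0, 1), got {p}")
    a = np.sort(null.null_values)
    n = a.size
    m = int(math.floor(p * (n + 1) - 1 + 1e-9))
    if m < 0:
        warnings.warn(
            f"p={p:g} is beyond the resolution of {n} null values "
            f"(minimum attainable p is {1.0 / (n + 1):.3g}); returning the "
            "maximum null value",
            ResolutionWarning,
            stacklevel=2,
        )
        return CriticalThreshold(value=float(a[-1]), p=p, resolvable=False)
    m = min(m, n - 1)
    return CriticalThreshold(value=float(a[n - m - 1]), p=p, resolvable=True)


def threshold_map(lmap: LSCTPMap, threshold) -> LSCTPMap:
    """Remove vertices with mean_r below ``threshold`` from the inclusion mask.

    ``threshold`` may be a float or a :class:`CriticalThreshold`.  Values
    themselves are untouched; NaN is written where a vertex drops out.
    """
    t = threshold.value if isinstance(threshold, CriticalThreshold) else float(threshold)
    if not math.isfinite(t):
        raise ParameterError(f"threshold must be finite, got {t}")
    keep = lmap.included.mask & ~(np.nan_to_num(lmap.mean_r, nan=-np.inf) < t)
    included = VertexMask(keep, label=lmap.included.label)
    return replace(lmap, mean_r=np.where(keep, lmap.mean_r, np.nan), included=included)


def thresholds_table(nulls, ps) -> pd.DataFrame:
    """Critical-threshold table: rows = window diameter, columns = p level."""
    rows = {}
    for null in nulls:
        rows[null.diameter] = {
            f"p<{p:g}": critical_value(null, p).value for p in ps
        }
        rows[null.diameter]["smoothed"] = null.smoothed
        rows[null.diameter]["n_null_values"] = null.n_values
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "diameter_mm"
    return table
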