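"""The LSCTP statistic: per-vertex all-pairs inter-subject correlation of
windowed thickness profiles, averaged on the Fisher-z scale.

For a cohort of n subjects, each vertex yields n(n-1)/2 Pearson
correlations between subjects' thickness profiles over the window members.
These are averaged as tanh(mean(atanh(r))) and reported on the r scale,
which is the scale on which maps are thresholded and colored.

Exclusion rule: a vertex is excluded when (a) any subject has a thickness
of exactly zero anywhere in the window, (b) the window holds fewer than
``min_members`` vertices (default 3, the smallest count yielding a
nondegenerate correlation), or (c) some subject's windowed profile is
constant (zero variance without zeros — counted separately in the log).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .model import (
    CohortThickness,
    DimensionError,
    InsufficientDataError,
    InvariantError,
    ParameterError,
    TriangleMesh,
    UndefinedCorrelationError,
    VertexMask,
)
from .windowing import all_window_members

__all__ = [
    "LSCTPMap",
    "pairwise_profile_correlations",
    "fisher_average",
    "lsctp_map",
    "harmonize_masks",
]

logger = logging.getLogger(__name__)

FISHER_CLAMP = 1e-7  # |r| clipped to 1 - FISHER_CLAMP before atanh


@dataclass(eq=False)
class LSCTPMap:
    """Per-vertex mean inter-subject profile correlation.

    ``mean_r`` is NaN at excluded vertices; ``included`` records the
    inclusion mask; ``exclusion_counts`` tallies why vertices were dropped.
    """

    mean_r: np.ndarray
    included: VertexMask
    diameter: float
    n_subjects: int
    exclusion_counts: dict = None

    def __post_init__(self):
        self.mean_r = np.asarray(self.mean_r, dtype=np.float64)
        if self.diameter <= 0:
            raise InvariantError(f"window diameter must be > 0, got {self.diameter}")
        if self.mean_r.shape[0] != self.included.n_vertices:
            raise DimensionError("mean_r and inclusion mask differ in length")
        if self.n_subjects < 2:
            raise InvariantError("LSCTP needs at least 2 subjects")
        defined = np.isfinite(self.mean_r)
        if not (defined == self.included.mask).all():
            raise InvariantError("mean_r must be defined exactly where included")
        if defined.any() and (np.abs(self.mean_r[defined]) > 1).any():
            raise InvariantError("mean correlations must lie in [-1, 1]")
        if self.exclusion_counts is None:
            self.exclusion_counts = {}

    @property
    def n_vertices(self) -> int:
        return self.mean_r.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n_subjects * (self.n_subjects - 1) // 2


def pairwise_profile_correlations(
    window_data, subject_ids=None, method: str = "pearson"
) -> np.ndarray:
    """All unordered pairwise correlations between rows of a subjects x
    window-vertices matrix, in lexicographic pair order (0-1, 0-2, ..., 1-2, ...).
    """
    X = np.asarray(window_data, dtype=np.float64)
    if X.ndim != 2:
        raise DimensionError(f"window data must be 2-D, got shape {X.shape}")
    n, m = X.shape
    if n < 2:
        raise InsufficientDataError(f"need at least 2 subjects, got {n}")
    if m < 3:
        raise InsufficientDataError(f"need at least 3 window vertices, got {m}")
    if method == "spearman":
        X = np.vstack([rankdata(row) for row in X])
    elif method != "pearson":
        raise ParameterError(f"unknown correlation method {method!r}")
    sd = X.std(axis=1)
    if (sd == 0).any():
        k = int(np.flatnonzero(sd == 0)[0])
        subject = subject_ids[k] if subject_ids is not None else k
        raise UndefinedCorrelationError(
            f"constant windowed profile for subject {subject!r}: correlation undefined",
            subject=subject,
        )
    corr = np.corrcoef(X)
    iu = np.triu_indices(n, k=1)
    return corr[iu]


def fisher_average(correlations) -> float:
    """tanh of the mean atanh(r), with |r| clamped to 1 - 1e-7.

    The clamp keeps identical profiles (r = 1 exactly) from producing
    infinite z values; the result always lies strictly inside (-1, 1).
    """
    r = np.asarray(correlations, dtype=np.float64)
    if r.size == 0:
        raise ParameterError("cannot Fisher-average an empty list of correlations")
    if (np.abs(r) > 1 + 1e-12).any() or not np.isfinite(r).all():
        raise ParameterError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(r, -1 + FISHER_CLAMP, 1 - FISHER_CLAMP))
    return float(np.tanh(z.mean()))


def lsctp_map(
    cohort: CohortThickness,
    mesh: TriangleMesh,
    diameter: float,
    *,
    min_members: int = 3,
    method: str = "pearson",
    windows=None,
) -> LSCTPMap:
    """Compute the LSCTP map of a cohort at one window diameter.

    ``windows`` may carry precomputed per-vertex member lists (as returned
    by :func:`lsctp.windowing.all_window_members`) to amortize the KD-tree
    queries over repeated calls on the same mesh.
    """
    if diameter <= 0:
        raise ParameterError(f"window diameter must be > 0, got {diameter}")
    if cohort.n_vertices != mesh.n_vertices:
        raise DimensionError(
            f"cohort has {cohort.n_vertices} columns for a mesh of "
            f"{mesh.n_vertices} vertices"
        )
    if windows is None:
        windows = all_window_members(mesh, diameter)
    matrix = cohort.matrix
    zero_cols = (matrix == 0).any(axis=0)  # vertex poisons every window containing it
    V = mesh.n_vertices
    mean_r = np.full(V, np.nan)
    counts = {"zero_thickness": 0, "too_few_members": 0, "constant_profile": 0}
    for v in range(V):
        members = windows[v]
        if members.shape[0] < min_members:
            counts["too_few_members"] += 1
            continue
        if zero_cols[members].any():
            counts["zero_thickness"] += 1
            continue
        sub = matrix[:, members]
        if method == "spearman":
            sub = np.vstack([rankdata(row) for row in sub])
        sd = sub.std(axis=1)
        if (sd == 0).any():
            counts["constant_profile"] += 1
            continue
        corr = np.corrcoef(sub)
        iu = np.triu_indices(cohort.n_subjects, k=1)
        mean_r[v] = fisher_average(corr[iu])
    included = VertexMask(np.isfinite(mean_r), label=f"lsctp-included-{diameter}mm")
    if included.n_members == 0:
        warnings.warn(
            f"all {V} vertices excluded at diameter {diameter} mm", stacklevel=2
        )
    logger.info(
        "LSCTP map at %.3g mm: %d/%d vertices included (excluded: %s)",
        diameter, included.n_members, V, counts,
    )
    return LSCTPMap(
        mean_r=mean_r,
        included=included,
        diameter=float(diameter),
        n_subjects=cohort.n_subjects,
        exclusion_counts=counts,
    )


def harmonize_masks(maps) -> list:
    """Mask every map in a multi-diameter family to the largest-diameter mask.

    The exclusion rule removes more vertices at larger diameters, so
    intersecting with the largest-diameter inclusion set makes maps of
    different window sizes comparable vertex for vertex.
    """
    maps = list(maps)
    if not maps:
        raise ParameterError("harmonize_masks needs at least one map")
    V = maps[0].n_vertices
    for m in maps:
        if m.n_vertices != V:
            raise DimensionError("maps live on meshes of different sizes")
    reference = max(maps, key=lambda m: m.diameter)
    out = []
    for m in maps:
        joint = m.included & reference.included
        joint.label = m.included.label
        mean_r = np.where(joint.mask, m.mean_r, np.nan)
        out.append(replace(m, mean_r=mean_r, included=joint))
    if any(m.included.n_members == 0 for m in out) and reference.included.n_members > 0:
        warnings.warn("mask harmonization left at least one map fully excluded",
                      stacklevel=2)
    return out
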