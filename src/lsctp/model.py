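"""Core data model: meshes, per-vertex maps, cohorts, masks, and the error
hierarchy shared by every analysis module.

Conventions
-----------
* Vertex and face indices are 0-based everywhere.
* Coordinates and thickness are in millimetres; no unit conversion is ever
  applied.
* A thickness of exactly 0 is the one and only missingness code ("no cortex
  here", e.g. the medial wall).  NaN on input is an error, not missingness.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LSCTPError",
    "FormatError",
    "DimensionError",
    "ParameterError",
    "InvariantError",
    "InsufficientDataError",
    "UndefinedCorrelationError",
    "UndefinedSmoothnessError",
    "SmoothingTargetError",
    "TriangleMesh",
    "VertexScalarMap",
    "CohortThickness",
    "VertexMask",
]


class LSCTPError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(LSCTPError):
    """A file is not in the expected on-disk format."""


class DimensionError(LSCTPError):
    """Array shapes or vertex counts do not line up."""


class ParameterError(LSCTPError):
    """A caller-supplied parameter is out of its valid range."""


class InvariantError(LSCTPError):
    """A domain-type invariant is violated (e.g. negative thickness)."""


class InsufficientDataError(LSCTPError):
    """Not enough data to compute the requested statistic."""


class UndefinedCorrelationError(LSCTPError):
    """A correlation is undefined because a profile is constant.

    Carries the offending subject identifier (or row index) so callers can
    convert the error into a vertex exclusion.
    """

    def __init__(self, message: str, subject=None):
        super().__init__(message)
        self.subject = subject


class UndefinedSmoothnessError(LSCTPError):
    """Smoothness is undefined (zero overall variance)."""


class SmoothingTargetError(LSCTPError):
    """A smoothing target FWHM could not be bracketed.

    Carries the best FWHM achieved and the iteration count at which it was
    achieved.
    """

    def __init__(self, message: str, best_fwhm: float, best_iterations: int):
        super().__init__(message)
        self.best_fwhm = best_fwhm
        self.best_iterations = best_iterations


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    return arr


@dataclass(eq=False)
class TriangleMesh:
    """A triangulated surface: vertex coordinates (mm) plus faces.

    Faces are triples of 0-based vertex indices.  The mesh is the shared
    reference surface onto which every subject's thickness map has been
    resampled; a registration sphere and a folded anatomical surface are
    both represented by this one type.
    """

    vertex_coords: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertex_coords = _as_float_array(self.vertex_coords, "vertex_coords")
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertex_coords.ndim != 2 or self.vertex_coords.shape[1] != 3:
            raise DimensionError(
                f"vertex_coords must be (V, 3); got {self.vertex_coords.shape}"
            )
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DimensionError(f"faces must be (F, 3); got {self.faces.shape}")
        if self.faces.shape[0] == 0:
            raise InvariantError("mesh has no faces; edge set would be empty")
        if not np.isfinite(self.vertex_coords).all():
            raise InvariantError("vertex coordinates must be finite")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=0) >= self.n_vertices:
            raise InvariantError(
                f"face indices must lie in [0, {self.n_vertices}); "
                f"found range [{self.faces.min()}, {self.faces.max()}]"
            )
        degenerate = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degenerate.any():
            raise InvariantError(
                f"{int(degenerate.sum())} face(s) repeat a vertex index"
            )

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (E, 2) index array."""
        raw = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]]
        )
        raw.sort(axis=1)
        return np.unique(raw, axis=0)


@dataclass(eq=False)
class VertexScalarMap:
    """One real value per vertex of a named mesh (thickness, LSCTP, SD, ...).

    ``allow_nan=True`` permits NaN as an explicit "undefined here" marker in
    derived statistic maps; input thickness maps must be fully finite.
    """

    values: np.ndarray
    mesh_name: str = ""
    subject_id: str = ""
    allow_nan: bool = False

    def __post_init__(self):
        self.values = _as_float_array(self.values, "values")
        if self.values.ndim != 1:
            raise DimensionError(f"values must be 1-D; got shape {self.values.shape}")
        if self.allow_nan:
            if np.isinf(self.values).any():
                raise InvariantError("values may not be infinite")
        elif not np.isfinite(self.values).all():
            raise InvariantError("values must be finite (NaN is not a missingness code)")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


@dataclass(eq=False)
class CohortThickness:
    """Subjects x vertices nonnegative thickness matrix (mm).

    Zero encodes "no cortex here"; the sliding-window analysis excludes any
    vertex whose window contains a zero for at least one subject.
    """

    matrix: np.ndarray
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.matrix = _as_float_array(self.matrix, "matrix")
        if self.matrix.ndim != 2:
            raise DimensionError(f"matrix must be 2-D; got shape {self.matrix.shape}")
        if self.matrix.shape[0] < 2:
            raise InvariantError("a cohort needs at least 2 subjects")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(self.matrix.shape[0])]
        if len(self.subject_ids) != self.matrix.shape[0]:
            raise DimensionError(
                f"{len(self.subject_ids)} subject ids for {self.matrix.shape[0]} rows"
            )
        if not np.isfinite(self.matrix).all():
            s, v = np.argwhere(~np.isfinite(self.matrix))[0]
            raise InvariantError(
                f"non-finite thickness for subject {self.subject_ids[s]!r} at vertex {v}"
            )
        if (self.matrix < 0).any():
            s, v = np.argwhere(self.matrix < 0)[0]
            raise InvariantError(
                f"negative thickness for subject {self.subject_ids[s]!r} at vertex {v}"
            )

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[1]


@dataclass(eq=False)
class VertexMask:
    """Boolean membership flags over the vertices of one mesh."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 1:
            raise DimensionError(f"mask must be 1-D; got shape {self.mask.shape}")

    @classmethod
    def from_indices(cls, n_vertices: int, indices, label: str = "") -> "VertexMask":
        indices = np.asarray(indices, dtype=np.int64)
        if indices.size and (indices.min() < 0 or indices.max() >= n_vertices):
            raise InvariantError(
                f"label index out of bounds: mesh has {n_vertices} vertices, "
                f"indices span [{indices.min()}, {indices.max()}]"
            )
        mask = np.zeros(n_vertices, dtype=bool)
        mask[indices] = True
        return cls(mask=mask, label=label)

    @property
    def n_vertices(self) -> int:
        return self.mask.shape[0]

    @property
    def n_members(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def __and__(self, other: "VertexMask") -> "VertexMask":
        if self.n_vertices != other.n_vertices:
            raise DimensionError("masks are defined on meshes of different sizes")
        return VertexMask(self.mask & other.mask, label=self.label)

    def __invert__(self) -> "VertexMask":
        return VertexMask(~self.mask, label=self.label)
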