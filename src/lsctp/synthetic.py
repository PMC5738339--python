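"""Synthetic spherical cohorts: the test bed for the whole pipeline.

The generator emulates the statistical structure the sliding-window
analysis assumes: a cohort of n subjects on one shared mesh, nonnegative
thickness with zero marking the medial wall, spatially smooth fields, and
regions where subjects share a common thickness profile plus independent
idiosyncratic variation.

Inside a region of shared-profile strength rho, subject s's thickness at
vertex v is

    t_s(v) = base + sd * (sqrt(rho) * c(v) + sqrt(1 - rho) * e_s(v))

where c is one common smooth unit-variance field and the e_s are
independent per-subject smooth unit-variance fields.  With this sqrt
mixing, rho equals the expected Pearson correlation between any two
subjects' profiles, which makes rho the directly recoverable ground-truth
quantity.  Fields are smoothed white noise (nearest-neighbor smoothing of
i.i.d. Gaussians), so windows contain nonconstant profiles at every scale;
the number of smoothing iterations sets the spatial scale of the profiles.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model import (
    CohortThickness,
    ParameterError,
    TriangleMesh,
    VertexMask,
)
from .smoothness import averaging_operator
from .windowing import build_neighbor_graph

__all__ = [
    "make_icosphere",
    "fsaverage_like_radius",
    "spherical_cap",
    "simulate_cohort",
    "CohortGroundTruth",
]

# icosahedron with circumradius 1
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=np.float64,
) / np.sqrt(1.0 + _PHI**2)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    """One midpoint subdivision step (vectorized)."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
    midpoints = 0.5 * (verts[uniq[:, 0]] + verts[uniq[:, 1]])
    mid_idx = inverse.reshape(3, -1).T + verts.shape[0]  # per-face edge midpoints
    a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
    ab, bc, ca = mid_idx[:, 0], mid_idx[:, 1], mid_idx[:, 2]
    new_faces = np.concatenate(
        [
            np.stack([a, ab, ca], axis=1),
            np.stack([b, bc, ab], axis=1),
            np.stack([c, ca, bc], axis=1),
            np.stack([ab, bc, ca], axis=1),
        ]
    )
    return np.vstack([verts, midpoints]), new_faces


def make_icosphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected to ``radius``.

    Vertex count is 10 * 4**s + 2.
    """
    if subdivisions < 0 or int(subdivisions) != subdivisions:
        raise ParameterError(f"subdivisions must be a nonnegative integer, got {subdivisions}")
    if radius <= 0:
        raise ParameterError(f"radius must be > 0, got {radius}")
    verts, faces = _ICO_VERTS.copy(), _ICO_FACES.copy()
    for _ in range(int(subdivisions)):
        verts, faces = _subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return TriangleMesh(
        vertex_coords=verts * radius,
        faces=faces,
        name=f"icosphere-s{subdivisions}-r{radius:g}",
    )


def fsaverage_like_radius(subdivisions: int) -> float:
    """Radius giving the vertex density of the standard 100 mm registration
    sphere (163842 vertices = subdivision 7) at a coarser subdivision.

    Halving the radius per missing subdivision level keeps the mean
    inter-neighbor distance near the reference value of ~0.94 mm, so window
    diameters in mm remain comparable across mesh resolutions.
    """
    return 100.0 * 2.0 ** (subdivisions - 7)


def spherical_cap(mesh: TriangleMesh, center_vertex: int, arc_radius: float,
                  label: str = "") -> VertexMask:
    """Vertices within great-circle (arc) distance ``arc_radius`` mm of a
    center vertex, on a sphere centered at the coordinate origin."""
    coords = mesh.vertex_coords
    radii = np.linalg.norm(coords, axis=1)
    sphere_r = float(radii.mean())
    unit = coords / radii[:, None]
    cosang = np.clip(unit @ unit[center_vertex], -1.0, 1.0)
    arc = np.arccos(cosang) * sphere_r
    return VertexMask(arc <= arc_radius, label=label or f"cap-{center_vertex}")


@dataclass(eq=False)
class CohortGroundTruth:
    """Generative truth for one synthetic cohort."""

    rho: np.ndarray          # per-vertex expected inter-subject correlation
    medial: VertexMask       # zero-thickness (non-cortex) vertices
    regions: list            # [(VertexMask, rho)] as passed in
    params: dict

    def to_json(self, **kwargs) -> str:
        payload = dict(self.params)
        payload["rho_per_vertex"] = self.rho.tolist()
        payload["medial_indices"] = self.medial.indices.tolist()
        payload["regions"] = [
            {"label": m.label, "n_vertices": m.n_members, "rho": r}
            for m, r in self.regions
        ]
        return json.dumps(payload, **kwargs)


def _smooth_unit_field(operator, rng, n_vertices: int, iterations: int) -> np.ndarray:
    """Nearest-neighbor-smoothed standard-normal field, standardized to
    zero mean and unit population variance."""
    field = rng.standard_normal(n_vertices)
    for _ in range(iterations):
        field = operator @ field
    field -= field.mean()
    sd = field.std()
    if sd == 0:
        raise ParameterError("degenerate field: increase mesh size or lower smoothing")
    return field / sd


def simulate_cohort(
    mesh: TriangleMesh,
    n_subjects: int,
    regions=None,
    base_thickness: float = 2.5,
    noise_sd: float = 0.5,
    smooth_iterations: int = 10,
    idio_smooth_iterations: int = None,
    medial_mask: VertexMask = None,
    seed=0,
):
    """Simulate a thickness cohort with known shared-profile structure.

    Parameters
    ----------
    regions : list of (VertexMask, rho)
        Non-overlapping vertex sets with shared-profile strength
        ``0 <= rho <= 1``; outside all regions rho = 0.
    base_thickness, noise_sd : float, mm
        Mean thickness and the standard deviation of the smooth variation
        around it (defaults 2.5 and 0.5 mm, typical cortical values).
    smooth_iterations : int
        Nearest-neighbor smoothing iterations applied to the underlying
        white-noise fields; sets the spatial scale of the profiles.
    idio_smooth_iterations : int, optional
        Separate spatial scale for the per-subject (idiosyncratic) fields;
        defaults to ``smooth_iterations``.  A smoother shared field with
        rougher idiosyncratic fields reproduces the empirically observed
        rise of LSCTP with window size: small windows see mostly
        fine-grained idiosyncratic variation, large windows recover the
        shared structure, and ``rho`` is the large-window limit of the
        expected inter-subject correlation.
    medial_mask : VertexMask, optional
        Vertices set to exactly 0 ("no cortex"), after clipping everything
        else at >= 0.1 mm so zero stays unambiguous as the missingness code.

    Returns
    -------
    (CohortThickness, CohortGroundTruth)
    """
    regions = list(regions or [])
    if n_subjects < 2:
        raise ParameterError("need at least 2 subjects")
    if noise_sd <= 0:
        raise ParameterError(f"noise_sd must be > 0, got {noise_sd}")
    V = mesh.n_vertices
    rho = np.zeros(V)
    claimed = np.zeros(V, dtype=bool)
    for m, r in regions:
        if m.n_vertices != V:
            raise ParameterError("region mask does not match the mesh")
        if not 0.0 <= r <= 1.0:
            raise ParameterError(f"region strength must be in [0, 1], got {r}")
        if (claimed & m.mask).any():
            raise ParameterError("regions may not overlap")
        claimed |= m.mask
        rho[m.mask] = r
    graph = build_neighbor_graph(mesh)
    operator = averaging_operator(graph)
    root = np.random.SeedSequence(seed)
    common_rng = np.random.default_rng(root.spawn(1)[0])
    c = _smooth_unit_field(operator, common_rng, V, smooth_iterations)
    shared = np.sqrt(rho) * c
    idio_scale = np.sqrt(1.0 - rho)
    if idio_smooth_iterations is None:
        idio_smooth_iterations = smooth_iterations
    subject_seqs = np.random.SeedSequence(seed, spawn_key=(1,)).spawn(n_subjects)
    matrix = np.empty((n_subjects, V))
    for s, seq in enumerate(subject_seqs):
        e = _smooth_unit_field(operator, np.random.default_rng(seq), V,
                               idio_smooth_iterations)
        matrix[s] = base_thickness + noise_sd * (shared + idio_scale * e)
    matrix = np.maximum(matrix, 0.1)
    if medial_mask is not None:
        if medial_mask.n_vertices != V:
            raise ParameterError("medial mask does not match the mesh")
        matrix[:, medial_mask.mask] = 0.0
        medial = medial_mask
    else:
        medial = VertexMask(np.zeros(V, dtype=bool), label="medial")
    cohort = CohortThickness(
        matrix=matrix,
        subject_ids=[f"sub-{s:02d}" for s in range(n_subjects)],
    )
    truth = CohortGroundTruth(
        rho=rho,
        medial=medial,
        regions=regions,
        params={
            "mesh": mesh.name,
            "n_subjects": n_subjects,
            "base_thickness_mm": base_thickness,
            "noise_sd_mm": noise_sd,
            "smooth_iterations": smooth_iterations,
            "idio_smooth_iterations": idio_smooth_iterations,
            "seed": int(seed) if np.isscalar(seed) else None,
        },
    )
    return cohort, truth
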