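"""Shared fixtures: small spheres at registration-sphere vertex density.

Radii follow the package convention (``fsaverage_like_radius``) so that the
mean inter-neighbor distance is ~0.94 mm at every subdivision level and
window diameters in mm are comparable across mesh resolutions.
"""
import numpy as np
import pytest

from lsctp import (
    VertexMask,
    build_neighbor_graph,
    fsaverage_like_radius,
    make_icosphere,
    simulate_cohort,
    spherical_cap,
)


@pytest.fixture(scope="session")
def icosahedron():
    return make_icosphere(0, 1.0)


@pytest.fixture(scope="session")
def sphere2():
    """162 vertices, radius 3.125 mm."""
    return make_icosphere(2, fsaverage_like_radius(2))


@pytest.fixture(scope="session")
def sphere3():
    """642 vertices, radius 6.25 mm."""
    return make_icosphere(3, fsaverage_like_radius(3))


@pytest.fixture(scope="session")
def sphere4():
    """2562 vertices, radius 12.5 mm."""
    return make_icosphere(4, fsaverage_like_radius(4))


@pytest.fixture(scope="session")
def sphere3_graph(sphere3):
    return build_neighbor_graph(sphere3)


@pytest.fixture(scope="session")
def cohort12(sphere3):
    """12 subjects on sphere3: one rho=0.5 cap, one medial cap of zeros."""
    cap = spherical_cap(sphere3, 0, 3.0, "roi")
    medial = spherical_cap(sphere3, 100, 2.0, "medial")
    cohort, truth = simulate_cohort(
        sphere3, 12, regions=[(cap, 0.5)], medial_mask=medial, seed=1
    )
    return cohort, truth, cap, medial


@pytest.fixture(scope="session")
def full_mask(sphere3):
    return VertexMask(np.ones(sphere3.n_vertices, dtype=bool), label="all")
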