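"""FWHM estimation, nearest-neighbor smoothing, smoothing to a target."""
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from lsctp import (
    EdgeStats,
    ParameterError,
    SmoothingTargetError,
    UndefinedSmoothnessError,
    VertexMask,
    VertexScalarMap,
    averaging_operator,
    build_neighbor_graph,
    edge_statistics,
    estimate_fwhm,
    make_icosphere,
    map_smoothness,
    nn_smooth,
    smooth_to_target,
)


class TestEstimateFWHM:
    def test_equal_variances_give_sqrt2_dv(self):
        # var(ds) = var(s): ln(1 - 1/2) = -ln 2 cancels, FWHM = sqrt(2) * dv
        stats = EdgeStats(dv=1.0, var_ds=0.7, var_s=0.7)
        assert estimate_fwhm(stats) == pytest.approx(math.sqrt(2.0), abs=1e-12)

    def test_white_noise_limit_is_zero(self):
        assert estimate_fwhm(EdgeStats(dv=1.0, var_ds=2.0, var_s=1.0)) == 0.0
        assert estimate_fwhm(EdgeStats(dv=1.0, var_ds=3.0, var_s=1.0)) == 0.0

    def test_constant_field_flagged_infinite(self):
        fwhm = estimate_fwhm(EdgeStats(dv=1.0, var_ds=0.0, var_s=1.0))
        assert math.isinf(fwhm)

    def test_zero_overall_variance_undefined(self):
        with pytest.raises(UndefinedSmoothnessError):
            estimate_fwhm(EdgeStats(dv=1.0, var_ds=0.5, var_s=0.0))

    def test_fully_constant_field_is_infinitely_smooth(self):
        assert math.isinf(estimate_fwhm(EdgeStats(dv=1.0, var_ds=0.0, var_s=0.0)))

    def test_iid_noise_estimates_near_zero(self, sphere4):
        """White noise has essentially no spatial structure: FWHM stays
        well below the inter-neighbor distance across seeds."""
        g = build_neighbor_graph(sphere4)
        fwhms = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rep = map_smoothness(g, VertexScalarMap(rng.standard_normal(g.n_vertices)))
            fwhms.append(rep.fwhm_dv_units)
        assert np.mean(fwhms) < 0.5

    def test_constant_field_serialized_as_flag_not_infinity(self, sphere3_graph):
        rep = map_smoothness(
            sphere3_graph, VertexScalarMap(np.zeros(sphere3_graph.n_vertices) + 2.0)
        )
        d = rep.to_dict()
        assert d["constant_field"] is True
        assert d["fwhm_mm"] is None


class TestNNSmooth:
    def test_constant_map_is_a_fixed_point(self, sphere3_graph):
        vmap = VertexScalarMap(np.full(sphere3_graph.n_vertices, 3.3))
        out = nn_smooth(sphere3_graph, vmap, 5)
        np.testing.assert_allclose(out.values, vmap.values, atol=1e-12)

    def test_zero_iterations_is_identity(self, sphere3_graph):
        rng = np.random.default_rng(0)
        vmap = VertexScalarMap(rng.standard_normal(sphere3_graph.n_vertices))
        np.testing.assert_array_equal(
            nn_smooth(sphere3_graph, vmap, 0).values, vmap.values
        )

    def test_impulse_spreads_to_one_sixth_on_icosahedron(self, icosahedron):
        """Degree-5 vertices average over self + 5 neighbors = 6 values."""
        g = build_neighbor_graph(icosahedron)
        impulse = np.zeros(12)
        impulse[0] = 1.0
        out = nn_smooth(g, VertexScalarMap(impulse), 1)
        assert out.values[0] == pytest.approx(1 / 6)
        neighbors = set(g.edges[(g.edges == 0).any(axis=1)].ravel()) - {0}
        for v in neighbors:
            assert out.values[v] == pytest.approx(1 / 6)

    def test_matches_dense_matrix_power_oracle(self, sphere2):
        """k iterations equal multiplication by the k-th power of the dense
        row-stochastic averaging matrix."""
        g = build_neighbor_graph(sphere2)
        n = g.n_vertices
        dense = np.eye(n)
        for a, b in g.edges:
            dense[a, b] = dense[b, a] = 1.0
        dense /= dense.sum(axis=1, keepdims=True)
        rng = np.random.default_rng(9)
        values = rng.standard_normal(n)
        expected = np.linalg.matrix_power(dense, 3) @ values
        out = nn_smooth(g, VertexScalarMap(values), 3)
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    def test_mean_preserved_exactly_on_vertex_transitive_mesh(self, icosahedron):
        g = build_neighbor_graph(icosahedron)
        rng = np.random.default_rng(2)
        values = rng.standard_normal(12)
        out = nn_smooth(g, VertexScalarMap(values), 4)
        assert out.values.mean() == pytest.approx(values.mean(), abs=1e-12)

    def test_masked_smoothing_never_leaks_across_boundary(self, sphere3):
        g = build_neighbor_graph(sphere3)
        inside = sphere3.vertex_coords[:, 2] > 0
        values = np.where(inside, 1.0, 1e9)
        out = nn_smooth(g, VertexScalarMap(values), 3, mask=VertexMask(inside))
        np.testing.assert_allclose(out.values[inside], 1.0, atol=1e-9)
        np.testing.assert_allclose(out.values[~inside], 1e9)

    def test_negative_iterations_rejected(self, sphere3_graph):
        with pytest.raises(ParameterError):
            nn_smooth(sphere3_graph, VertexScalarMap(np.ones(sphere3_graph.n_vertices)), -1)


class TestSmoothnessGrowth:
    def test_fwhm_monotone_in_iterations_on_white_noise(self, sphere4):
        """Averaged over 20 seeds, FWHM grows monotonically with N."""
        g = build_neighbor_graph(sphere4)
        A = averaging_operator(g)
        iters = list(range(11))
        mean_fwhm = np.zeros(len(iters))
        for seed in range(20):
            f = np.random.default_rng(seed).standard_normal(g.n_vertices)
            for k, n in enumerate(iters):
                if n > 0:
                    f = A @ f
                mean_fwhm[k] += map_smoothness(g, VertexScalarMap(f)).fwhm
        rho = spearmanr(iters, mean_fwhm).statistic
        assert rho >= 0.95

    def test_sqrt_n_scaling_constant_across_iteration_counts(self):
        """FWHM/(dv*sqrt(N)) is the same constant for N in {9, 16, 25}."""
        mesh = make_icosphere(5, 25.0)
        g = build_neighbor_graph(mesh)
        A = averaging_operator(g)
        ratios = []
        for N in (9, 16, 25):
            vals = []
            for seed in range(5):
                f = np.random.default_rng(seed).standard_normal(g.n_vertices)
                for _ in range(N):
                    f = A @ f
                vals.append(map_smoothness(g, VertexScalarMap(f)).fwhm_dv_units
                            / math.sqrt(N))
            ratios.append(np.mean(vals))
        assert max(ratios) / min(ratios) < 1.08


class TestSmoothToTarget:
    def test_zero_target_needs_no_smoothing(self, sphere3_graph):
        rng = np.random.default_rng(1)
        vmap = VertexScalarMap(rng.standard_normal(sphere3_graph.n_vertices))
        _, n = smooth_to_target(sphere3_graph, vmap, 0.0, 50)
        assert n == 0

    def test_own_fwhm_needs_no_smoothing(self, sphere3_graph):
        rng = np.random.default_rng(1)
        vmap = VertexScalarMap(rng.standard_normal(sphere3_graph.n_vertices))
        own = map_smoothness(sphere3_graph, vmap).fwhm
        _, n = smooth_to_target(sphere3_graph, vmap, own, 50)
        assert n == 0

    def test_recovers_the_iteration_count_that_made_the_target(self):
        """Smoothing fresh noise to the FWHM produced by 16 iterations on
        another noise field takes ~16 iterations."""
        mesh = make_icosphere(5, 25.0)
        g = build_neighbor_graph(mesh)
        A = averaging_operator(g)
        f = np.random.default_rng(100).standard_normal(g.n_vertices)
        for _ in range(16):
            f = A @ f
        target = map_smoothness(g, VertexScalarMap(f)).fwhm
        fresh = VertexScalarMap(
            np.random.default_rng(200).standard_normal(g.n_vertices)
        )
        _, n = smooth_to_target(g, fresh, target, 64)
        assert 14 <= n <= 18

    def test_iteration_count_is_mesh_scale_invariant(self, sphere3):
        """The same data on two meshes (one a rescaled copy) needs the same
        number of iterations to reach the respective target smoothness:
        FWHM comparisons happen in dv units implicitly."""
        big = make_icosphere(3, 2 * 6.25)
        rng = np.random.default_rng(11)
        reference = rng.standard_normal(sphere3.n_vertices)
        shuffled = rng.permutation(reference)
        ns = []
        for mesh in (sphere3, big):
            g = build_neighbor_graph(mesh)
            ref_smooth = nn_smooth(g, VertexScalarMap(reference), 9)
            target = map_smoothness(g, ref_smooth).fwhm
            _, n = smooth_to_target(g, VertexScalarMap(shuffled), target, 64)
            ns.append(n)
        assert abs(ns[0] - ns[1]) <= 1

    def test_unreachable_target_raises_with_best_achieved(self, sphere3_graph):
        rng = np.random.default_rng(1)
        vmap = VertexScalarMap(rng.standard_normal(sphere3_graph.n_vertices))
        with pytest.raises(SmoothingTargetError) as err:
            smooth_to_target(sphere3_graph, vmap, 1e6, 3)
        assert err.value.best_iterations <= 3
        assert err.value.best_fwhm < 1e6
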