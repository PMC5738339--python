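"""The LSCTP statistic: pairwise correlations, Fisher averaging, full maps."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lsctp import (
    CohortThickness,
    InsufficientDataError,
    ParameterError,
    UndefinedCorrelationError,
    fisher_average,
    harmonize_masks,
    lsctp_map,
    pairwise_profile_correlations,
    simulate_cohort,
    spherical_cap,
)


def naive_lsctp(matrix, coords, diameter, min_members=3):
    """Independent brute-force oracle: nested loops, textbook Pearson,
    hand-rolled Fisher averaging."""
    V = coords.shape[0]
    n = matrix.shape[0]
    out = np.full(V, np.nan)
    for v in range(V):
        members = [
            u for u in range(V)
            if math.dist(coords[u], coords[v]) <= diameter / 2.0
        ]
        sub = matrix[:, members]
        if len(members) < min_members or (sub == 0).any():
            continue
        if any(sub[i].std() == 0 for i in range(n)):
            continue
        zs = []
        for i in range(n):
            for j in range(i + 1, n):
                x, y = sub[i], sub[j]
                r = ((x * y).mean() - x.mean() * y.mean()) / (x.std() * y.std())
                r = min(max(r, -1 + 1e-7), 1 - 1e-7)
                zs.append(math.atanh(r))
        out[v] = math.tanh(sum(zs) / len(zs))
    return out


class TestPairwiseCorrelations:
    def test_42_subjects_yield_861_pairs(self):
        rng = np.random.default_rng(0)
        r = pairwise_profile_correlations(rng.standard_normal((42, 10)))
        assert r.shape == (861,)  # 42*41/2

    def test_identical_rows_correlate_perfectly(self):
        row = np.array([1.0, 2.0, 5.0, 3.0])
        r = pairwise_profile_correlations(np.vstack([row, row]))
        assert r[0] == pytest.approx(1.0)

    def test_reversed_profile_anticorrelates(self):
        r = pairwise_profile_correlations([[1, 2, 3], [3, 2, 1]])
        assert r[0] == pytest.approx(-1.0)

    def test_constant_row_names_subject(self):
        with pytest.raises(UndefinedCorrelationError) as err:
            pairwise_profile_correlations(
                [[1, 1, 1], [1, 2, 3]], subject_ids=["flat", "ok"]
            )
        assert err.value.subject == "flat"

    def test_too_few_window_vertices_rejected(self):
        with pytest.raises(InsufficientDataError, match="3 window vertices"):
            pairwise_profile_correlations([[1, 2], [2, 1]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_pair_order_is_lexicographic(self, seed):
        """r[k] must be corr(row_i, row_j) for the k-th (i<j) pair in order."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((4, 6))
        r = pairwise_profile_correlations(X)
        expected = []
        for i in range(4):
            for j in range(i + 1, 4):
                expected.append(np.corrcoef(X[i], X[j])[0, 1])
        np.testing.assert_allclose(r, expected, atol=1e-12)


class TestFisherAverage:
    def test_identical_values_average_to_themselves(self):
        assert fisher_average([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_closed_form_mixture(self):
        # mean of atanh(0)=0 and atanh(0.8)=ln(9)/2 is ln(9)/4; tanh of that
        # is (3-1)/(3+1) = 0.5
        assert fisher_average([0.0, 0.8]) == pytest.approx(0.5, abs=1e-12)

    def test_perfect_correlation_clamped(self):
        assert fisher_average([1.0]) >= 0.9999

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            fisher_average([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1.0, 1.0), min_size=1, max_size=20))
    def test_result_strictly_inside_unit_interval(self, rs):
        assert -1.0 < fisher_average(rs) < 1.0


class TestLSCTPMap:
    def test_identical_smooth_cohort_gives_unit_similarity(self, sphere3):
        profile = 2.0 + np.abs(sphere3.vertex_coords[:, 2]) / 10.0
        cohort = CohortThickness(np.vstack([profile] * 4))
        lmap = lsctp_map(cohort, sphere3, 3.0)
        assert lmap.included.n_members > 0
        assert np.nanmin(lmap.mean_r) >= 0.9999

    def test_zero_thickness_poisons_every_window_containing_it(self, sphere3):
        rng = np.random.default_rng(1)
        matrix = rng.uniform(1.5, 3.5, (4, sphere3.n_vertices))
        v0 = 17
        matrix[2, v0] = 0.0
        lmap = lsctp_map(CohortThickness(matrix), sphere3, 3.0)
        from lsctp import all_window_members

        windows = all_window_members(sphere3, 3.0)
        for v, members in enumerate(windows):
            if v0 in members:
                assert not lmap.included.mask[v]
            else:
                assert lmap.included.mask[v]

    def test_matches_brute_force_oracle(self, sphere2):
        """Full map equals the naive nested-loop implementation to 1e-12."""
        rng = np.random.default_rng(7)
        matrix = rng.uniform(1.0, 4.0, (4, sphere2.n_vertices))
        matrix[0, 3] = 0.0  # exercise the exclusion rule too
        lmap = lsctp_map(CohortThickness(matrix), sphere2, 3.0)
        oracle = naive_lsctp(matrix, sphere2.vertex_coords, 3.0)
        np.testing.assert_array_equal(np.isnan(lmap.mean_r), np.isnan(oracle))
        np.testing.assert_allclose(lmap.mean_r, oracle, atol=1e-12)

    def test_subject_order_invariance(self, sphere2):
        rng = np.random.default_rng(3)
        matrix = rng.uniform(1.0, 4.0, (5, sphere2.n_vertices))
        a = lsctp_map(CohortThickness(matrix), sphere2, 3.0)
        b = lsctp_map(CohortThickness(matrix[::-1]), sphere2, 3.0)
        np.testing.assert_allclose(a.mean_r, b.mean_r, atol=1e-12)

    def test_positive_affine_rescaling_of_one_subject_is_invisible(self, sphere2):
        rng = np.random.default_rng(5)
        matrix = rng.uniform(1.0, 4.0, (4, sphere2.n_vertices))
        a = lsctp_map(CohortThickness(matrix), sphere2, 3.0)
        rescaled = matrix.copy()
        rescaled[1] = 1.7 * rescaled[1] + 0.3
        b = lsctp_map(CohortThickness(rescaled), sphere2, 3.0)
        np.testing.assert_allclose(a.mean_r, b.mean_r, atol=1e-10)

    def test_exclusion_grows_with_diameter(self, sphere3):
        medial = spherical_cap(sphere3, 100, 2.0, "medial")
        cohort, _ = simulate_cohort(sphere3, 4, medial_mask=medial, seed=2)
        excluded = {}
        for d in (2.0, 3.0, 5.0):
            lmap = lsctp_map(cohort, sphere3, d)
            excluded[d] = set(np.flatnonzero(~lmap.included.mask))
        assert excluded[2.0] <= excluded[3.0] <= excluded[5.0]
        assert len(excluded[5.0]) > len(excluded[2.0])

    def test_constant_profile_excluded_and_counted_separately(self, sphere2):
        matrix = np.vstack(
            [
                np.full(sphere2.n_vertices, 2.0),  # constant but nonzero
                1.0 + np.abs(sphere2.vertex_coords[:, 0]),
                1.0 + np.abs(sphere2.vertex_coords[:, 1]),
            ]
        )
        with pytest.warns(UserWarning, match="excluded"):
            lmap = lsctp_map(CohortThickness(matrix), sphere2, 3.0)
        assert lmap.included.n_members == 0
        assert lmap.exclusion_counts["constant_profile"] > 0
        assert lmap.exclusion_counts["zero_thickness"] == 0

    def test_all_excluded_map_warns_but_is_valid(self, sphere2):
        matrix = np.zeros((2, sphere2.n_vertices))
        matrix += 0.0
        matrix[0, 0] = 1.0
        matrix[1, 0] = 2.0
        with pytest.warns(UserWarning, match="excluded"):
            lmap = lsctp_map(CohortThickness(matrix), sphere2, 3.0)
        assert lmap.included.n_members == 0


class TestHarmonizeMasks:
    def test_small_map_inherits_largest_diameter_mask(self, sphere3):
        medial = spherical_cap(sphere3, 100, 2.0, "medial")
        cohort, _ = simulate_cohort(sphere3, 4, medial_mask=medial, seed=2)
        m4 = lsctp_map(cohort, sphere3, 4.0)
        m8 = lsctp_map(cohort, sphere3, 8.0)
        h4, h8 = harmonize_masks([m4, m8])
        np.testing.assert_array_equal(h4.included.mask, m8.included.mask)
        np.testing.assert_array_equal(h8.included.mask, m8.included.mask)
        # values untouched where still included
        keep = h4.included.mask
        np.testing.assert_allclose(h4.mean_r[keep], m4.mean_r[keep])

    def test_single_map_unchanged(self, sphere3, cohort12):
        cohort = cohort12[0]
        m = lsctp_map(cohort, sphere3, 3.0)
        (h,) = harmonize_masks([m])
        np.testing.assert_array_equal(h.included.mask, m.included.mask)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            harmonize_masks([])
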