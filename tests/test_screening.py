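"""MDSD statistic, skewness filter, hub calls and cumulative diagnostic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mdsd.estimators import AdjacencyPath, TuningGrid
from mdsd.screening import (DegreePath, call_hubs, cumulative_mdsd,
                            degree_skewness, degrees_from_path,
                            filter_path_by_skewness, mdsd)

from conftest import brute_force_mdsd


class TestMdsd:
    def test_hand_example(self):
        # single model, degrees (2, 1, 1): node 1 distance 1+1, others 1
        values = mdsd(np.array([[2], [1], [1]]))
        np.testing.assert_allclose(values, [1.0, 0.5, 0.5])

    def test_constant_columns_give_zero(self):
        D = np.tile([[3], [3], [3], [3]], (1, 5))
        np.testing.assert_array_equal(mdsd(D), np.zeros(4))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = rng.integers(2, 12)
            M = rng.integers(1, 6)
            D = rng.integers(0, p, size=(p, M))
            np.testing.assert_allclose(mdsd(D), brute_force_mdsd(D),
                                       rtol=1e-10)

    @given(arrays(np.int64, shape=st.tuples(st.integers(2, 8),
                                            st.integers(1, 4)),
                  elements=st.integers(0, 7)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariants(self, D):
        D = np.minimum(D, D.shape[0] - 1)
        values = mdsd(D)
        assert np.all(values >= 0)
        # permutation of path columns leaves MDSD unchanged
        perm = np.random.default_rng(0).permutation(D.shape[1])
        np.testing.assert_allclose(values, mdsd(D[:, perm]), rtol=1e-12)
        # duplicating the path leaves MDSD unchanged
        np.testing.assert_allclose(values, mdsd(np.hstack([D, D])),
                                   rtol=1e-12)
        # degrees scaled by c scale MDSD by c^2
        np.testing.assert_allclose(mdsd(3 * D), 9 * values, rtol=1e-12)

    def test_sum_identity(self):
        # sum_i MDSD_i = 2 p^2/(p-1) * mean over models of degree variance
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = rng.integers(3, 15)
            D = rng.integers(0, p, size=(p, rng.integers(1, 6)))
            lhs = mdsd(D).sum()
            rhs = 2 * p**2 / (p - 1) * D.var(axis=0).mean()
            np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_zero_iff_degree_equals_all_others(self):
        D = np.array([[2, 3], [2, 3], [0, 1]])
        values = mdsd(D)
        assert values[2] > 0
        # nodes 0 and 1 always share the majority degree but differ from 2
        assert values[0] == values[1] > 0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            mdsd(np.array([[1]]))


class TestSkewness:
    @pytest.mark.parametrize("column, expected", [
        ([1, 2, 3], 0.0),
        ([0, 0, 0, 10], np.sqrt(4 / 3)),
    ])
    def test_known_values(self, column, expected):
        assert degree_skewness(column) == pytest.approx(expected)

    def test_constant_column_undefined(self):
        assert np.isnan(degree_skewness([4, 4, 4]))

    def test_adjusted_small_sample_correction(self):
        # G1 = g1 * sqrt(p(p-1))/(p-2) = sqrt(4/3) * sqrt(12)/2 = 2
        assert degree_skewness([0, 0, 0, 10], adjusted=True) == pytest.approx(2.0)


class TestFilter:
    def _degpath(self, columns):
        return DegreePath(np.array(columns).T)

    def test_retains_strictly_above_threshold(self):
        # columns engineered to have skewness ~ (1.15, 0, 0.65)
        D = np.array([[0, 0, 0, 3], [1, 2, 2, 3], [0, 1, 1, 3]]).T
        reduced, mask, skews = filter_path_by_skewness(DegreePath(D), 0.5)
        assert mask.tolist() == [True, False, True]
        assert reduced.n_models == 2

    def test_all_empty_graphs_error(self):
        D = np.zeros((5, 4), dtype=int)
        with pytest.raises(ValueError, match="no path models"):
            filter_path_by_skewness(DegreePath(D), 0.5)

    def test_minus_infinity_retains_everything(self):
        D = np.array([[0, 0, 0, 3], [1, 2, 2, 3]]).T
        _, mask, _ = filter_path_by_skewness(DegreePath(D), -np.inf)
        # the constant-skew-defined columns are retained; only
        # zero-variance columns could ever drop
        assert mask.all()


class TestCallHubs:
    def test_worked_example(self):
        res = call_hubs([10, 0.5, 0.5, 0.5, 0.5], gamma=3)
        assert res.mean_mdsd == pytest.approx(2.4)
        assert res.cutoff == pytest.approx(7.2)
        assert res.hub_ids == [1]

    def test_constant_mdsd_no_hubs(self):
        res = call_hubs([2.0, 2.0, 2.0], gamma=1.5)
        assert not res.hub_flags.any()

    def test_all_zero_mdsd(self):
        res = call_hubs(np.zeros(6), gamma=3)
        assert res.cutoff == 0
        assert not res.hub_flags.any()

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError):
            call_hubs([1.0, 2.0], gamma=0)


class TestCumulative:
    def test_final_prefix_equals_mdsd_and_monotone(self):
        rng = np.random.default_rng(3)
        D = rng.integers(0, 6, size=(7, 5))
        cum, _ = cumulative_mdsd(D)
        np.testing.assert_allclose(cum[:, -1], mdsd(D), rtol=1e-12)
        assert np.all(np.diff(cum, axis=1) >= -1e-12)

    def test_not_monotone_in_degree(self):
        # node 0 has the lower degree everywhere yet the larger MDSD
        # contribution, because it sits far from the bulk
        D = np.array([[0, 0],
                      [5, 5],
                      [5, 5],
                      [5, 5],
                      [4, 4]])
        cum, deg = cumulative_mdsd(D)
        assert deg[0, -1] < deg[1, -1]
        assert cum[0, -1] > cum[1, -1]

    def test_multi_axis_grid_rejected(self):
        grid = TuningGrid([("a", [1.0, 2.0]), ("b", [1.0])])
        dp = DegreePath(np.zeros((3, 2), dtype=int), grid=grid)
        with pytest.raises(ValueError, match="single-axis"):
            cumulative_mdsd(dp)


class TestDegreesFromPath:
    def test_star_and_boundary_graphs(self):
        p = 4
        empty = np.zeros((p, p), dtype=bool)
        star = np.zeros((p, p), dtype=bool)
        star[0, 1:] = star[1:, 0] = True
        complete = ~np.eye(p, dtype=bool)
        grid = TuningGrid([("lambda", [3.0, 2.0, 1.0])])
        path = AdjacencyPath(grid, [empty, star, complete], "test", 0.0)
        degpath = degrees_from_path(path)
        np.testing.assert_array_equal(
            degpath.degrees,
            np.array([[0, 3, 3], [0, 1, 3], [0, 1, 3], [0, 1, 3]]))

    def test_empty_path_rejected(self):
        grid = TuningGrid([("lambda", [1.0])])
        path = AdjacencyPath(grid, [], "test", 0.0, kept_indices=[])
        with pytest.raises(ValueError):
            degrees_from_path(path)
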