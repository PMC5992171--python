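import itertools
import math

import numpy as np
import pytest

from octlumen.dp_edge import (CostMatrix, DPParams, LumenBoundary,
                              compute_cost_matrix, detect_boundary_circular,
                              pixel_cost, trace_min_cost_path)


def enumerate_min_cost(G, alpha):
    """Exhaustive oracle: try every +/-1-step path, one row per column.

    Recursion over columns, independent of the DP table; returns the
    minimum total cost and one optimal row sequence.
    """
    G = np.asarray(G, float)
    D, W = G.shape
    M = G.max()
    best = (math.inf, None)
    for start in range(D):
        stack = [(0, start, 2.0 * (M - G[start, 0]), [start])]
        while stack:
            i, j, c, path = stack.pop()
            if i == W - 1:
                if c < best[0]:
                    best = (c, path)
                continue
            for step in (-1, 0, 1):
                k = j + step
                if 0 <= k < D:
                    m = alpha if step else 1.0
                    w = 2.0 * M - G[j, i] - G[k, i + 1]
                    stack.append((i + 1, k, c + m * w, path + [k]))
    return best


def path_cost(G, rows, alpha):
    """Recompute a path's cost from first principles."""
    G = np.asarray(G, float)
    M = G.max()
    c = 2.0 * (M - G[rows[0], 0])
    for i in range(1, len(rows)):
        m = alpha if rows[i] != rows[i - 1] else 1.0
        c += m * (2.0 * M - G[rows[i - 1], i - 1] - G[rows[i], i])
    return c


class TestPixelCost:
    def test_brightest_transition_is_free(self):
        assert pixel_cost(1.0, 1.0, 1.0) == 0.0

    def test_darkest_transition_costs_twice_max(self):
        assert pixel_cost(0.0, 0.0, 1.0) == 2.0

    def test_direct_substitution(self):
        assert pixel_cost(0.25, 0.5, 1.0) == pytest.approx(1.25)

    def test_nonnegative_on_grid(self):
        for a, b in itertools.product(np.linspace(0, 1, 5), repeat=2):
            assert pixel_cost(a, b, 1.0) >= 0.0


class TestComputeCostMatrix:
    def test_bright_row_accumulates_zero_cost(self):
        G = np.zeros((8, 6))
        G[3, :] = 1.0
        cm = compute_cost_matrix(G, DPParams())
        np.testing.assert_allclose(cm.cost[3, :], 0.0)
        assert (cm.cost[np.arange(8) != 3, :] > 0).all()

    def test_uniform_image_all_rows_equal_and_straight(self):
        cm = compute_cost_matrix(np.full((6, 5), 0.4), DPParams())
        for i in range(5):
            assert np.ptp(cm.cost[:, i]) == pytest.approx(0.0)
        np.testing.assert_array_equal(cm.backpointer[:, 1:], 0)

    def test_single_column_pair_required(self):
        with pytest.raises(ValueError):
            compute_cost_matrix(np.zeros((8, 1)), DPParams())

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            D = int(rng.integers(2, 7))
            W = int(rng.integers(2, 9))
            G = rng.uniform(0, 1, (D, W))
            alpha = float(rng.uniform(1.0, 2.0))
            cm = compute_cost_matrix(G, DPParams(alpha=alpha))
            expected, _ = enumerate_min_cost(G, alpha)
            assert cm.cost[:, -1].min() == pytest.approx(expected, abs=1e-9)

    def test_spec_sized_random_instance(self, rng):
        G = rng.uniform(0, 1, (6, 9))
        cm = compute_cost_matrix(G, DPParams(alpha=1.5))
        expected, _ = enumerate_min_cost(G, 1.5)
        assert cm.cost[:, -1].min() == pytest.approx(expected, abs=1e-9)


class TestTraceMinCostPath:
    def test_diagonal_ridge_followed_exactly(self):
        G = np.zeros((8, 6))
        rows = np.array([1, 2, 3, 4, 5, 6])
        G[rows, np.arange(6)] = 1.0
        b = trace_min_cost_path(compute_cost_matrix(G, DPParams()))
        np.testing.assert_array_equal(b.depth_index, rows)

    def test_constant_ridge_followed(self):
        G = np.zeros((8, 6))
        G[4, :] = 1.0
        b = trace_min_cost_path(compute_cost_matrix(G, DPParams()))
        np.testing.assert_array_equal(b.depth_index, 4)

    def test_tie_breaks_to_smallest_row(self):
        cost = np.ones((10, 4))
        cost[3, -1] = cost[7, -1] = 0.0
        cm = CostMatrix(cost=cost, backpointer=np.zeros((10, 4), np.int8))
        assert trace_min_cost_path(cm).depth_index[-1] == 3

    def test_optimal_substructure(self, rng):
        G = rng.uniform(0, 1, (7, 10))
        alpha = 1.3
        cm = compute_cost_matrix(G, DPParams(alpha=alpha))
        b = trace_min_cost_path(cm)
        for i in range(10):
            prefix = b.depth_index[:i + 1]
            assert path_cost(G, prefix, alpha) == pytest.approx(
                cm.cost[prefix[-1], i], abs=1e-9)

    def test_path_cost_matches_reported_minimum(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            G = r.uniform(0, 1, (6, 8))
            cm = compute_cost_matrix(G, DPParams(alpha=1.5))
            b = trace_min_cost_path(cm)
            assert path_cost(G, b.depth_index, 1.5) == pytest.approx(
                cm.cost[:, -1].min(), abs=1e-9)


class TestAlphaBehaviour:
    # two-path fixture: from the bright (1.0) top-left pixel the path can
    # go straight onto a dark pixel (cost 1) or diagonally onto a bright
    # 0.9 pixel (cost 0.1 * alpha) — the choice flips at alpha = 10
    two_path = np.array([[1.0, 0.0],
                         [0.0, 0.9]])

    def test_brighter_diagonal_wins_at_alpha_one(self):
        b = trace_min_cost_path(
            compute_cost_matrix(self.two_path, DPParams(alpha=1.0)))
        np.testing.assert_array_equal(b.depth_index, [0, 1])

    def test_raising_alpha_never_reduces_straight_moves(self):
        n_straight = []
        for alpha in (1.0, 5.0, 15.0, 30.0):
            b = trace_min_cost_path(
                compute_cost_matrix(self.two_path, DPParams(alpha=alpha)))
            n_straight.append(int((np.diff(b.depth_index) == 0).sum()))
        assert n_straight == sorted(n_straight)
        assert n_straight[0] == 0 and n_straight[-1] == 1


class TestDetectBoundaryCircular:
    def test_symmetric_frame_gives_constant_closed_boundary(self):
        G = np.zeros((12, 16))
        G[5, :] = 1.0
        b = detect_boundary_circular(G, DPParams())
        assert b.closed
        np.testing.assert_array_equal(b.depth_index, 5)

    def test_bump_crossing_seam_recovered(self):
        # ridge mostly at row 10 with a +3 excursion centered on the seam
        W = 16
        truth = np.full(W, 10)
        truth[[0, 1, 2]] = [13, 12, 11]
        truth[[-3, -2, -1]] = [11, 12, 13]
        G = np.zeros((20, W))
        G[truth, np.arange(W)] = 1.0
        b = detect_boundary_circular(G, DPParams())
        assert b.closed
        np.testing.assert_array_equal(b.depth_index, truth)

    def test_shift_covariance(self, rng):
        W = 16
        truth = 8 + np.round(2 * np.sin(2 * np.pi * np.arange(W) / W)).astype(int)
        G = np.zeros((16, W))
        G[truth, np.arange(W)] = 1.0
        b0 = detect_boundary_circular(G, DPParams())
        for shift in (3, 7):
            bs = detect_boundary_circular(np.roll(G, shift, axis=1), DPParams())
            np.testing.assert_array_equal(bs.depth_index,
                                          np.roll(b0.depth_index, shift))

    def test_narrow_image_rejected(self):
        with pytest.raises(ValueError):
            detect_boundary_circular(np.zeros((12, 4)), DPParams())

    def test_unpadded_mode_available(self):
        G = np.zeros((12, 16))
        G[5, :] = 1.0
        b = detect_boundary_circular(G, DPParams(pad_mode="none"))
        np.testing.assert_array_equal(b.depth_index, 5)


class TestBoundaryInvariants:
    def test_step_constraint_enforced(self):
        with pytest.raises(ValueError, match="step"):
            LumenBoundary(depth_index=[3, 7, 3])

    def test_alpha_below_one_rejected(self):
        with pytest.raises(ValueError):
            DPParams(alpha=0.5)
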