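"""Connectedness-based binarization and classical metrics vs BFS oracles."""

import math

import numpy as np
import pytest

from fcgbnet import (
    BinaryGraph,
    ConnectivityMatrix,
    FCGBSequence,
    UnconnectableGraphError,
    compute_metrics,
    find_threshold,
    laplacian_lambda2,
    metrics_series,
)

from conftest import oracle_connected, oracle_path_length_and_efficiency


def weighted_graph(values):
    m = np.array(values, dtype=float)
    np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix(m)


def random_weighted(rng, n, p_edge):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.uniform(size=len(iu[0])) < p_edge
    w = rng.uniform(0.05, 1.0, size=len(iu[0])) * mask
    m[iu] = w
    return ConnectivityMatrix(m + m.T)


class TestLambda2:
    def test_disconnected_pair_is_zero(self):
        assert laplacian_lambda2(np.zeros((2, 2))) == 0.0

    def test_triangle_is_three(self):
        A = np.ones((3, 3)) - np.eye(3)
        assert laplacian_lambda2(A) == pytest.approx(3.0)

    def test_path_of_three_is_one(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert laplacian_lambda2(A) == pytest.approx(1.0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            laplacian_lambda2(np.array([[0, 1], [0, 0]], dtype=float))

    def test_positivity_iff_bfs_connected(self, rng):
        """lambda_2 > 0 agrees with BFS connectivity on 200 random graphs."""
        for _ in range(200):
            n = int(rng.integers(2, 13))
            A = (random_weighted(rng, n, rng.uniform(0.1, 0.9)).values > 0).astype(
                float
            )
            assert (laplacian_lambda2(A) > 1e-9) == oracle_connected(A.tolist())


class TestFindThreshold:
    def test_uniform_point_eight_graph(self):
        F = weighted_graph(0.8 * np.ones((4, 4)))
        g = find_threshold(F)
        assert g.threshold_T == pytest.approx(0.79)
        assert laplacian_lambda2(g.adjacency) == pytest.approx(4.0)  # K4

    def test_weighted_path_connects_at_0p49(self):
        F = weighted_graph([[0, 0.9, 0], [0.9, 0, 0.5], [0, 0.5, 0]])
        g = find_threshold(F)
        assert g.threshold_T == pytest.approx(0.49)
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        np.testing.assert_array_equal(g.adjacency, expected)

    def test_block_diagonal_unconnectable(self):
        F = weighted_graph(
            [[0, 0.9, 0, 0], [0.9, 0, 0, 0], [0, 0, 0, 0.9], [0, 0, 0.9, 0]]
        )
        with pytest.raises(UnconnectableGraphError):
            find_threshold(F)

    def test_threshold_is_maximal_and_monotone(self, rng):
        """Binarizing one step above T disconnects; lowering T only adds edges."""
        for _ in range(40):
            n = int(rng.integers(3, 13))
            F = random_weighted(rng, n, rng.uniform(0.4, 0.9))
            try:
                g = find_threshold(F)
            except UnconnectableGraphError:
                assert not oracle_connected((F.values > 0).astype(int).tolist())
                continue
            assert oracle_connected(g.adjacency.astype(int).tolist())
            above = (F.values > g.threshold_T + g.step_used).astype(float)
            np.fill_diagonal(above, 0.0)
            assert not oracle_connected(above.astype(int).tolist())
            # monotone non-decreasing edge set as T decreases
            below = (F.values > g.threshold_T - g.step_used).astype(float)
            np.fill_diagonal(below, 0.0)
            assert np.all(below >= g.adjacency)

    def test_step_refinement_when_weights_are_tiny(self):
        """Edge weights below the coarse grid need the refined step."""
        F = weighted_graph([[0, 0.004, 0], [0.004, 0, 0.007], [0, 0.007, 0]])
        g = find_threshold(F, step=0.01)
        assert g.step_used < 0.01
        assert oracle_connected(g.adjacency.astype(int).tolist())
        assert g.threshold_T < 0.004


class TestComputeMetrics:
    def test_complete_graph_k4(self):
        g = BinaryGraph(np.ones((4, 4)) - np.eye(4), 0.5, 0.01)
        row = compute_metrics(g)
        assert row.clustering == pytest.approx(1.0)
        assert row.char_path_length == pytest.approx(1.0)
        assert row.global_efficiency == pytest.approx(1.0)
        assert row.vulnerability == pytest.approx(0.0)

    def test_five_node_star(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1.0
        row = compute_metrics(BinaryGraph(A, 0.5, 0.01))
        assert row.clustering == pytest.approx(0.0)
        assert row.char_path_length == pytest.approx(1.6)   # (4*1 + 6*2)/10
        assert row.global_efficiency == pytest.approx(0.7)  # (4*1 + 6*0.5)/10
        assert row.vulnerability == pytest.approx(1.0)      # hub removal isolates all

    def test_disconnected_input_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            compute_metrics(BinaryGraph(np.zeros((3, 3)), 0.5, 0.01))

    def test_path_and_efficiency_match_bfs_oracle(self, rng):
        """30 random connected graphs agree with all-pairs BFS to 1e-12."""
        done = 0
        while done < 30:
            n = int(rng.integers(3, 13))
            A = (random_weighted(rng, n, 0.5).values > 0).astype(float)
            if not oracle_connected(A.astype(int).tolist()):
                continue
            row = compute_metrics(BinaryGraph(A, 0.0, 0.01))
            cpl, eff = oracle_path_length_and_efficiency(A.astype(int).tolist())
            assert row.char_path_length == pytest.approx(cpl, abs=1e-12)
            assert row.global_efficiency == pytest.approx(eff, abs=1e-12)
            assert 0.0 <= row.clustering <= 1.0
            assert row.char_path_length >= 1.0
            assert row.vulnerability <= 1.0
            done += 1


class TestMetricsSeries:
    def test_identical_epochs_identical_rows(self, rng):
        F = random_weighted(rng, 6, 0.9)
        seq = FCGBSequence([F, F], 10, 100, 100.0)
        rows = metrics_series(seq)
        assert rows[0].clustering == rows[1].clustering
        assert rows[0].threshold_T == rows[1].threshold_T

    def test_unconnectable_epoch_flagged_not_fatal(self, rng):
        good = random_weighted(rng, 4, 1.0)
        bad = ConnectivityMatrix(
            np.kron(np.eye(2), np.array([[0, 0.9], [0.9, 0]]))
        )
        seq = FCGBSequence([good, bad, good], 10, 100, 100.0)
        rows = metrics_series(seq)
        assert len(rows) == 3
        assert not rows[0].is_missing
        assert rows[1].is_missing
        assert math.isnan(rows[1].char_path_length)

    def test_threshold_matches_standalone_search(self, rng):
        mats = [random_weighted(rng, 5, 0.9) for _ in range(4)]
        seq = FCGBSequence(mats, 10, 100, 100.0)
        rows = metrics_series(seq)
        for m, r in zip(mats, rows):
            assert r.threshold_T == find_threshold(m).threshold_T
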