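"""Similarity matrix, entropy thresholding and centrality features.

Centralities are checked against the brute-force all-pairs BFS / dense
eigensolver oracles in smrnet.reference.
"""

import numpy as np
import pandas as pd
import pytest

from smrnet import network, reference


def random_adjacency(rng, n, p=0.4):
    C = (rng.random((n, n)) < p).astype(int)
    C = np.triu(C, 1)
    return C + C.T


class TestSpearmanAbsMatrix:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.standard_normal(10)
        M = np.vstack([x, np.exp(2 * x) + 5])
        D = network.spearman_abs_matrix(M)
        assert D[0, 1] == pytest.approx(1.0)

    def test_reversal_gives_one(self, rng):
        """Anti-correlated provinces are maximally similar under |rho|."""
        x = rng.standard_normal(12)
        D = network.spearman_abs_matrix(np.vstack([x, -x]))
        assert D[0, 1] == pytest.approx(1.0)

    def test_hand_computed_rank_correlation(self):
        # ranks (1,2,3,4) vs (2,1,4,3): Pearson on ranks = 0.6
        M = np.vstack([[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [1.0, 3.0, 2.0, 4.0]])
        D = network.spearman_abs_matrix(M)
        assert D[0, 1] == pytest.approx(0.6, abs=1e-12)
        assert D[0, 1] == pytest.approx(
            abs(reference.pearson_on_ranks(M[0], M[1])), abs=1e-12
        )

    def test_symmetry_and_unit_diagonal(self, rng):
        M = rng.standard_normal((8, 6))
        D = network.spearman_abs_matrix(M)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 1.0)

    def test_constant_province_is_error(self):
        M = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError):
            network.spearman_abs_matrix(M)


class TestBetweenness:
    def test_path_graph(self):
        C = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        np.testing.assert_allclose(network.betweenness(C), [0, 1, 0])

    def test_complete_graph(self):
        C = 1 - np.eye(4, dtype=int)
        np.testing.assert_allclose(network.betweenness(C), 0)

    def test_cycle_c4(self):
        """Opposite pair has 2 geodesics, one through each intermediate."""
        C = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]])
        np.testing.assert_allclose(network.betweenness(C), 0.5)

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(25):
            C = random_adjacency(rng, int(rng.integers(3, 8)))
            np.testing.assert_allclose(
                network.betweenness(C), reference.betweenness_bruteforce(C), atol=1e-12
            )


class TestEntropy:
    def test_uniform_betweenness_is_log_n(self):
        # cycle C5: all nodes equal betweenness > 0 -> H = log2 5
        n = 5
        C = np.zeros((n, n), dtype=int)
        for i in range(n):
            C[i, (i + 1) % n] = C[(i + 1) % n, i] = 1
        assert network.entropy_of_betweenness(C) == pytest.approx(np.log2(n))

    def test_star_graph_point_mass(self):
        C = np.zeros((5, 5), dtype=int)
        C[0, 1:] = C[1:, 0] = 1
        assert network.entropy_of_betweenness(C) == 0.0

    def test_path_p4_one_bit(self):
        C = np.diag(np.ones(3), 1).astype(int)
        C = C + C.T
        assert network.entropy_of_betweenness(C) == pytest.approx(1.0)

    def test_empty_graph_zero(self):
        assert network.entropy_of_betweenness(np.zeros((4, 4), dtype=int)) == 0.0


class TestThresholdScan:
    def test_degenerate_constant_similarity(self):
        D = np.full((5, 5), 0.5)
        np.fill_diagonal(D, 1.0)
        net = network.threshold_scan(D)
        # every threshold gives H=0; tie rule returns the smallest candidate
        assert net.threshold == pytest.approx(0.5)
        assert all(h == 0.0 for _, h in net.entropy_curve)

    def test_maximum_verified_exhaustively(self, rng):
        for trial in range(5):
            n = 8
            D = rng.uniform(0, 1, (n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 1.0)
            net = network.threshold_scan(D)
            # independent recomputation at every distinct threshold
            best = max(
                (
                    reference.entropy_bruteforce(
                        reference.betweenness_bruteforce(network.adjacency(D, th))
                    )
                    for th in np.unique(D[~np.eye(n, dtype=bool)])
                )
            )
            got = reference.entropy_bruteforce(
                reference.betweenness_bruteforce(net.C)
            )
            assert got == pytest.approx(best, abs=1e-12)

    def test_bridge_between_blocks(self, rng):
        """Two dense blocks joined by one moderately-similar bridge pair."""
        n = 10
        D = np.full((n, n), 0.1)
        D[:5, :5] = 0.9
        D[5:, 5:] = 0.9
        D[4, 5] = D[5, 4] = 0.5
        np.fill_diagonal(D, 1.0)
        net = network.threshold_scan(D)
        assert net.threshold <= 0.5  # the chosen network retains the bridge
        assert net.C[4, 5] == 1

    def test_edge_monotonicity_in_threshold(self, rng):
        D = rng.uniform(0, 1, (9, 9))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 1.0)
        ths = np.sort(rng.uniform(0, 1, 6))
        prev = None
        for th in ths:
            C = network.adjacency(D, th)
            if prev is not None:
                assert np.all(C <= prev)  # raising th never adds edges
            prev = C

    def test_relabeling_invariance(self, rng):
        n = 7
        D = rng.uniform(0, 1, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 1.0)
        perm = rng.permutation(n)
        net1 = network.threshold_scan(D)
        net2 = network.threshold_scan(D[np.ix_(perm, perm)])
        assert net1.threshold == pytest.approx(net2.threshold)
        np.testing.assert_array_equal(net1.C[np.ix_(perm, perm)], net2.C)

    def test_too_small(self):
        with pytest.raises(ValueError):
            network.threshold_scan(np.array([[1.0]]))


class TestCentralityFeatures:
    def test_complete_k5_symmetry(self):
        C = 1 - np.eye(5, dtype=int)
        feats = network.centrality_features(
            network.ProvinceNetwork(C.astype(float), 0.5, C, [])
        )
        np.testing.assert_allclose(feats["degree"], 4)
        np.testing.assert_allclose(feats["closeness"], 1.0)
        np.testing.assert_allclose(feats["eigenvector"], 1 / np.sqrt(5), atol=1e-9)

    def test_star_closeness_and_eigenvector(self):
        n = 5
        C = np.zeros((n, n), dtype=int)
        C[0, 1:] = C[1:, 0] = 1
        feats = network.centrality_features(network.ProvinceNetwork(C.astype(float), 0.5, C, []))
        assert feats["closeness"][0] == pytest.approx(1.0)
        np.testing.assert_allclose(feats["closeness"][1:], 4 / 7)
        # hub/leaf eigenvector ratio is sqrt(N-1) = 2 for a star
        assert feats["eigenvector"][0] / feats["eigenvector"][1] == pytest.approx(2.0, abs=1e-8)

    def test_all_centralities_match_bruteforce(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 8))
            C = random_adjacency(rng, n)
            feats = network.centrality_features(
                network.ProvinceNetwork(C.astype(float), 0.5, C, [])
            )
            np.testing.assert_allclose(feats["degree"], reference.degree_bruteforce(C))
            np.testing.assert_allclose(
                feats["betweenness"], reference.betweenness_bruteforce(C), atol=1e-12
            )
            np.testing.assert_allclose(
                feats["closeness"], reference.closeness_bruteforce(C), atol=1e-12
            )
            v = feats["eigenvector"].to_numpy()
            if C.sum() == 0:
                np.testing.assert_allclose(v, 0)
            else:
                lam, _ = reference.eigenvector_bruteforce(C)
                assert np.all(v >= -1e-12)
                assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-8)
                assert np.linalg.norm(C @ v - lam * v) < 1e-8

    def test_isolated_node_zero_closeness(self):
        C = np.zeros((3, 3), dtype=int)
        C[0, 1] = C[1, 0] = 1
        feats = network.centrality_features(network.ProvinceNetwork(C.astype(float), 0.5, C, []))
        assert feats["closeness"][2] == 0.0


class TestAugmentPanel:
    def _parts(self, rng, n=6):
        panel = pd.DataFrame(
            rng.standard_normal((n, 5)),
            index=[f"P{i}" for i in range(n)],
            columns=list("abcde"),
        )
        C = random_adjacency(rng, n)
        net = network.ProvinceNetwork(C.astype(float), 0.5, C, [], node_ids=panel.index.to_numpy())
        feats = network.centrality_features(net)
        feats.index = panel.index
        return panel, feats

    def test_appends_four_columns(self, rng):
        panel, feats = self._parts(rng)
        out = network.augment_panel(panel, feats)
        assert out.shape == (6, 9)
        pd.testing.assert_frame_equal(out[panel.columns], panel)

    def test_empty_network_zero_columns(self, rng):
        panel, _ = self._parts(rng)
        C = np.zeros((6, 6), dtype=int)
        feats = network.centrality_features(network.ProvinceNetwork(C.astype(float), 0.5, C, []))
        feats.index = panel.index
        out = network.augment_panel(panel, feats)
        assert (out[["degree", "betweenness", "closeness", "eigenvector"]] == 0).all().all()

    def test_id_mismatch_error(self, rng):
        panel, feats = self._parts(rng)
        feats.index = [f"Q{i}" for i in range(6)]
        with pytest.raises(ValueError):
            network.augment_panel(panel, feats)
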