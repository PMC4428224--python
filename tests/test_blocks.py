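"""Block enumeration, edge matrices, and SVD summaries."""
import numpy as np
import pandas as pd
import pytest

from modconn.blocks import (block_edge_matrix, block_label,
                            block_mean_connectivity, block_svd_summary,
                            coordinates_table, enumerate_blocks,
                            summarize_blocks)
from modconn.connectivity import SubjectConnectome, build_connectome
from modconn.synthetic import SimulationDesign, generate_parcellation

from conftest import run_synthetic_study, make_design


class TestEnumerateBlocks:
    def test_two_modules_give_three_blocks(self, toy_parcellation):
        bi = enumerate_blocks(toy_parcellation)
        assert len(bi) == 3
        assert bi.labels == ("Med Vis - Med Vis", "Med Vis - DMN",
                             "DMN - DMN")
        assert [b.n_edges for b in bi] == [1, 4, 1]

    def test_blocks_partition_upper_triangle(self):
        design = SimulationDesign(n_modules=4, nodes_per_module=(3, 5, 2, 4))
        parc = generate_parcellation(design)
        bi = enumerate_blocks(parc)
        n = parc.n_nodes
        assert len(bi) == 4 + 6
        all_edges = np.concatenate([b.edges for b in bi])
        assert len(all_edges) == n * (n - 1) // 2
        assert np.all(all_edges[:, 0] < all_edges[:, 1])
        assert len({tuple(e) for e in all_edges}) == len(all_edges)

    def test_block_sizes_follow_module_sizes(self):
        design = SimulationDesign(n_modules=3, nodes_per_module=(3, 4, 5))
        bi = enumerate_blocks(generate_parcellation(design))
        sizes = {b.label: b.n_edges for b in bi}
        assert sizes[block_label("Med Vis", "Med Vis")] == 3
        assert sizes[block_label("OP Vis", "OP Vis")] == 6
        assert sizes[block_label("Med Vis", "OP Vis")] == 12


def _toy_connectomes(rng, n_nodes=4, n_subjects=3):
    ids = tuple(f"n{i}" for i in range(n_nodes))
    out = []
    for s in range(n_subjects):
        X = rng.standard_normal((30, n_nodes))
        out.append(build_connectome(X, f"sub-{s}", ids))
    return out


class TestBlockEdgeMatrix:
    def test_values_round_trip(self, rng, toy_parcellation):
        conns = _toy_connectomes(rng)
        bi = enumerate_blocks(toy_parcellation)
        for block in bi:
            M = block_edge_matrix(conns, block)
            assert M.shape == (block.n_edges, 3)
            for e, (i, j) in enumerate(block.edges):
                for s, c in enumerate(conns):
                    assert M[e, s] == c.matrix[i, j]

    def test_node_order_mismatch_raises(self, rng, toy_parcellation):
        conns = _toy_connectomes(rng)
        R = conns[1].matrix
        bad = SubjectConnectome("sub-1", R, ("x0", "x1", "x2", "x3"))
        bi = enumerate_blocks(toy_parcellation)
        with pytest.raises(ValueError, match="node order mismatch"):
            block_edge_matrix([conns[0], bad], bi[0])


class TestBlockSvdSummary:
    def test_rank_one_matrix_recovered_exactly(self):
        u = np.array([3.0, 0.0, 4.0]) / 5.0
        v = np.array([1.0, -2.0, 0.5, 0.5])
        v = v - v.mean()
        X = np.outer(u, v)  # already row-demeaned
        s = block_svd_summary(X)
        np.testing.assert_allclose(np.abs(s.left_vector), np.abs(u),
                                   atol=1e-12)
        got = s.coordinates.to_numpy()
        ratio = got / v
        np.testing.assert_allclose(ratio, ratio[0], atol=1e-10)
        assert s.variance_explained == pytest.approx(1.0, abs=1e-12)

    def test_single_edge_block_coordinates_are_demeaned_edge_values(self, rng):
        x = rng.standard_normal(6)
        s = block_svd_summary(x[None, :])
        got = s.coordinates.to_numpy()
        expect = x - x.mean()
        # equal up to a global sign
        sign = np.sign(np.dot(got, expect))
        np.testing.assert_allclose(got, sign * expect, atol=1e-12)

    def test_matches_gram_matrix_oracle(self, rng):
        """First singular pair agrees with an independent eigendecomposition
        of the subject-space Gram matrix."""
        X = rng.standard_normal((20, 24))
        Xd = X - X.mean(axis=1, keepdims=True)
        s = block_svd_summary(X)
        G = Xd.T @ Xd
        w, V = np.linalg.eigh(G)
        sigma = np.sqrt(w[-1])
        coords = sigma * V[:, -1]
        got = s.coordinates.to_numpy()
        if np.dot(coords, got) < 0:
            coords = -coords
        np.testing.assert_allclose(got, coords, atol=1e-10)
        assert s.variance_explained == pytest.approx(w[-1] / w.sum(),
                                                     abs=1e-12)

    def test_coordinates_sum_to_zero(self, rng):
        for m, n in [(1, 5), (10, 24), (100, 24)]:
            s = block_svd_summary(rng.standard_normal((m, n)))
            assert abs(s.coordinates.sum()) < 1e-10

    def test_sign_aligned_with_block_mean(self, rng):
        X = rng.standard_normal((15, 10)) + 0.3
        s = block_svd_summary(X)
        r = np.corrcoef(s.coordinates, s.mean_connectivity)[0, 1]
        assert r > 0

    def test_left_vector_unit_norm_and_variance_bounds(self, rng):
        s = block_svd_summary(rng.standard_normal((30, 12)))
        assert np.linalg.norm(s.left_vector) == pytest.approx(1.0, abs=1e-12)
        assert 1.0 / min(30, 11) <= s.variance_explained <= 1.0

    def test_subject_order_invariance(self, rng):
        X = rng.standard_normal((12, 8))
        ids = [f"s{k}" for k in range(8)]
        perm = rng.permutation(8)
        a = block_svd_summary(X, ids)
        b = block_svd_summary(X[:, perm], [ids[k] for k in perm])
        np.testing.assert_allclose(a.coordinates.reindex(b.coordinates.index),
                                   b.coordinates, atol=1e-9)

    def test_edge_order_invariance(self, rng):
        X = rng.standard_normal((12, 8))
        perm = rng.permutation(12)
        a = block_svd_summary(X)
        b = block_svd_summary(X[perm])
        np.testing.assert_allclose(a.coordinates, b.coordinates, atol=1e-9)

    def test_no_variation_raises(self):
        with pytest.raises(ValueError, match="no variation"):
            block_svd_summary(np.ones((4, 6)))


class TestBlockMeanConnectivity:
    def test_hand_computed_toy(self, toy_parcellation):
        # two subjects with fixed 4x4 matrices
        def mat(v01, v23, cross):
            R = np.full((4, 4), cross)
            R[0, 1] = R[1, 0] = v01
            R[2, 3] = R[3, 2] = v23
            np.fill_diagonal(R, 1.0)
            return R

        ids = tuple(toy_parcellation.nodes["node_id"])
        conns = [SubjectConnectome("s1", mat(0.5, -0.2, 0.1), ids),
                 SubjectConnectome("s2", mat(0.3, -0.4, -0.1), ids)]
        groups = pd.Series({"s1": 1, "s2": 2})
        bi = enumerate_blocks(toy_parcellation)
        per, gm, dom = block_mean_connectivity(conns,
                                               bi["Med Vis - Med Vis"], groups)
        assert per.tolist() == [0.5, 0.3]
        assert gm[1] == 0.5 and gm[2] == 0.3
        assert dom == {1: 1, 2: 1}
        per, gm, dom = block_mean_connectivity(conns, bi["DMN - DMN"], groups)
        assert per.tolist() == [-0.2, -0.4]
        assert dom == {1: -1, 2: -1}
        per, _, _ = block_mean_connectivity(conns, bi["Med Vis - DMN"])
        np.testing.assert_allclose(per.to_numpy(), [0.1, -0.1], atol=1e-12)

    def test_mixed_edges_average_to_zero(self, toy_parcellation):
        ids = tuple(toy_parcellation.nodes["node_id"])
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.2
        R[2, 3] = R[3, 2] = -0.2
        c = SubjectConnectome("s1", R, ids)
        bi = enumerate_blocks(toy_parcellation)
        per, _, _ = block_mean_connectivity([c, c], bi["Med Vis - DMN"])
        assert per.iloc[0] == 0.0


def test_summaries_zero_sum_on_synthetic_study(small_study):
    coords = coordinates_table(small_study["summaries"])
    assert np.abs(coords.sum(axis=0)).max() < 1e-10


def test_planted_effect_recovered_in_coordinates():
    """Group-mean coordinate difference carries the planted sign across
    seeds (parameter recovery at delta = 0.3, T = 1000)."""
    label = block_label("EC", "FPR")
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        study = run_synthetic_study(
            make_design(seed=seed, planted=[("EC", "FPR", 0.3, 1)],
                        sizes=(2, 2, 2, 2, 2, 2, 3, 3, 2)))
        s = study["summaries"][label]
        g = study["groups"]
        diff = (s.coordinates[g == 1].mean() - s.coordinates[g == 2].mean())
        if diff > 0:
            hits += 1
    assert hits >= 0.95 * n_seeds
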