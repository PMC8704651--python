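import numpy as np
import pytest

from brainlayers.multilayer import (
    build_supra,
    kcore_distribution,
    ml_degree,
    ml_eigenvector,
    ml_kcore,
    ml_pagerank,
)
from brainlayers.single_layer import (
    degree,
    eigenvector_centrality,
    kcore,
    pagerank,
)

from conftest import random_graph
from test_single_layer import TRIANGLE, pagerank_oracle


def random_stack(rng, n=10, L=4, p=0.3):
    return [random_graph(rng, n=n, p=p) for _ in range(L)]


class TestBuildSupra:
    def test_block_structure_of_identical_triangles(self):
        supra = build_supra([TRIANGLE] * 4, interlayer_weight=1.0)
        assert supra.matrix.shape == (12, 12)
        deg = supra.matrix.sum(axis=1)
        # intra-degree 2 plus inter-degree 3 at every node-layer
        assert np.allclose(deg, 5.0)
        for a in range(4):
            assert np.array_equal(supra.intra_block(a), TRIANGLE)

    def test_zero_interlayer_weight_is_block_diagonal(self, rng):
        nets = random_stack(rng)
        supra = build_supra(nets, interlayer_weight=0.0)
        off = supra.matrix.copy()
        for a in range(4):
            s = slice(a * 10, (a + 1) * 10)
            off[s, s] = 0
        assert np.all(off == 0)

    def test_offdiagonal_blocks_are_weighted_identity(self, rng):
        nets = random_stack(rng)
        w = 0.7
        supra = build_supra(nets, interlayer_weight=w)
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                block = supra.matrix[a * 10 : (a + 1) * 10, b * 10 : (b + 1) * 10]
                assert np.array_equal(block, w * np.eye(10))

    def test_mismatched_sizes_rejected(self, rng):
        with pytest.raises(ValueError, match="electrodes"):
            build_supra([random_graph(rng, n=5), random_graph(rng, n=6)])


class TestMlDegree:
    def test_two_triangle_layers(self):
        supra = build_supra([TRIANGLE, TRIANGLE])
        assert ml_degree(supra).values.tolist() == [4, 4, 4]

    def test_empty_layers(self):
        supra = build_supra([np.zeros((4, 4))] * 3)
        assert np.all(ml_degree(supra).values == 0)

    def test_equals_sum_of_per_layer_degrees(self, rng):
        nets = random_stack(rng)
        supra = build_supra(nets)
        expected = sum(degree(a).values for a in nets)
        assert np.array_equal(ml_degree(supra).values, expected)


class TestMlPagerank:
    def test_single_layer_reduction(self, rng):
        a = random_graph(rng, n=12)
        supra = build_supra([a])
        assert np.allclose(ml_pagerank(supra, r=0.85).values,
                           pagerank(a, damping=0.85).values, atol=1e-12)

    def test_identical_layers_have_uniform_replica_occupancy(self, rng):
        a = random_graph(rng, n=8, p=0.4)
        supra = build_supra([a] * 3)
        from brainlayers.single_layer import pagerank_vector

        p = pagerank_vector(supra.matrix, damping=0.85)
        per_layer = p.reshape(3, 8)
        assert np.allclose(per_layer, per_layer[0], atol=1e-10)

    def test_matches_power_iteration_on_supra_walk(self, rng):
        supra = build_supra(random_stack(rng, n=8))
        got = ml_pagerank(supra, r=0.85).values
        ref = pagerank_oracle(supra.matrix, 0.85).reshape(4, 8).sum(axis=0)
        assert np.allclose(got, ref, atol=1e-10)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)


class TestMlEigenvector:
    def test_identical_layers_proportional_to_single_layer(self, rng):
        """Supra eigenvector of L identical layers is ones_L (x) u with
        eigenvalue lambda_1 + (L-1) * weight."""
        a = TRIANGLE + 0.0
        a = np.zeros((5, 5))
        a[:3, :3] = TRIANGLE
        a[2, 3] = a[3, 2] = 1
        a[3, 4] = a[4, 3] = 1
        L, w = 4, 1.0
        supra = build_supra([a] * L, interlayer_weight=w)
        u = eigenvector_centrality(a).values
        got = ml_eigenvector(supra).values
        assert np.allclose(got, u / np.linalg.norm(u), atol=1e-8)
        lam_single = np.linalg.eigvalsh(a)[-1]
        lam_supra = np.linalg.eigvalsh(supra.matrix)[-1]
        assert lam_supra == pytest.approx(lam_single + (L - 1) * w, abs=1e-10)

    def test_single_layer_reduction(self, rng):
        a = random_graph(rng, n=10)
        supra = build_supra([a])
        assert np.allclose(ml_eigenvector(supra).values,
                           eigenvector_centrality(a).values, atol=1e-12)

    def test_matches_dense_eigendecomposition(self, rng):
        supra = build_supra(random_stack(rng, n=8))
        w, v = np.linalg.eigh(supra.matrix)
        lead = np.abs(v[:, -1])
        ref = lead.reshape(4, 8).sum(axis=0)
        ref = ref / np.linalg.norm(ref)
        assert np.allclose(ml_eigenvector(supra).values, ref, atol=1e-8)


class TestMlKcore:
    def test_triangular_prism_is_3_core(self):
        supra = build_supra([TRIANGLE, TRIANGLE], interlayer_weight=1.0)
        assert ml_kcore(supra).values.tolist() == [3, 3, 3]

    def test_empty_layers_leave_replica_cliques(self):
        # empty layers, weight 1: replicas form K_L per electrode -> core L-1
        L = 4
        supra = build_supra([np.zeros((3, 3))] * L, interlayer_weight=1.0)
        assert ml_kcore(supra).values.tolist() == [L - 1] * 3

    def test_single_layer_reduction(self, rng):
        a = random_graph(rng, n=10)
        supra = build_supra([a])
        assert np.array_equal(ml_kcore(supra).values, kcore(a).values)

    def test_nonunit_weight_warns_and_uses_unweighted_graph(self, rng):
        supra = build_supra([TRIANGLE, TRIANGLE], interlayer_weight=0.5)
        with pytest.warns(UserWarning, match="unweighted"):
            vals = ml_kcore(supra).values
        assert vals.tolist() == [3, 3, 3]

    def test_coreness_distribution_table(self, rng):
        supra = build_supra(random_stack(rng, n=6))
        tab = kcore_distribution(supra)
        assert tab["n_k"].sum() == 24
        assert ((tab["P"] >= 0) & (tab["P"] <= 1)).all()
        # the maximal core has P = 1 at its own level only when it is the
        # only level; in general n_k / kcore_size is a proper fraction
        assert tab["kcore_size"].is_monotonic_decreasing


def test_layer_order_invariance_of_aggregates(rng):
    nets = random_stack(rng, n=8)
    supra = build_supra(nets)
    perm_supra = build_supra([nets[2], nets[0], nets[3], nets[1]])
    for fn in (ml_degree, ml_kcore, ml_pagerank):
        assert np.allclose(fn(supra).values, fn(perm_supra).values, atol=1e-9)


def test_electrode_permutation_equivariance(rng):
    nets = random_stack(rng, n=8)
    perm = rng.permutation(8)
    supra = build_supra(nets)
    supra_p = build_supra([a[np.ix_(perm, perm)] for a in nets])
    for fn in (ml_degree, ml_kcore, ml_pagerank):
        assert np.allclose(fn(supra).values[perm], fn(supra_p).values, atol=1e-9)


def test_extended_edge_list_covers_intra_and_inter_edges(rng):
    from brainlayers.multilayer import extended_edge_list

    supra = build_supra([TRIANGLE, TRIANGLE], interlayer_weight=1.0)
    tab = extended_edge_list(supra)
    assert len(tab) == int(supra.matrix.sum()) // 2
    inter = tab[tab.layer_i != tab.layer_j]
    assert (inter.node_i == inter.node_j).all()
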