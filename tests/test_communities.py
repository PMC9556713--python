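"""Walktrap community detection: transition matrix, modularity, dendrogram."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import symptomnet as sn
from symptomnet.estimation import IsingNetwork

from conftest import random_network


def _net(weight_pairs, p, w=1.0):
    W = np.zeros((p, p))
    for pair in weight_pairs:
        if len(pair) == 3:
            a, b, wt = pair
        else:
            (a, b), wt = pair, w
        W[a, b] = W[b, a] = wt
    return IsingNetwork([f"n{i}" for i in range(p)], W, np.zeros(p))


class TestTransitionMatrix:
    def test_single_edge(self):
        P = sn.walk_transition_matrix(_net([(0, 1, 0.8)], 2))
        assert np.allclose(P, [[0, 1], [1, 0]])

    def test_equal_triangle(self):
        P = sn.walk_transition_matrix(_net([(0, 1), (1, 2), (0, 2)], 3))
        assert np.allclose(P, 0.5 * (np.ones((3, 3)) - np.eye(3)))

    def test_isolated_self_loop(self):
        P = sn.walk_transition_matrix(_net([(0, 1)], 3))
        assert P[2, 2] == 1.0

    def test_rows_stochastic_nonnegative(self):
        for seed in range(10):
            net = random_network(seed, signed=True)
            P = sn.walk_transition_matrix(net)
            assert np.all(P >= 0)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestModularity:
    def test_one_community_zero(self):
        net = _net([(0, 1), (1, 2)], 3)
        assert sn.modularity(net, {f"n{i}": 0 for i in range(3)}) == pytest.approx(0.0)

    def test_two_cliques_half(self):
        net = _net([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6, w=0.7)
        labels = {f"n{i}": int(i >= 3) for i in range(6)}
        assert sn.modularity(net, labels) == pytest.approx(0.5)

    def test_singleton_split_negative(self):
        net = _net([(0, 1, 0.4)], 2)
        assert sn.modularity(net, {"n0": 0, "n1": 1}) == pytest.approx(-0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_double_sum_oracle(self, seed):
        net = random_network(seed, p_min=6, p_max=6, signed=True)
        rng = np.random.default_rng(seed + 100)
        labels = {lab: int(c) for lab, c in
                  zip(net.node_labels, rng.integers(0, 3, net.p))}
        A = np.abs(net.weights)
        m = A[np.triu_indices(net.p, 1)].sum()
        if m == 0:
            pytest.skip("empty draw")
        # direct double-sum definition: (1/2m) sum_ij (A_ij - d_i d_j / 2m) δ(c_i,c_j)
        d = A.sum(axis=1)
        lab = np.array([labels[x] for x in net.node_labels])
        q = 0.0
        for i in range(net.p):
            for j in range(net.p):
                if lab[i] == lab[j]:
                    q += A[i, j] - d[i] * d[j] / (2 * m)
        q /= 2 * m
        assert sn.modularity(net, labels) == pytest.approx(q, abs=1e-12)

    def test_empty_network_warns(self):
        net = _net([], 3)
        with pytest.warns(UserWarning):
            assert sn.modularity(net, {f"n{i}": 0 for i in range(3)}) == 0.0


class TestWalktrap:
    def test_two_disconnected_triangles(self):
        net = _net([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6, w=0.7)
        part = sn.walktrap(net)
        assert part.n_communities == 2
        assert len({part.labels[f"n{i}"] for i in range(3)}) == 1
        assert len({part.labels[f"n{i}"] for i in range(3, 6)}) == 1
        assert part.modularity_per_cut[part.chosen_cut] == pytest.approx(0.5)

    def test_single_edge_one_community(self):
        part = sn.walktrap(_net([(0, 1, 0.4)], 2))
        assert part.n_communities == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_three_blocks_recovered(self, seed):
        model = sn.make_planted_model(12, 3, 1.0, 0.05, (0, 0), seed)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(12)
        W = model.beta[np.ix_(perm, perm)]
        labels = [model.node_labels[i] for i in perm]
        net = IsingNetwork(labels, W, np.zeros(12))
        part = sn.walktrap(net)
        truth = [model.true_communities[l] for l in labels]
        pred = [part.labels[l] for l in labels]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_merge_count_invariant(self):
        # merges = initial singletons - connected components
        net = _net([(0, 1), (1, 2), (3, 4)], 6)  # components: {0,1,2},{3,4},{5}
        part = sn.walktrap(net)
        assert len(part.merge_sequence) == 6 - 3
        assert len(part.modularity_per_cut) == len(part.merge_sequence) + 1

    def test_isolated_nodes_stay_singletons(self):
        net = _net([(0, 1), (1, 2), (0, 2)], 5)
        part = sn.walktrap(net)
        assert part.labels["n3"] != part.labels["n4"]
        assert part.labels["n3"] not in {part.labels[f"n{i}"] for i in range(3)}

    def test_chosen_cut_attains_maximum(self):
        for seed in range(5):
            net = random_network(seed, p_min=6, p_max=9)
            part = sn.walktrap(net)
            assert part.modularity_per_cut[part.chosen_cut] == max(
                part.modularity_per_cut)

    def test_permutation_equivariance(self):
        net = random_network(3, p_min=8, p_max=8)
        part = sn.walktrap(net)
        rng = np.random.default_rng(1)
        perm = rng.permutation(net.p)
        net2 = IsingNetwork([net.node_labels[i] for i in perm],
                            net.weights[np.ix_(perm, perm)],
                            net.thresholds[perm])
        part2 = sn.walktrap(net2)
        # same grouping of the same node labels
        for a, b in itertools.combinations(net.node_labels, 2):
            assert ((part.labels[a] == part.labels[b])
                    == (part2.labels[a] == part2.labels[b]))

    def test_clique_components_returned_exactly(self):
        net = _net([(0, 1), (2, 3), (3, 4), (2, 4)], 5)
        part = sn.walktrap(net)
        groups = {}
        for n, c in part.labels.items():
            groups.setdefault(c, set()).add(n)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset({"n0", "n1"}), frozenset({"n2", "n3", "n4"})}

    def test_negative_edges_enter_as_absolute(self):
        pos = _net([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6, w=0.7)
        W = pos.weights.copy()
        W[0, 1] = W[1, 0] = -0.7
        neg = IsingNetwork(pos.node_labels, W, np.zeros(6))
        assert sn.walktrap(neg).labels == sn.walktrap(pos).labels

    def test_invalid_walk_length(self):
        with pytest.raises(ValueError):
            sn.walktrap(_net([(0, 1)], 2), t=0)


class TestIgraphCrossCheck:
    """The reference implementation (igraph community_walktrap) as an
    independent oracle: on clean block structure memberships must agree, and
    on arbitrary graphs our maximum-modularity cut is never worse."""

    def test_block_structure_agreement(self):
        import igraph as ig
        model = sn.make_planted_model(12, 3, 1.0, 0.05, (0, 0), 2)
        net = IsingNetwork(model.node_labels, model.beta, np.zeros(12))
        mine = sn.walktrap(net, t=4)
        g = ig.Graph.Adjacency((model.beta > 0).tolist(), mode="undirected")
        g.es["weight"] = [model.beta[e.source, e.target] for e in g.es]
        theirs = g.community_walktrap(weights="weight", steps=4).as_clustering()
        a = [mine.labels[l] for l in net.node_labels]
        assert adjusted_rand_score(a, theirs.membership) == 1.0

    def test_comparable_modularity_on_random_graphs(self):
        """Merge-cost tie-breaking details differ between implementations, so
        either dendrogram can win on one graph; over many graphs the chosen
        cuts must be of the same quality."""
        import igraph as ig
        diffs = []
        for seed in range(12):
            net = random_network(seed, p_min=6, p_max=11)
            W = net.weights
            if not (W > 0).any():
                continue
            mine = sn.walktrap(net, t=4)
            g = ig.Graph.Adjacency((W > 0).tolist(), mode="undirected")
            g.es["weight"] = [W[e.source, e.target] for e in g.es]
            try:
                theirs = g.community_walktrap(weights="weight",
                                              steps=4).as_clustering()
            except ig.InternalError:
                continue
            q_mine = mine.modularity_per_cut[mine.chosen_cut]
            diffs.append(q_mine - theirs.modularity)
        assert len(diffs) >= 8
        assert np.mean(diffs) > -0.01
        assert min(diffs) > -0.1
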