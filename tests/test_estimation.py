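"""Estimator tests: pseudo-likelihood, EBIC selection, lasso path, rules."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logit

import symptomnet as sn
from symptomnet.estimation import (DegenerateNodeError, EstimationConfig,
                                   NodewiseFit, read_edgelist, write_edgelist,
                                   write_graphml)
from symptomnet.io import OccurrenceMatrix


def _matrix(rows, codes=None):
    arr = np.asarray(rows, dtype=float)
    codes = codes or [f"s{j}" for j in range(arr.shape[1])]
    return OccurrenceMatrix(arr, [f"p{i}" for i in range(arr.shape[0])], codes)


class TestPseudoLoglik:
    def test_zero_parameters(self):
        X = _matrix([[1, 1], [0, 1], [1, 0]])
        assert sn.pseudo_loglik(0.0, np.zeros(1), X, 0) == pytest.approx(
            -3 * np.log(2), abs=1e-12)

    def test_single_row_closed_form(self):
        X = _matrix([[1, 0]])
        t = 0.7
        assert sn.pseudo_loglik(t, np.zeros(1), X, 0) == pytest.approx(
            t - np.log(1 + np.exp(t)), abs=1e-12)

    def test_two_row_hand_value(self):
        X = _matrix([[1, 1], [0, 1]])
        v = sn.pseudo_loglik(0.5, np.array([1.0]), X, 0)
        assert v == pytest.approx(1.5 - 2 * np.log(1 + np.exp(1.5)), abs=1e-10)

    def test_dimension_mismatch(self):
        X = _matrix([[1, 1, 0]])
        with pytest.raises(ValueError):
            sn.pseudo_loglik(0.0, np.zeros(1), X, 0)


class TestEbic:
    def test_gamma_zero_is_bic(self):
        assert sn.ebic(-50, 3, 200, 10, 0.0) == pytest.approx(
            100 + 3 * np.log(200))

    def test_empty_neighborhood(self):
        assert sn.ebic(-50, 0, 200, 10, 5.0) == 100.0

    def test_scalar_evaluation(self):
        assert sn.ebic(-100, 2, 100, 38, 0.25) == pytest.approx(
            200 + 2 * np.log(100) + 0.5 * 2 * np.log(37), abs=1e-9)


class TestPath:
    @pytest.fixture(scope="class")
    def data(self):
        model = sn.make_planted_model(5, 2, 1.2, 0.0, (-1.5, -0.5), 17)
        return sn.gibbs_sample(model, 400, seed=4)

    def test_rho_max_fit_is_intercept_only(self, data):
        fits = sn.fit_node_lasso_path(data, 0)
        first = fits[0]
        assert first.neighbor_set == ()
        assert first.intercept == pytest.approx(
            logit(data.values[:, 0].mean()), abs=1e-6)

    def test_constant_column_degenerate(self):
        X = _matrix([[1, 1], [1, 0], [1, 1]])
        with pytest.raises(DegenerateNodeError):
            sn.fit_node_lasso_path(X, 0)

    def test_objective_matches_convex_oracle(self, data):
        """Penalized objective at the solver's solution vs L-BFGS-B on the
        split positive/negative-part formulation."""
        V = data.values
        fits = sn.fit_node_lasso_path(data, 1)
        m = V.shape[1] - 1
        for f in fits[::20]:
            def neg_obj(z, rho=f.rho):
                b = z[1:1 + m] - z[1 + m:]
                return -sn.pseudo_loglik(z[0], b, V, 1) + rho * z[1:].sum()
            z0 = np.zeros(1 + 2 * m)
            z0[0] = f.intercept
            res = minimize(neg_obj, z0, method="L-BFGS-B",
                           bounds=[(None, None)] + [(0, None)] * (2 * m),
                           options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12})
            mine = (-sn.pseudo_loglik(f.intercept, f.coefficients, V, 1)
                    + f.rho * np.abs(f.coefficients).sum())
            assert mine <= res.fun + 1e-6

    def test_independent_columns_mostly_empty(self):
        empty = 0
        for seed in range(6):
            model = sn.make_planted_model(5, 5, 0.0, 0.0, (0.0, 0.0), seed)
            X = sn.gibbs_sample(model, 500, seed=seed)
            net = sn.estimate_network(X)
            empty += len(net.edges()) == 0
        assert empty >= 5


class TestSelectByEbic:
    def _fit(self, ebic_value, n_neighbors, rho, loglik=-10.0, n=100):
        coefs = np.zeros(9)
        coefs[:n_neighbors] = 0.5
        return NodewiseFit(0, 0.0, coefs, tuple(range(1, 1 + n_neighbors)),
                           rho, loglik, ebic_value, n=n)

    def test_picks_minimum(self):
        fits = [self._fit(212.8, 2, 1.0), self._fit(205.1, 3, 0.5),
                self._fit(300.0, 5, 0.1)]
        assert sn.select_by_ebic(fits).ebic_value == 205.1

    def test_tie_prefers_smaller_neighborhood(self):
        fits = [self._fit(100.0, 3, 0.2), self._fit(100.0, 1, 0.1)]
        assert len(sn.select_by_ebic(fits).neighbor_set) == 1

    def test_tie_then_larger_rho(self):
        fits = [self._fit(100.0, 1, 0.1), self._fit(100.0, 1, 0.9)]
        assert sn.select_by_ebic(fits).rho == 0.9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sn.select_by_ebic([])

    def test_neighborhood_size_non_increasing_in_gamma(self):
        model = sn.make_planted_model(6, 2, 1.2, 0.0, (-2.0, -1.0), 23)
        X = sn.gibbs_sample(model, 500, seed=6)
        fits = sn.fit_node_lasso_path(X, 0)
        sizes = [len(sn.select_by_ebic(fits, gamma=g).neighbor_set)
                 for g in (0.0, 0.25, 0.5, 1.0, 2.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestEstimateNetwork:
    def test_symmetric_zero_diagonal(self, balanced_network):
        W = balanced_network.weights
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0)

    def test_and_rule_subset_of_or(self, balanced_data, fast_config):
        or_net = sn.estimate_network(balanced_data, fast_config)
        and_net = sn.estimate_network(
            balanced_data, EstimationConfig(rule="AND", grid_size=30))
        or_edges = {(a, b) for a, b, _ in or_net.edges()}
        and_edges = {(a, b) for a, b, _ in and_net.edges()}
        assert and_edges <= or_edges

    def test_planted_edges_mostly_within_blocks_and_positive(
            self, balanced_model, balanced_network):
        comm = balanced_model.true_communities
        edges = balanced_network.edges()
        within = [(a, b, w) for a, b, w in edges if comm[a] == comm[b]]
        assert len(within) >= 0.95 * len(edges)
        assert all(w > 0 for _, _, w in within)
        # every true within-block pair recovered at this sample size
        assert len(within) == 20

    def test_constant_column_isolated(self, fast_config):
        rng = np.random.default_rng(0)
        vals = (rng.random((200, 4)) < 0.5).astype(float)
        vals[:, 2] = 1.0
        X = _matrix(vals)
        net = sn.estimate_network(X, fast_config)
        assert np.all(net.weights[2] == 0)
        assert np.isfinite(net.thresholds).all()

    def test_small_n_warns(self, fast_config):
        model = sn.make_planted_model(6, 2, 1.0, 0.0, (-2, -1), 1)
        X = sn.gibbs_sample(model, 5, seed=1)
        if X.values.min(axis=0).max() == 1 or X.values.max(axis=0).min() == 0:
            pytest.skip("draw produced constant columns")
        with pytest.warns(UserWarning, match="unstable"):
            sn.estimate_network(X, fast_config)

    def test_deterministic(self, balanced_data, fast_config):
        a = sn.estimate_network(balanced_data, fast_config)
        b = sn.estimate_network(balanced_data, fast_config)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.thresholds, b.thresholds)


class TestDensityAndCounts:
    def test_density_examples(self):
        p = 4
        W = np.zeros((p, p))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = -0.2
        net = sn.IsingNetwork([f"n{i}" for i in range(p)], W, np.zeros(p))
        assert sn.network_density(net) == 33.33
        empty = sn.IsingNetwork(["a", "b"], np.zeros((2, 2)), np.zeros(2))
        assert sn.network_density(empty) == 0.0
        full = sn.IsingNetwork([f"n{i}" for i in range(5)],
                               np.ones((5, 5)) - np.eye(5), np.zeros(5))
        assert sn.network_density(full) == 100.0

    def test_parameter_count(self):
        assert sn.parameter_count(38) == (38, 703)
        assert sn.parameter_count(2) == (2, 1)
        assert sn.parameter_count(20) == (20, 190)


def test_edgelist_round_trip(tmp_path, balanced_network):
    path = tmp_path / "edges.tsv"
    write_edgelist(balanced_network, path)
    back = read_edgelist(path, node_labels=balanced_network.node_labels)
    assert np.allclose(back.weights, balanced_network.weights)


def test_graphml_export(tmp_path, balanced_network):
    import networkx as nx
    path = tmp_path / "net.graphml"
    write_graphml(balanced_network, path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == balanced_network.p
    assert g.number_of_edges() == len(balanced_network.edges())
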