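"""Shared fixtures: planted models, sampled data, brute-force graph oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.estimation import EstimationConfig, IsingNetwork


@pytest.fixture(scope="session")
def balanced_model() -> sn.PlantedIsingModel:
    """Two-block model with thresholds balancing the couplings (~50% occurrence)."""
    return sn.make_planted_model(10, 2, 1.5, 0.0, (-3.0, -3.0), seed=42)


@pytest.fixture(scope="session")
def balanced_data(balanced_model) -> sn.OccurrenceMatrix:
    return sn.gibbs_sample(balanced_model, 1500, seed=7)


@pytest.fixture(scope="session")
def balanced_network(balanced_data) -> IsingNetwork:
    return sn.estimate_network(balanced_data)


@pytest.fixture()
def fast_config() -> EstimationConfig:
    """Smaller penalty grid for unit tests that only need a valid estimate."""
    return EstimationConfig(grid_size=30)


def random_network(seed: int, p_min: int = 4, p_max: int = 8,
                   density: float = 0.5, signed: bool = False) -> IsingNetwork:
    """A random symmetric weighted network for oracle comparisons."""
    rng = np.random.default_rng(seed)
    p = int(rng.integers(p_min, p_max + 1))
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                w = rng.uniform(0.2, 1.5)
                if signed and rng.random() < 0.2:
                    w = -w
                W[i, j] = W[j, i] = w
    return IsingNetwork([f"n{i}" for i in range(p)], W, np.zeros(p))


def brute_force_centralities(net: IsingNetwork) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs simple-path enumeration oracle for closeness and betweenness.

    Edge length 1/|w|; closeness = 1/sum of shortest distances (NaN if any
    node unreachable); betweenness = per-pair fractional count of shortest
    paths through each interior node.
    """
    p = net.p
    W = np.abs(net.weights)
    dist = np.full((p, p), np.inf)

    def all_paths(s, u):
        # (length, interior nodes) of every simple s-u path
        out = []
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, length = stack.pop()
            if node == u:
                out.append((length, path[1:-1]))
                continue
            for nxt in range(p):
                if W[node, nxt] > 0 and nxt not in path:
                    stack.append((nxt, path + [nxt], length + 1.0 / W[node, nxt]))
        return out

    bet = np.zeros(p)
    for s, u in itertools.combinations(range(p), 2):
        paths = all_paths(s, u)
        if not paths:
            continue
        best = min(l for l, _ in paths)
        dist[s, u] = dist[u, s] = best
        shortest = [mid for l, mid in paths if l <= best * (1 + 1e-12)]
        for mid in shortest:
            for v in mid:
                bet[v] += 1.0 / len(shortest)
    clo = np.full(p, np.nan)
    for j in range(p):
        row = np.delete(dist[j], j)
        if np.all(np.isfinite(row)) and p > 1:
            clo[j] = 1.0 / row.sum()
    return clo, bet
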