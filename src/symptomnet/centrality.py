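"""Node centrality indices for weighted symptom networks.

Strength is the total absolute weight incident to a node.  Closeness and
betweenness operate on shortest paths with edge length 1/|w| (a stronger
association is a shorter distance): closeness is the inverse of the summed
distances to all other nodes, undefined (NaN) whenever some node is
unreachable; betweenness counts, for each unordered pair, the fraction of
shortest paths brokered by the node (endpoints excluded, ties split
fractionally).
"""

from __future__ import annotations

from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .estimation import EstimationConfig, IsingNetwork, estimate_network
from .io import OccurrenceMatrix

__all__ = [
    "strength",
    "closeness",
    "betweenness",
    "centrality_table",
    "remove_node_and_reanalyze",
]

CENTRALITY_INDICES = ("strength", "closeness", "betweenness")


def _distance_graph(net: IsingNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.p))
    W = np.abs(net.weights)
    for i in range(net.p):
        for j in range(i + 1, net.p):
            if W[i, j] > 0:
                g.add_edge(i, j, distance=1.0 / W[i, j])
    return g


def strength(net: IsingNetwork) -> pd.Series:
    """Sum of absolute incident edge weights per node."""
    vals = np.abs(net.weights).sum(axis=1)
    return pd.Series(vals, index=net.node_labels, name="strength")


def closeness(net: IsingNetwork) -> pd.Series:
    """Inverse of the summed shortest-path distances; NaN if not all reachable."""
    g = _distance_graph(net)
    out = np.full(net.p, np.nan)
    if net.p == 1:
        return pd.Series(out, index=net.node_labels, name="closeness")
    for j in range(net.p):
        dist = nx.single_source_dijkstra_path_length(g, j, weight="distance")
        if len(dist) == net.p:
            total = sum(dist.values())
            out[j] = 1.0 / total if total > 0 else np.nan
    return pd.Series(out, index=net.node_labels, name="closeness")


def betweenness(net: IsingNetwork) -> pd.Series:
    """Unnormalized shortest-path betweenness (fractional tie counting)."""
    g = _distance_graph(net)
    bc = nx.betweenness_centrality(g, weight="distance", normalized=False)
    vals = np.array([bc[j] for j in range(net.p)])
    return pd.Series(vals, index=net.node_labels, name="betweenness")


def centrality_table(net: IsingNetwork) -> pd.DataFrame:
    """All three indices per node, ordered by descending strength."""
    df = pd.DataFrame({
        "strength": strength(net),
        "closeness": closeness(net),
        "betweenness": betweenness(net),
    })
    df.index.name = "code"
    return df.sort_values("strength", ascending=False, kind="stable")


def remove_node_and_reanalyze(X: OccurrenceMatrix, node: str,
                              config: EstimationConfig = EstimationConfig(),
                              mode: Literal["reestimate", "delete"] = "reestimate",
                              network: IsingNetwork | None = None,
                              ) -> tuple[IsingNetwork, pd.DataFrame]:
    """Drop one symptom and recompute the network and its centralities.

    'reestimate' (default) refits the p-1 node network from the data;
    'delete' removes the node from an already fitted `network` instead.
    """
    if node not in X.symptom_codes:
        raise ValueError(f"unknown symptom code {node!r}")
    if mode == "reestimate":
        keep = [c for c in X.symptom_codes if c != node]
        net = estimate_network(X.subset_symptoms(keep), config)
    else:
        if network is None:
            network = estimate_network(X, config)
        idx = [i for i, c in enumerate(network.node_labels) if c != node]
        net = IsingNetwork([network.node_labels[i] for i in idx],
                           network.weights[np.ix_(idx, idx)],
                           network.thresholds[idx],
                           dict(network.estimation_meta, removed=node))
    return net, centrality_table(net)
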