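"""Random-walk (Walktrap) community detection on weighted symptom networks.

Short random walks tend to stay inside densely connected groups; nodes whose
t-step walk distributions look alike are structurally similar.  Starting from
singleton communities, the algorithm repeatedly merges the adjacent pair with
the lowest Ward-style merge cost on degree-weighted walk-profile distances,
records modularity after every merge, and returns the cut with maximum
modularity.

Edge weights enter the walks and the modularity as absolute values by
default — estimated symptom networks occasionally carry a negative edge, and
transition probabilities must stay nonnegative.  A config switch zeroes
negative edges instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .estimation import IsingNetwork

__all__ = [
    "CommunityPartition",
    "walk_transition_matrix",
    "walktrap",
    "modularity",
    "write_partition_csv",
]


@dataclass
class CommunityPartition:
    """Result of the agglomeration: final labels plus the full dendrogram.

    labels : node label -> community id at the chosen cut (0..K-1, ids in
        order of first member appearance).
    merge_sequence : (community_a, community_b, new_id, merge_cost) per merge;
        initial singleton communities are numbered 0..p-1 in node order.
    modularity_per_cut : entry i is the modularity of the partition after i
        merges (entry 0 = all singletons).
    chosen_cut : index into modularity_per_cut attaining the maximum.
    """

    labels: dict[str, int]
    merge_sequence: list[tuple[int, int, int, float]]
    modularity_per_cut: list[float]
    chosen_cut: int

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.labels.items():
            out.setdefault(c, []).append(node)
        return out


def _effective_weights(net: IsingNetwork,
                       negative: Literal["absolute", "zero"] = "absolute") -> np.ndarray:
    W = net.weights
    if negative == "absolute":
        return np.abs(W)
    return np.where(W > 0, W, 0.0)


def walk_transition_matrix(net: IsingNetwork,
                           negative: Literal["absolute", "zero"] = "absolute"
                           ) -> np.ndarray:
    """Row-stochastic one-step walk matrix; isolated nodes self-loop."""
    A = _effective_weights(net, negative)
    deg = A.sum(axis=1)
    P = np.zeros_like(A)
    nz = deg > 0
    P[nz] = A[nz] / deg[nz, None]
    for j in np.flatnonzero(~nz):
        P[j, j] = 1.0
    return P


def modularity(net: IsingNetwork, labels: Mapping[str, int],
               negative: Literal["absolute", "zero"] = "absolute") -> float:
    """Newman modularity Q = sum_c (e_c/m - (d_c/2m)^2) on effective weights."""
    if set(labels) != set(net.node_labels):
        raise ValueError("labels must cover every node exactly once")
    A = _effective_weights(net, negative)
    m = A[np.triu_indices(net.p, k=1)].sum()
    if m == 0:
        warnings.warn("empty network: modularity defined as 0", stacklevel=2)
        return 0.0
    lab = np.array([labels[x] for x in net.node_labels])
    deg = A.sum(axis=1)
    q = 0.0
    for c in np.unique(lab):
        idx = lab == c
        e_c = A[np.ix_(idx, idx)][np.triu_indices(int(idx.sum()), k=1)].sum()
        d_c = deg[idx].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def walktrap(net: IsingNetwork, t: int = 4,
             negative: Literal["absolute", "zero"] = "absolute") -> CommunityPartition:
    """Agglomerative community detection via t-step random-walk profiles.

    Community profiles are the member-averaged rows of P^t; the distance
    between communities is the degree-weighted Euclidean distance between
    profiles, and the merge cost is the Ward increment
    |A||B| / (|A|+|B|) * r(A,B)^2 / p.  Only adjacent communities merge, so
    disconnected components agglomerate independently and isolated nodes stay
    singletons.  Ties break on the smallest (id_a, id_b) pair.
    """
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    p = net.p
    A = _effective_weights(net, negative)
    # lazy walk (half self-loop), as in the canonical implementation: keeps
    # the chain aperiodic so short-walk profiles are well behaved
    P = 0.5 * (np.eye(p) + walk_transition_matrix(net, negative))
    Pt = np.linalg.matrix_power(P, t)
    deg = A.sum(axis=1)
    inv_d = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)

    # community state
    size = {c: 1 for c in range(p)}
    profile = {c: Pt[c].copy() for c in range(p)}
    members: dict[int, list[int]] = {c: [c] for c in range(p)}
    adj: dict[int, set[int]] = {c: set() for c in range(p)}
    for i in range(p):
        for j in range(i + 1, p):
            if A[i, j] > 0:
                adj[i].add(j)
                adj[j].add(i)

    def merge_cost(a: int, b: int) -> float:
        diff = profile[a] - profile[b]
        r2 = float(np.sum(diff * diff * inv_d))
        return (size[a] * size[b]) / (size[a] + size[b]) * r2 / p

    labels_now = np.arange(p)
    merge_sequence: list[tuple[int, int, int, float]] = []
    mods = [modularity(net, dict(zip(net.node_labels, labels_now)), negative)]
    next_id = p
    active = set(range(p))
    while True:
        best = None
        for a in sorted(active):
            for b in sorted(adj[a]):
                if b <= a:
                    continue
                cost = merge_cost(a, b)
                if best is None or cost < best[0] - 1e-15 or (
                        abs(cost - best[0]) <= 1e-15 and (a, b) < (best[1], best[2])):
                    best = (cost, a, b)
        if best is None:
            break
        cost, a, b = best
        new = next_id
        next_id += 1
        profile[new] = (size[a] * profile[a] + size[b] * profile[b]) / (size[a] + size[b])
        size[new] = size[a] + size[b]
        members[new] = members[a] + members[b]
        adj[new] = (adj[a] | adj[b]) - {a, b}
        for c in adj[new]:
            adj[c].discard(a)
            adj[c].discard(b)
            adj[c].add(new)
        for c in (a, b):
            active.discard(c)
            del profile[c], size[c], adj[c]
        active.add(new)
        merge_sequence.append((a, b, new, float(cost)))
        lab = np.empty(p, dtype=int)
        for c in active:
            for node in members[c]:
                lab[node] = c
        mods.append(modularity(net, dict(zip(net.node_labels, lab)), negative))

    chosen = int(np.argmax(mods))
    # replay merges up to the chosen cut
    groups: dict[int, list[int]] = {c: [c] for c in range(p)}
    for a, b, new, _ in merge_sequence[:chosen]:
        groups[new] = groups.pop(a) + groups.pop(b)
    # canonical ids by first node appearance
    final = np.empty(p, dtype=int)
    order = sorted(groups.values(), key=min)
    for cid, nodes in enumerate(order):
        for node in nodes:
            final[node] = cid
    return CommunityPartition(
        labels={lab: int(final[i]) for i, lab in enumerate(net.node_labels)},
        merge_sequence=merge_sequence,
        modularity_per_cut=[float(q) for q in mods],
        chosen_cut=chosen,
    )


def write_partition_csv(part: CommunityPartition, path: str | Path,
                        names: Mapping[int, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("node,community_id,community_name\n")
        for node, c in part.labels.items():
            fh.write(f"{node},{c},{(names or {}).get(c, '')}\n")
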