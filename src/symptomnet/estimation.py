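"""Sparse Ising network estimation from binary symptom data (eLasso).

Each symptom is regressed on all others with an l1-penalized logistic
regression along a descending penalty path; the neighbourhood minimizing the
extended BIC,

    EBIC = -2 l + |J| log n + 2 gamma |J| log(p - 1),

is selected per node, and the two directed estimates for each pair are
symmetrized under the OR rule (edge present if either direction selects it;
weight = mean of the two directed coefficients, the unselected one entering
as zero) or the AND rule (both must select it).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import yaml

from ._solver import logistic_lasso_path, rho_max_for
from .io import OccurrenceMatrix, round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "EstimationConfig",
    "NodewiseFit",
    "IsingNetwork",
    "DegenerateNodeError",
    "pseudo_loglik",
    "ebic",
    "fit_node_lasso_path",
    "select_by_ebic",
    "estimate_network",
    "network_density",
    "parameter_count",
    "to_networkx",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
]


class DegenerateNodeError(ValueError):
    """The response column is constant: no nodewise regression exists."""


@dataclass(frozen=True)
class EstimationConfig:
    """Settings of the nodewise estimator.

    gamma : EBIC hyperparameter (0 reduces to BIC); 0.25 is the standard
        choice for symptom networks.
    rule : 'OR' keeps an edge if either directed regression selects it,
        'AND' requires both.
    or_weight : with a one-sided selection under OR, 'mean_with_zero'
        averages the nonzero estimate with zero; 'single' keeps it as is.
    grid_size, floor_ratio : geometric penalty grid from rho_max down to
        floor_ratio * rho_max.
    """

    gamma: float = 0.25
    rule: Literal["OR", "AND"] = "OR"
    grid_size: int = 100
    floor_ratio: float = 0.01
    tol: float = 1e-8
    max_iter: int = 10_000
    or_weight: Literal["mean_with_zero", "single"] = "mean_with_zero"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.rule not in ("OR", "AND"):
            raise ValueError("rule must be 'OR' or 'AND'")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if not 0 < self.floor_ratio < 1:
            raise ValueError("floor_ratio must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EstimationConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


@dataclass
class NodewiseFit:
    """One penalized logistic fit of node j on all other nodes."""

    node_index: int
    intercept: float
    coefficients: np.ndarray  # over the other p-1 nodes, original order
    neighbor_set: tuple[int, ...]  # indices into the full node list
    rho: float
    loglik: float
    ebic_value: float
    n: int = 0  # rows used in the fit; needed to re-score under another gamma


@dataclass
class IsingNetwork:
    """Estimated (or constructed) symmetric weighted network over symptoms."""

    node_labels: list[str]
    weights: np.ndarray
    thresholds: np.ndarray
    estimation_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        p = len(self.node_labels)
        if self.weights.shape != (p, p):
            raise ValueError(f"weights must be {p}x{p}")
        if self.thresholds.shape != (p,):
            raise ValueError(f"thresholds must have length {p}")
        if not np.all(np.isfinite(self.weights)) or not np.all(np.isfinite(self.thresholds)):
            raise ValueError("weights and thresholds must be finite")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weights must have zero diagonal")

    @property
    def p(self) -> int:
        return len(self.node_labels)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0:
                    out.append((self.node_labels[i], self.node_labels[j],
                                float(self.weights[i, j])))
        return out


def pseudo_loglik(tau_j: float, beta_row: np.ndarray, X: OccurrenceMatrix | np.ndarray,
                  j: int) -> float:
    """Conditional Bernoulli log-likelihood of column j given the others.

    sum_i [ tau_j x_ij + sum_{k != j} beta_jk x_ij x_ik
            - log(1 + exp(tau_j + sum_k x_ik beta_jk)) ]
    """
    V = X.values if isinstance(X, OccurrenceMatrix) else np.asarray(X, dtype=float)
    y = V[:, j]
    others = np.delete(V, j, axis=1)
    beta_row = np.asarray(beta_row, dtype=float)
    if beta_row.shape != (others.shape[1],):
        raise ValueError(f"beta_row must have length {others.shape[1]}")
    eta = tau_j + others @ beta_row
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def ebic(loglik: float, neighborhood_size: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC of a nodewise fit with |J| selected neighbours."""
    if n < 1 or p < 2:
        raise ValueError("need n >= 1 and p >= 2")
    if not 0 <= neighborhood_size <= p - 1:
        raise ValueError("neighborhood_size must lie in 0..p-1")
    return (-2.0 * loglik + neighborhood_size * np.log(n)
            + 2.0 * gamma * neighborhood_size * np.log(p - 1))


def fit_node_lasso_path(X: OccurrenceMatrix, j: int,
                        config: EstimationConfig = EstimationConfig(),
                        _collapsed: tuple[np.ndarray, np.ndarray] | None = None
                        ) -> list[NodewiseFit]:
    """Penalized fits of node j over the whole descending rho grid.

    The binary rows are collapsed to unique patterns with multiplicities
    before fitting — an exact reformulation that keeps every iteration
    O(#patterns) instead of O(n).
    """
    V = X.values
    if np.isnan(V).any():
        raise ValueError("estimation requires complete data")
    n, p = V.shape
    if V[:, j].min() == V[:, j].max():
        raise DegenerateNodeError(f"column {X.symptom_codes[j]!r} is constant")
    if _collapsed is None:
        U, counts = np.unique(V, axis=0, return_counts=True)
    else:
        U, counts = _collapsed
    y = U[:, j]
    others = np.ascontiguousarray(np.delete(U, j, axis=1))
    c = counts.astype(float)
    rmax = rho_max_for(others, y, c)
    if rmax <= 0:
        rmax = 1e-8
    rhos = np.geomspace(rmax, config.floor_ratio * rmax, config.grid_size)
    taus, betas, _ = logistic_lasso_path(others, y, rhos, config.tol,
                                         config.max_iter, counts=c)
    other_idx = [k for k in range(p) if k != j]
    fits = []
    for r in range(len(rhos)):
        coef = betas[r]
        nz = np.flatnonzero(coef != 0.0)
        eta = taus[r] + others @ coef
        loglik = float(np.sum(c * (y * eta - np.logaddexp(0.0, eta))))
        fits.append(NodewiseFit(
            node_index=j, intercept=float(taus[r]), coefficients=coef.copy(),
            neighbor_set=tuple(other_idx[k] for k in nz), rho=float(rhos[r]),
            loglik=loglik, ebic_value=ebic(loglik, len(nz), n, p, config.gamma),
            n=n))
    return fits


def select_by_ebic(fits: Sequence[NodewiseFit], gamma: float | None = None) -> NodewiseFit:
    """Fit with lowest EBIC; ties go to the smaller neighbourhood, then larger rho.

    Pass `gamma` to re-score an existing path under a different hyperparameter
    (the stored loglik, |J| and n are reused).
    """
    if not fits:
        raise ValueError("empty fit sequence")
    if gamma is None:
        scored = [(f.ebic_value, len(f.neighbor_set), -f.rho, i)
                  for i, f in enumerate(fits)]
    else:
        scored = [(ebic(f.loglik, len(f.neighbor_set), f.n,
                        len(f.coefficients) + 1, gamma),
                   len(f.neighbor_set), -f.rho, i)
                  for i, f in enumerate(fits)]
    best = min(scored)
    return fits[best[3]]


def estimate_network(X: OccurrenceMatrix,
                     config: EstimationConfig = EstimationConfig()) -> IsingNetwork:
    """Full eLasso estimate: nodewise paths, EBIC selection, symmetrization.

    Constant columns become isolated nodes (warned); their threshold is the
    Haldane-corrected empirical logit so it stays finite.
    """
    V = X.values
    if np.isnan(V).any():
        raise ValueError("estimation requires complete data (run complete_case_filter)")
    n, p = V.shape
    if p < 2:
        raise ValueError("need at least 2 symptoms to estimate a network")
    col_min = V.min(axis=0)
    col_max = V.max(axis=0)
    constant = col_min == col_max
    if (~constant).sum() < 2:
        raise ValueError("fewer than 2 non-constant symptom columns")
    if n < p:
        warnings.warn(f"n={n} < p={p}: estimates may be unstable", stacklevel=2)

    collapsed = np.unique(V, axis=0, return_counts=True)
    directed = np.zeros((p, p))
    thresholds = np.zeros(p)
    for j in range(p):
        if constant[j]:
            c = V[:, j].sum()
            thresholds[j] = np.log((c + 0.5) / (n - c + 0.5))
            logger.warning("symptom %r is constant; kept as isolated node",
                           X.symptom_codes[j])
            continue
        fits = fit_node_lasso_path(X, j, config, _collapsed=collapsed)
        best = select_by_ebic(fits)
        thresholds[j] = best.intercept
        other_idx = [k for k in range(p) if k != j]
        for pos, k in enumerate(other_idx):
            directed[j, k] = best.coefficients[pos]

    weights = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = directed[i, j], directed[j, i]
            if config.rule == "AND":
                w = 0.5 * (a + b) if (a != 0 and b != 0) else 0.0
            else:  # OR
                if a != 0 and b != 0:
                    w = 0.5 * (a + b)
                elif a != 0 or b != 0:
                    one_sided = a if a != 0 else b
                    w = 0.5 * one_sided if config.or_weight == "mean_with_zero" else one_sided
                else:
                    w = 0.0
            weights[i, j] = weights[j, i] = w

    meta = {"gamma": config.gamma, "rule": config.rule, "n": n,
            "or_weight": config.or_weight, "grid_size": config.grid_size,
            "floor_ratio": config.floor_ratio}
    return IsingNetwork(list(X.symptom_codes), weights, thresholds, meta)


def network_density(net: IsingNetwork) -> float:
    """Percentage of potential edges realized, to two decimals (half-up)."""
    p = net.p
    if p < 2:
        raise ValueError("density undefined for p < 2")
    n_edges = int(np.count_nonzero(np.triu(net.weights, k=1)))
    return round_half_up(100.0 * n_edges / (p * (p - 1) / 2), 2)


def parameter_count(p: int) -> tuple[int, int]:
    """(threshold parameters, pairwise association parameters) for p nodes."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return p, p * (p - 1) // 2


def to_networkx(net: IsingNetwork, absolute: bool = False) -> nx.Graph:
    """networkx Graph with 'weight' edge attributes (optionally |w|)."""
    g = nx.Graph()
    g.add_nodes_from(net.node_labels)
    for a, b, w in net.edges():
        g.add_edge(a, b, weight=abs(w) if absolute else w)
    return g


def write_edgelist(net: IsingNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_edgelist(path: str | Path, node_labels: Sequence[str] | None = None) -> IsingNetwork:
    rows = [ln.split("\t") for ln in Path(path).read_text().splitlines()[1:] if ln]
    seen: list[str] = []
    for a, b, _ in rows:
        for x in (a, b):
            if x not in seen:
                seen.append(x)
    labels = list(node_labels) if node_labels is not None else seen
    pos = {lab: i for i, lab in enumerate(labels)}
    W = np.zeros((len(labels), len(labels)))
    for a, b, w in rows:
        W[pos[a], pos[b]] = W[pos[b], pos[a]] = float(w)
    return IsingNetwork(labels, W, np.zeros(len(labels)), {"source": str(path)})


def write_graphml(net: IsingNetwork, path: str | Path) -> None:
    g = to_networkx(net)
    for lab, t in zip(net.node_labels, net.thresholds):
        g.nodes[lab]["threshold"] = float(t)
    for k, v in net.estimation_meta.items():
        g.graph[k] = v
    nx.write_graphml(g, path)
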