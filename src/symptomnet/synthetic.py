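"""Synthetic binary symptom data from fully specified Ising models.

Every downstream stage of the pipeline (estimation, community detection,
centrality, stability) is exercised on data drawn from planted models so the
ground-truth graph and community structure are known by construction.

Variables are coded {0,1}: the single-site conditional of the Ising model is
then exactly the logistic regression the nodewise estimator fits,

    P(x_j = 1 | x_rest) = logistic(tau_j + sum_k beta_jk x_k),

with tau_j the autonomous tendency of symptom j to occur and beta_jk the
pairwise coupling.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from numba import njit
from scipy.special import logsumexp

from .io import OccurrenceMatrix, SchemaError

__all__ = [
    "PlantedIsingModel",
    "LongitudinalDesign",
    "make_planted_model",
    "exact_joint_distribution",
    "gibbs_sample",
    "generate_longitudinal",
    "save_model",
    "load_model",
    "write_true_edgelist",
]


@dataclass
class PlantedIsingModel:
    """A ground-truth Ising model with planted community structure.

    tau : length-p node thresholds (log-odds scale).
    beta : p x p symmetric coupling matrix with zero diagonal.
    true_communities : node label -> community id.
    """

    node_labels: list[str]
    tau: np.ndarray
    beta: np.ndarray
    true_communities: dict[str, int]

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        p = len(self.node_labels)
        if self.tau.shape != (p,):
            raise ValueError(f"tau must have length {p}")
        if self.beta.shape != (p, p):
            raise ValueError(f"beta must be {p}x{p}")
        if not np.all(np.isfinite(self.tau)) or not np.all(np.isfinite(self.beta)):
            raise ValueError("tau and beta must be finite")
        if not np.allclose(self.beta, self.beta.T):
            raise ValueError("beta must be symmetric")
        if np.any(np.diag(self.beta) != 0):
            raise ValueError("beta must have zero diagonal")
        if set(self.true_communities) != set(self.node_labels):
            raise ValueError("true_communities must assign every node exactly one id")

    @property
    def p(self) -> int:
        return len(self.node_labels)


@dataclass
class LongitudinalDesign:
    """Repeated-assessment design: one Ising model per time point.

    carryover in [0,1] controls patient-level autocorrelation: a patient's
    state at t+1 starts from their state at t and is refreshed with fewer
    Gibbs sweeps the larger the carryover. missingness_rate is the chance a
    patient skips a whole assessment (an all-missing row, never zeros).
    """

    time_point_labels: list[str]
    models: list[PlantedIsingModel]
    carryover: float = 0.0
    missingness_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.time_point_labels) != len(self.models):
            raise ValueError("one model per time point required")
        labels0 = self.models[0].node_labels
        for m in self.models:
            if m.node_labels != labels0:
                raise SchemaError("all per-time-point models must share node labels")
        if not 0.0 <= self.carryover <= 1.0:
            raise ValueError("carryover must lie in [0, 1]")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ValueError("missingness_rate must lie in [0, 1]")


def make_planted_model(p: int, n_communities: int, within_coupling: float,
                       between_coupling: float, tau_range: tuple[float, float],
                       seed: int, node_labels: Sequence[str] | None = None) -> PlantedIsingModel:
    """Block-structured Ising model: near-equal blocks, constant couplings.

    Every within-block pair gets `within_coupling`, every between-block pair
    `between_coupling`; thresholds are drawn uniformly from `tau_range`.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 1 <= n_communities <= p:
        raise ValueError("n_communities must lie in 1..p")
    lo, hi = float(tau_range[0]), float(tau_range[1])
    if not (np.isfinite(lo) and np.isfinite(hi) and np.isfinite(within_coupling)
            and np.isfinite(between_coupling)):
        raise ValueError("couplings and tau_range must be finite")
    if node_labels is None:
        node_labels = [f"s{i + 1:02d}" for i in range(p)]
    blocks = np.array_split(np.arange(p), n_communities)
    comm = np.empty(p, dtype=int)
    for b, idx in enumerate(blocks):
        comm[idx] = b
    beta = np.where(comm[:, None] == comm[None, :], within_coupling, between_coupling)
    np.fill_diagonal(beta, 0.0)
    rng = np.random.default_rng(seed)
    tau = rng.uniform(lo, hi, size=p)
    return PlantedIsingModel(list(node_labels), tau, beta,
                             {lab: int(c) for lab, c in zip(node_labels, comm)})


def exact_joint_distribution(model: PlantedIsingModel) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate all 2^p states and their exact probabilities.

    P(x) ∝ exp(sum_j tau_j x_j + sum_{j<k} beta_jk x_j x_k). Serves as the
    brute-force oracle for the Gibbs sampler. Refuses p > 20.
    """
    p = model.p
    if p > 20:
        raise ValueError(f"exact enumeration refused for p={p} > 20 (2^p states)")
    states = np.array(list(itertools.product((0, 1), repeat=p)), dtype=float)
    energy = states @ model.tau + 0.5 * np.einsum("ij,jk,ik->i", states, model.beta, states)
    logz = logsumexp(energy)
    return states.astype(np.int8), np.exp(energy - logz)


@njit(cache=True)
def _gibbs_kernel(tau, beta, state, u, out, burn_in, thin):  # pragma: no cover - numba
    """Systematic-sweep single-site Gibbs updates; u holds pre-drawn uniforms."""
    p = tau.shape[0]
    n_out = out.shape[0]
    sweep = 0
    total = burn_in + n_out * thin if thin > 0 else burn_in + n_out
    step = thin if thin > 0 else 1
    k = 0
    for sweep in range(total):
        for j in range(p):
            eta = tau[j]
            for m in range(p):
                eta += beta[j, m] * state[m]
            pj = 1.0 / (1.0 + np.exp(-eta))
            state[j] = 1.0 if u[sweep, j] < pj else 0.0
        if sweep >= burn_in and (sweep - burn_in) % step == step - 1:
            if k < n_out:
                for j in range(p):
                    out[k, j] = state[j]
                k += 1
    return out


def _run_gibbs(model: PlantedIsingModel, n: int, burn_in: int, thin: int,
               rng: np.random.Generator, init: np.ndarray | None = None) -> np.ndarray:
    p = model.p
    step = thin if thin > 0 else 1
    total = burn_in + n * step
    u = rng.random((total, p))
    state = (rng.random(p) < 0.5).astype(float) if init is None else init.astype(float).copy()
    out = np.empty((n, p))
    _gibbs_kernel(model.tau, model.beta, state, u, out, burn_in, step)
    return out


def gibbs_sample(model: PlantedIsingModel, n: int, burn_in: int = 1000,
                 thin: int = 10, seed: int = 0,
                 time_point: str | None = None) -> OccurrenceMatrix:
    """Draw `n` states by single-site Gibbs sampling (one chain, systematic sweeps).

    Records every `thin`-th sweep after `burn_in` warm-up sweeps. The same
    seed yields byte-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if burn_in < 0 or thin < 0:
        raise ValueError("burn_in and thin must be >= 0")
    rng = np.random.default_rng(seed)
    vals = _run_gibbs(model, n, burn_in, thin, rng)
    ids = [f"p{i + 1:05d}" for i in range(n)]
    return OccurrenceMatrix(vals, ids, list(model.node_labels), time_point)


#: full refresh sweeps applied between assessments at carryover 0; the count
#: shrinks linearly to 0 as carryover -> 1.  The chain is stationary, so the
#: per-time-point marginal law is exact for any sweep count — carryover only
#: tunes cross-time dependence.
CARRYOVER_FULL_SWEEPS = 10


def generate_longitudinal(design: LongitudinalDesign, n: int, seed: int = 0,
                          burn_in: int = 1000, thin: int = 10
                          ) -> tuple[list[OccurrenceMatrix], list[str]]:
    """Correlated assessments for the same patients at each time point.

    T1 is a stationary Gibbs draw (independent patients). Each later time
    point starts every patient from their previous state and applies
    ``round((1 - carryover) * CARRYOVER_FULL_SWEEPS)`` refresh sweeps under
    that time point's model. Whole assessments are dropped (all-NaN rows)
    independently with probability `missingness_rate`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"p{i + 1:05d}" for i in range(n)]
    p = design.models[0].p
    refresh = int(round((1.0 - design.carryover) * CARRYOVER_FULL_SWEEPS))
    mats: list[OccurrenceMatrix] = []
    prev = None
    for t, (label, model) in enumerate(zip(design.time_point_labels, design.models)):
        if t == 0:
            # independent stationary draws per patient via one long chain
            vals = _run_gibbs(model, n, burn_in, thin, rng)
        else:
            vals = np.empty((n, p))
            total = max(refresh, 0)
            if total == 0:
                vals[:] = prev
            else:
                u = rng.random((n, total, p))
                for i in range(n):
                    state = prev[i].copy()
                    out1 = np.empty((1, p))
                    _gibbs_kernel(model.tau, model.beta, state, u[i], out1,
                                  total - 1, 1)
                    vals[i] = out1[0]
        prev = vals.copy()
        miss = rng.random(n) < design.missingness_rate
        shown = vals.copy()
        shown[miss] = np.nan
        mats.append(OccurrenceMatrix(shown, ids, list(model.node_labels), label))
    return mats, ids


def save_model(model: PlantedIsingModel, path: str | Path) -> None:
    """Write a model spec as YAML (beta stored as dense lower triangle)."""
    p = model.p
    tril = [[float(model.beta[i, j]) for j in range(i)] for i in range(p)]
    doc = {
        "node_labels": list(model.node_labels),
        "tau": [float(t) for t in model.tau],
        "beta_lower_triangle": tril,
        "communities": {k: int(v) for k, v in model.true_communities.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path) -> PlantedIsingModel:
    text = Path(path).read_text()
    doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    labels = doc["node_labels"]
    p = len(labels)
    beta = np.zeros((p, p))
    for i, row in enumerate(doc["beta_lower_triangle"]):
        for j, w in enumerate(row):
            beta[i, j] = beta[j, i] = w
    return PlantedIsingModel(labels, np.asarray(doc["tau"], dtype=float), beta,
                             dict(doc["communities"]))


def write_true_edgelist(model: PlantedIsingModel, path: str | Path) -> None:
    """Ground-truth graph as a tab-separated (node_a, node_b, weight) list."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for i in range(model.p):
            for j in range(i + 1, model.p):
                w = model.beta[i, j]
                if w != 0:
                    fh.write(f"{model.node_labels[i]}\t{model.node_labels[j]}\t{w:.10g}\n")
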