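"""Bootstrap accuracy and stability of estimated symptom networks.

Accuracy: nonparametric bootstrap (patients resampled with replacement)
percentile 95% confidence intervals for every edge weight.

Stability: case-dropping and node-dropping subsetting bootstraps.  For a
grid of drop proportions q, networks are re-estimated on random subsets and
the Pearson correlation between the subset and full-sample centralities is
recorded per index.  The correlation-stability (CS) coefficient is the
largest q such that, at q and at every smaller tested q, at least 95% of
replicates keep a correlation of at least 0.7.  Values above 0.25 indicate
moderate and above 0.5 strong stability.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .centrality import CENTRALITY_INDICES, centrality_table
from .estimation import EstimationConfig, IsingNetwork, estimate_network
from .io import OccurrenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityReport",
    "DEFAULT_DROP_LEVELS",
    "bootstrap_edge_ci",
    "case_dropping_bootstrap",
    "node_dropping_bootstrap",
    "cs_coefficient",
    "stability_report",
]

DEFAULT_DROP_LEVELS = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.75)


def _estimable(values: np.ndarray) -> bool:
    col_const = values.min(axis=0) == values.max(axis=0)
    return int((~col_const).sum()) >= 2


def bootstrap_edge_ci(X: OccurrenceMatrix, config: EstimationConfig = EstimationConfig(),
                      B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Percentile (2.5, 97.5) bootstrap bounds for every potential edge.

    Degenerate resamples (fewer than two non-constant columns) are skipped
    and counted in the frame's ``attrs['n_skipped']``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    base = estimate_network(X, config)
    p = X.p
    iu = np.triu_indices(p, k=1)
    reps = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, X.n, size=X.n)
        vals = X.values[idx]
        if not _estimable(vals):
            skipped += 1
            logger.warning("degenerate bootstrap resample skipped")
            continue
        m = OccurrenceMatrix(vals, [f"b{i}" for i in range(X.n)],
                             list(X.symptom_codes), X.time_point)
        reps.append(estimate_network(m, config).weights[iu])
    if not reps:
        raise RuntimeError("all bootstrap replicates degenerate")
    R = np.vstack(reps)
    lo = np.percentile(R, 2.5, axis=0)
    hi = np.percentile(R, 97.5, axis=0)
    df = pd.DataFrame({
        "node_a": [X.symptom_codes[i] for i in iu[0]],
        "node_b": [X.symptom_codes[j] for j in iu[1]],
        "estimate": base.weights[iu],
        "lower": lo,
        "upper": hi,
    })
    df.attrs["n_skipped"] = skipped
    df.attrs["B"] = B
    return df


def _correlations(original: pd.DataFrame, subset: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation per index over nodes where both sides are defined."""
    out = {}
    common = original.index.intersection(subset.index)
    for idx in CENTRALITY_INDICES:
        a = original.loc[common, idx].to_numpy(dtype=float)
        b = subset.loc[common, idx].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            out[idx] = np.nan  # undefined, recorded as missing (never 0)
        else:
            out[idx] = float(np.corrcoef(a, b)[0, 1])
    return out


def case_dropping_bootstrap(X: OccurrenceMatrix,
                            levels: Sequence[float] = DEFAULT_DROP_LEVELS,
                            B: int = 1000, seed: int = 0,
                            config: EstimationConfig = EstimationConfig()
                            ) -> pd.DataFrame:
    """Correlation samples between full-data and subset centralities.

    For each drop proportion q, B subsets of ceil((1-q) n) patients are drawn
    without replacement and the network re-estimated.  Returns a long frame
    with columns (level, replicate, index, correlation).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    for q in levels:
        if not 0 <= q < 1:
            raise ValueError("drop levels must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    original = centrality_table(estimate_network(X, config))
    rows = []
    for q in levels:
        keep = math.ceil((1.0 - q) * X.n)
        if keep < 10:
            logger.warning("level %.2f skipped: only %d rows would remain", q, keep)
            continue
        for b in range(B):
            idx = rng.choice(X.n, size=keep, replace=False)
            vals = X.values[idx]
            if not _estimable(vals):
                corr = {k: np.nan for k in CENTRALITY_INDICES}
            else:
                m = OccurrenceMatrix(vals, [X.patient_ids[i] for i in idx],
                                     list(X.symptom_codes), X.time_point)
                corr = _correlations(original, centrality_table(estimate_network(m, config)))
            for k, v in corr.items():
                rows.append((q, b, k, v))
    return pd.DataFrame(rows, columns=["level", "replicate", "index", "correlation"])


def node_dropping_bootstrap(X: OccurrenceMatrix,
                            levels: Sequence[float] = DEFAULT_DROP_LEVELS,
                            B: int = 1000, seed: int = 0,
                            config: EstimationConfig = EstimationConfig()
                            ) -> pd.DataFrame:
    """As case-dropping, but symptom columns are dropped instead of patients.

    Correlations are computed over the retained nodes only; levels leaving
    fewer than 3 nodes are skipped.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    original = centrality_table(estimate_network(X, config))
    rows = []
    for q in levels:
        keep = X.p - int(round(q * X.p))
        if keep < 3:
            logger.warning("node-drop level %.2f skipped: only %d nodes would remain", q, keep)
            continue
        for b in range(B):
            cols = sorted(rng.choice(X.p, size=keep, replace=False))
            m = X.subset_symptoms([X.symptom_codes[c] for c in cols])
            if not _estimable(m.values):
                corr = {k: np.nan for k in CENTRALITY_INDICES}
            else:
                corr = _correlations(original, centrality_table(estimate_network(m, config)))
            for k, v in corr.items():
                rows.append((q, b, k, v))
    return pd.DataFrame(rows, columns=["level", "replicate", "index", "correlation"])


def cs_coefficient(samples: pd.DataFrame, threshold: float = 0.7,
                   prob: float = 0.95) -> dict[str, float]:
    """CS per index: the largest q in the tested grid such that at q and at
    every smaller tested q at least `prob` of replicates correlate >= `threshold`
    with the full-sample centralities; 0 if no level qualifies.

    Undefined correlations count as failures.
    """
    if samples.empty:
        raise ValueError("no correlation samples")
    out: dict[str, float] = {}
    levels = sorted(samples["level"].unique())
    for idx in samples["index"].unique():
        sub = samples[samples["index"] == idx]
        cs = 0.0
        for q in levels:
            corr = sub.loc[sub["level"] == q, "correlation"].to_numpy(dtype=float)
            if len(corr) < 2:
                break
            ok = np.where(np.isnan(corr), False, corr >= threshold)
            if ok.mean() >= prob:
                cs = q
            else:
                if q < max(levels):
                    logger.info("CS(%s): monotone qualifier binds at level %.2f", idx, q)
                break
        out[str(idx)] = float(cs)
    return out


@dataclass
class StabilityReport:
    """Bundle of edge CIs, correlation samples and CS coefficients."""

    edge_ci: pd.DataFrame
    case_dropping: pd.DataFrame
    node_dropping: pd.DataFrame | None
    cs: dict[str, float]
    B: int
    seed: int
    levels: tuple[float, ...] = DEFAULT_DROP_LEVELS

    def to_json(self, path: str | Path) -> None:
        doc = {
            "B": self.B,
            "seed": self.seed,
            "levels": list(self.levels),
            "cs": self.cs,
            "edge_ci": self.edge_ci.to_dict(orient="records"),
            "case_dropping": self.case_dropping.to_dict(orient="records"),
            "node_dropping": (self.node_dropping.to_dict(orient="records")
                              if self.node_dropping is not None else None),
        }
        Path(path).write_text(json.dumps(doc, indent=1, allow_nan=True, default=float))


def stability_report(X: OccurrenceMatrix, config: EstimationConfig = EstimationConfig(),
                     levels: Sequence[float] = DEFAULT_DROP_LEVELS,
                     B: int = 1000, seed: int = 0,
                     include_node_dropping: bool = True) -> StabilityReport:
    """Run the full accuracy/stability battery on one occurrence matrix."""
    edge_ci = bootstrap_edge_ci(X, config, B=B, seed=seed)
    cases = case_dropping_bootstrap(X, levels, B=B, seed=seed + 1, config=config)
    nodes = (node_dropping_bootstrap(X, levels, B=B, seed=seed + 2, config=config)
             if include_node_dropping else None)
    return StabilityReport(edge_ci=edge_ci, case_dropping=cases, node_dropping=nodes,
                           cs=cs_coefficient(cases), B=B, seed=seed,
                           levels=tuple(levels))
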