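"""End-to-end per-time-point analysis and cross-network cluster bookkeeping.

One call runs estimation, community detection, centralities, density,
occurrence rates and a force-directed layout for a single occurrence matrix;
helper functions name the detected communities against anchor symptom sets
and tabulate how consistently each named cluster recurs across networks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .centrality import centrality_table
from .communities import CommunityPartition, walktrap, write_partition_csv
from .estimation import (EstimationConfig, IsingNetwork, estimate_network,
                         network_density, to_networkx, write_edgelist,
                         write_graphml)
from .io import OccurrenceMatrix, RateTable, occurrence_rates, round_half_up

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "DEFAULT_ANCHORS",
    "run_timepoint_analysis",
    "match_and_name_clusters",
    "consistency_table",
    "layout_fr",
    "export_report",
]

#: anchor symptom sets for naming communities; the cores that recur in every
#: cancer-symptom network (codes as in the standard 38-symptom codebook).
DEFAULT_ANCHORS: dict[str, frozenset[str]] = {
    "psychological": frozenset({"Worry", "Sad", "Irritable", "Nervous"}),
    "respiratory": frozenset({"Sob", "Difbreath", "Chest"}),
    "gastrointestinal": frozenset({"Taste", "Appetite", "Nausea", "Vomit"}),
}


@dataclass(frozen=True)
class PipelineConfig:
    """One config for the whole pipeline; serializable as YAML."""

    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    walk_length: int = 4
    layout_iterations: int = 500
    seed: int = 0
    stability_levels: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.75)
    bootstrap_B: int = 1000
    anchors: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        est = EstimationConfig(**doc.pop("estimation", {}))
        anchors = {k: frozenset(v) for k, v in doc.pop("anchors", {}).items()} \
            or dict(DEFAULT_ANCHORS)
        if "stability_levels" in doc:
            doc["stability_levels"] = tuple(doc["stability_levels"])
        return cls(estimation=est, anchors=anchors, **doc)


@dataclass
class AnalysisReport:
    """Everything the pipeline computes for one time point."""

    time_point: str | None
    network: IsingNetwork
    partition: CommunityPartition
    centralities: pd.DataFrame
    density: float
    rates: RateTable
    layout: dict[str, tuple[float, float]]


def layout_fr(net: IsingNetwork, seed: int = 0, iterations: int = 500
              ) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold coordinates on absolute weights; seed-deterministic."""
    if net.p == 1:
        return {net.node_labels[0]: (0.0, 0.0)}
    g = to_networkx(net, absolute=True)
    pos = nx.spring_layout(g, seed=seed, iterations=iterations, weight="weight")
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}


def run_timepoint_analysis(X: OccurrenceMatrix,
                           config: PipelineConfig = PipelineConfig()) -> AnalysisReport:
    """estimate_network -> walktrap -> centralities -> density -> rates -> layout."""
    stage = "estimation"
    try:
        net = estimate_network(X, config.estimation)
        stage = "community detection"
        part = walktrap(net, t=config.walk_length)
        stage = "centrality"
        cent = centrality_table(net)
        stage = "density"
        dens = network_density(net)
        stage = "occurrence rates"
        rates = occurrence_rates(X)
        stage = "layout"
        layout = layout_fr(net, seed=config.seed, iterations=config.layout_iterations)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return AnalysisReport(time_point=X.time_point, network=net, partition=part,
                          centralities=cent, density=dens, rates=rates, layout=layout)


def match_and_name_clusters(partitions: Mapping[str, CommunityPartition],
                            anchors: Mapping[str, frozenset[str] | set[str]] | None = None,
                            ) -> dict[str, dict[int, str]]:
    """Assign anchor names to communities by maximal Jaccard overlap.

    Per network, each anchor names at most one community and each community
    receives at most one name (greedy by descending overlap); ties on the
    same anchor leave all tied communities unnamed, with a warning.
    """
    anchors = {k: frozenset(v) for k, v in (anchors or DEFAULT_ANCHORS).items()}
    all_syms = [s for v in anchors.values() for s in v]
    if len(all_syms) != len(set(all_syms)):
        raise ValueError("anchor sets must be disjoint")
    out: dict[str, dict[int, str]] = {}
    for net_name, part in partitions.items():
        members = part.members()
        cand = []
        for cid, nodes in members.items():
            nodeset = set(nodes)
            for name, anchor in anchors.items():
                j = len(nodeset & anchor) / len(nodeset | anchor)
                if j > 0:
                    cand.append((j, cid, name))
        cand.sort(key=lambda x: (-x[0], x[1], x[2]))
        named: dict[int, str] = {}
        used_names: set[str] = set()
        i = 0
        while i < len(cand):
            j, cid, name = cand[i]
            tied = [c for c in cand if c[0] == j and c[2] == name and c[1] != cid
                    and c[1] not in named]
            if tied and cid not in named and name not in used_names:
                warnings.warn(f"{net_name}: communities tied on anchor {name!r}; "
                              "none named", stacklevel=2)
                used_names.add(name)  # block the anchor entirely
                i += 1
                continue
            if cid not in named and name not in used_names:
                named[cid] = name
                used_names.add(name)
            i += 1
        out[net_name] = named
    return out


def consistency_table(partitions: Mapping[str, CommunityPartition],
                      names: Mapping[str, Mapping[int, str]]) -> pd.DataFrame:
    """Cluster consistency across networks.

    For each cluster name, the union of member symptoms across all networks
    is the denominator; per network the consistency is
    100 * |members there| / |union|, half-up to one decimal (0 when absent).
    """
    cluster_members: dict[str, dict[str, set[str]]] = {}
    for net_name, part in partitions.items():
        by_id = part.members()
        for cid, cname in names.get(net_name, {}).items():
            cluster_members.setdefault(cname, {})[net_name] = set(by_id[cid])
    rows = {}
    for cname, per_net in cluster_members.items():
        union: set[str] = set().union(*per_net.values())
        row = {}
        for net_name in partitions:
            present = per_net.get(net_name, set())
            row[net_name] = round_half_up(100.0 * len(present) / len(union), 1)
        row["union_size"] = len(union)
        rows[cname] = row
    df = pd.DataFrame(rows).T
    df.index.name = "cluster"
    return df


def export_report(report: AnalysisReport, out_dir: str | Path,
                  prefix: str | None = None) -> None:
    """Write the numerical artifacts of one analysis to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = prefix or (report.time_point or "network")
    write_edgelist(report.network, out / f"{tag}_edges.tsv")
    write_graphml(report.network, out / f"{tag}_network.graphml")
    pd.DataFrame({"code": report.network.node_labels,
                  "threshold": report.network.thresholds}).to_csv(
        out / f"{tag}_thresholds.csv", index=False)
    write_partition_csv(report.partition, out / f"{tag}_partition.csv")
    report.centralities.to_csv(out / f"{tag}_centrality.csv",
                               na_rep="")  # undefined closeness -> empty field
    report.rates.to_csv(out / f"{tag}_rates.csv")
    summary = {
        "time_point": report.time_point,
        "n_nodes": report.network.p,
        "n_edges": len(report.network.edges()),
        "density_percent": report.density,
        "n_communities": report.partition.n_communities,
        "modularity": report.partition.modularity_per_cut[report.partition.chosen_cut],
        "layout": {k: list(v) for k, v in sorted(report.layout.items())},
    }
    (out / f"{tag}_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
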