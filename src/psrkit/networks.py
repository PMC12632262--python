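"""Covariation networks: core/extended edge tiers, clusters, and hubs.

Core networks are the pairs whose corrected MI ranks in the top 1% of all
analysable pairs; extended networks add pairs ranking between the first and
second percentiles.  Both tiers are restricted to statistically significant
pairs (z ≥ threshold).  Clusters are connected components of the core graph
with at least ``min_size`` members; extended edges are attached to a cluster
when incident on one of its members (first-order neighbors only).  A
best-neighbor edge filter — keep an edge iff it is the maximum-scoring
incident edge of at least one endpoint — is available for sparsifying dense
cores before manual inspection.

Hub statistics summarize each position's cumulative corrected-MI score over
its significant pairs (every edge contributes to both endpoints) and its
degree in the significant-pair graph.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .covariation import CovariationResult, top_fraction_indices

__all__ = [
    "Edge",
    "Cluster",
    "NetworkSet",
    "HubReport",
    "best_neighbor_filter",
    "build_networks",
    "hub_report",
    "edges_to_tsv",
    "networks_to_sif",
    "clusters_to_json",
]

Edge = tuple[int, int, float]  # (pos_i, pos_j, corrected MI score)


def best_neighbor_filter(edges: Iterable[Edge]) -> list[Edge]:
    """Keep an edge iff it is the best (max-score) incident edge of at least
    one endpoint; score ties are all kept.  Deterministic."""
    edges = list(edges)
    best: dict[int, float] = {}
    for u, v, s in edges:
        for node in (u, v):
            if node not in best or s > best[node]:
                best[node] = s
    return [e for e in edges if e[2] == best[e[0]] or e[2] == best[e[1]]]


@dataclasses.dataclass(frozen=True)
class Cluster:
    """One core network: its member positions and edges."""

    members: tuple[int, ...]
    core_edges: tuple[Edge, ...]
    extended_edges: tuple[Edge, ...] = ()

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def extended_members(self) -> tuple[int, ...]:
        extra = {n for u, v, _ in self.extended_edges for n in (u, v)}
        return tuple(sorted(extra - set(self.members)))


@dataclasses.dataclass(frozen=True)
class NetworkSet:
    """Core and extended covariation networks for one alignment."""

    core_edges: tuple[Edge, ...]
    extended_edges: tuple[Edge, ...]
    clusters: tuple[Cluster, ...]
    min_cluster_size: int = 3
    core_pct: float = 0.01
    extended_pct: float = 0.02
    group_label: str = ""

    @property
    def clustered_positions(self) -> tuple[int, ...]:
        return tuple(sorted({m for c in self.clusters for m in c.members}))


def _ranked_pairs(cov: CovariationResult) -> pd.DataFrame:
    t = cov.pair_table()
    return t[np.isfinite(t["corrected_mi"])].reset_index(drop=True)


def build_networks(
    cov: CovariationResult,
    core_pct: float = 0.01,
    extended_pct: float = 0.02,
    min_size: int = 3,
    percentile_over: str = "all",
    best_neighbor: bool = False,
) -> NetworkSet:
    """Extract core/extended networks from a covariation result.

    The top ``core_pct`` (resp. ``core_pct``–``extended_pct``) of pairs by
    corrected MI — percentile basis ``"all"`` analysable pairs by default,
    or ``"significant"`` pairs only — are intersected with the significant
    set to form the core (resp. extended) tier.  Clusters are connected
    components of the core graph with ≥ ``min_size`` members; pass
    ``best_neighbor=True`` to sparsify the core with the best-neighbor
    filter before finding components.  No qualifying edges yields an empty
    NetworkSet, not an error.
    """
    if not 0 < core_pct <= extended_pct:
        raise ValueError("need 0 < core_pct <= extended_pct")
    if percentile_over not in ("all", "significant"):
        raise ValueError("percentile_over must be 'all' or 'significant'")
    pairs = _ranked_pairs(cov)
    if percentile_over == "significant":
        pairs = pairs[pairs["significant"]].reset_index(drop=True)
    empty = NetworkSet(
        (), (), (), min_size, core_pct, extended_pct, cov.group_label
    )
    if not len(pairs):
        return empty
    scores = pairs["corrected_mi"].to_numpy()
    core_idx = set(top_fraction_indices(scores, core_pct).tolist())
    ext_idx = set(top_fraction_indices(scores, extended_pct).tolist()) - core_idx

    def _edges(idx: set[int]) -> list[Edge]:
        sub = pairs.iloc[sorted(idx)]
        sub = sub[sub["significant"]]
        return [
            (int(i), int(j), float(s))
            for i, j, s in zip(sub["pos_i"], sub["pos_j"], sub["corrected_mi"])
        ]

    core = sorted(_edges(core_idx), key=lambda e: -e[2])
    extended = sorted(_edges(ext_idx), key=lambda e: -e[2])
    if not core:
        return empty

    cluster_edges = best_neighbor_filter(core) if best_neighbor else core
    g = nx.Graph()
    g.add_weighted_edges_from(cluster_edges)
    clusters: list[Cluster] = []
    for comp in nx.connected_components(g):
        if len(comp) < min_size:
            continue
        members = tuple(sorted(comp))
        mset = set(members)
        c_edges = tuple(e for e in core if e[0] in mset and e[1] in mset)
        x_edges = tuple(e for e in extended if e[0] in mset or e[1] in mset)
        clusters.append(Cluster(members, c_edges, x_edges))
    clusters.sort(key=lambda c: (-c.size, c.members))
    return NetworkSet(
        core_edges=tuple(core),
        extended_edges=tuple(extended),
        clusters=tuple(clusters),
        min_cluster_size=min_size,
        core_pct=core_pct,
        extended_pct=extended_pct,
        group_label=cov.group_label,
    )


@dataclasses.dataclass(frozen=True)
class HubReport:
    """Per-position cumulative corrected-MI scores over significant pairs."""

    scores: pd.DataFrame  # position, cumulative_score, degree (desc. order)
    top: pd.DataFrame
    k: int


def hub_report(cov: CovariationResult, k: int = 10) -> HubReport:
    """Cumulative score and degree per position over significant pairs.

    Each significant edge contributes its corrected score to both endpoints.
    Positions are sorted by cumulative score (descending, position number as
    the tie-break); the top-k table includes any position tied with the k-th
    cumulative score.
    """
    sig = cov.significant_pairs()
    cum: dict[int, float] = {}
    deg: dict[int, int] = {}
    for i, j, s in zip(sig["pos_i"], sig["pos_j"], sig["corrected_mi"]):
        for node in (int(i), int(j)):
            cum[node] = cum.get(node, 0.0) + float(s)
            deg[node] = deg.get(node, 0) + 1
    df = pd.DataFrame(
        {
            "position": list(cum),
            "cumulative_score": [cum[p] for p in cum],
            "degree": [deg[p] for p in cum],
        }
    ).sort_values(
        ["cumulative_score", "position"], ascending=[False, True]
    ).reset_index(drop=True)
    if len(df) > k:
        cutoff = df["cumulative_score"].iloc[k - 1]
        top = df[df["cumulative_score"] >= cutoff].reset_index(drop=True)
    else:
        top = df.copy()
    return HubReport(scores=df, top=top, k=k)


def _tiered_edges(ns: NetworkSet) -> pd.DataFrame:
    cluster_of: dict[frozenset, int] = {}
    for cid, cl in enumerate(ns.clusters, start=1):
        for e in cl.core_edges + cl.extended_edges:
            cluster_of[frozenset(e[:2])] = cid
    rows = []
    for tier, edges in (("core", ns.core_edges), ("extended", ns.extended_edges)):
        for u, v, s in edges:
            rows.append(
                {
                    "pos_i": u,
                    "pos_j": v,
                    "score": s,
                    "tier": tier,
                    "cluster_id": cluster_of.get(frozenset((u, v)), 0),
                }
            )
    return pd.DataFrame(
        rows, columns=["pos_i", "pos_j", "score", "tier", "cluster_id"]
    )


def edges_to_tsv(ns: NetworkSet, path: str | Path) -> None:
    _tiered_edges(ns).to_csv(path, sep="\t", index=False)


def networks_to_sif(ns: NetworkSet, path: str | Path) -> None:
    """SIF edge list (relation = tier) for graph tools such as Cytoscape."""
    with open(path, "w") as fh:
        for tier, edges in (
            ("core", ns.core_edges),
            ("extended", ns.extended_edges),
        ):
            for u, v, _ in edges:
                fh.write(f"{u}\t{tier}\t{v}\n")


def clusters_to_json(ns: NetworkSet, path: str | Path) -> None:
    payload = [
        {
            "cluster_id": cid,
            "core_member_count": cl.size,
            "members": list(cl.members),
            "extended_members": list(cl.extended_members),
            "core_edges": [list(e) for e in cl.core_edges],
            "extended_edges": [list(e) for e in cl.extended_edges],
        }
        for cid, cl in enumerate(ns.clusters, start=1)
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
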