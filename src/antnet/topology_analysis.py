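"""Topology statistics, betweenness centrality, hub/bottleneck calling,
multi-localization enrichment and expression overlay.

Path statistics (mean shortest path, diameter) are taken over connected node
pairs only, each unordered pair once — the convention of the Cytoscape
NetworkAnalyzer family of tools. Betweenness sums sigma_st(n)/sigma_st over
unordered pairs {s, t} with s != n != t inside each connected component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io_formats import AnnotationSet, InteractionNetwork


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    clustering_coefficient: float
    mean_shortest_path: float
    diameter: int
    degree_distribution: dict[int, int]
    powerlaw_slope: float

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["degree_distribution"] = {int(k): int(v) for k, v in self.degree_distribution.items()}
        return d


@dataclass
class CentralityTable:
    bc: dict[str, float] = field(default_factory=dict)
    degree: dict[str, int] = field(default_factory=dict)


def average_degree(n_edges: int, n_nodes: int) -> float:
    """2E/N — the handshake-lemma mean degree."""
    return 2.0 * n_edges / n_nodes


def summarize_topology(
    net: InteractionNetwork, count_low_degree_as_zero: bool = True
) -> TopologySummary:
    """Global topology summary of a simple undirected network.

    The clustering coefficient is the mean local clustering over all nodes
    (degree < 2 contributing 0 when ``count_low_degree_as_zero``). The
    power-law slope is the least-squares slope of log(count) vs log(degree)
    over non-empty degree bins with degree >= 1.
    """
    if net.n_nodes() == 0:
        raise ValueError("empty network")
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    nodes = list(g.nodes)
    if count_low_degree_as_zero:
        cc = sum(nx.clustering(g).values()) / n
    else:
        vals = [v for node, v in nx.clustering(g).items() if g.degree[node] >= 2]
        cc = sum(vals) / len(vals) if vals else 0.0
    total_dist = 0
    n_pairs = 0
    diameter = 0
    for source, dists in nx.all_pairs_shortest_path_length(g):
        for target, d in dists.items():
            if source < target:  # each unordered connected pair once
                total_dist += d
                n_pairs += 1
                diameter = max(diameter, d)
    mean_sp = total_dist / n_pairs if n_pairs else 0.0
    degrees = [g.degree[x] for x in nodes]
    dist: dict[int, int] = {}
    for d in degrees:
        dist[d] = dist.get(d, 0) + 1
    positive = sorted(k for k in dist if k >= 1)
    if len(positive) >= 2:
        logs = np.log(np.array(positive, dtype=float))
        logc = np.log(np.array([dist[k] for k in positive], dtype=float))
        slope = float(np.polyfit(logs, logc, 1)[0])
    else:
        slope = float("nan")
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        avg_degree=average_degree(e, n),
        clustering_coefficient=cc,
        mean_shortest_path=mean_sp,
        diameter=diameter,
        degree_distribution=dist,
        powerlaw_slope=slope,
    )


def betweenness(net: InteractionNetwork, ordered_pairs: bool = False) -> CentralityTable:
    """Exact betweenness centrality BC(n) = sum_{s!=n!=t} sigma_st(n)/sigma_st.

    Uses Brandes accumulation; with the default unordered-pair convention each
    pair {s, t} contributes once (set ``ordered_pairs`` to double for
    cross-tool comparison).
    """
    if net.n_nodes() == 0:
        raise ValueError("empty network")
    raw = nx.betweenness_centrality(net.graph, normalized=False)
    factor = 2.0 if ordered_pairs else 1.0
    table = CentralityTable()
    for node, val in raw.items():
        table.bc[node] = factor * val
        table.degree[node] = net.graph.degree[node]
    return table


def identify_hubs(net: InteractionNetwork, min_degree: int = 5) -> set[str]:
    """Proteins connecting with at least ``min_degree`` partners."""
    return {n for n in net.nodes if net.graph.degree[n] >= min_degree}


def identify_bottlenecks(bc: CentralityTable, top_fraction: float = 0.2) -> set[str]:
    """Top fraction of nodes by betweenness; boundary ties are all retained."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    nodes = sorted(bc.bc, key=lambda n: (-bc.bc[n], n))
    if not nodes:
        return set()
    k = math.ceil(top_fraction * len(nodes))
    cutoff = bc.bc[nodes[k - 1]]
    return {n for n in nodes if bc.bc[n] >= cutoff}


@dataclass
class EnrichmentRecord:
    odds_ratio: float
    p_value: float
    group_fraction: float
    complement_fraction: float
    table: tuple[tuple[int, int], tuple[int, int]]


def multiloc_enrichment(
    group: set[str], net: InteractionNetwork, ann: AnnotationSet
) -> EnrichmentRecord:
    """Fisher test of multi-localization (>= 2 compartments) in a node group
    versus the rest of the network."""
    if not group:
        raise ValueError("empty group")
    if not group <= net.nodes:
        raise ValueError("group contains nodes outside the network")

    def multi(n: str) -> bool:
        return len(ann.localization_of(n)) >= 2

    comp = net.nodes - group
    g_multi = sum(1 for n in group if multi(n))
    c_multi = sum(1 for n in comp if multi(n))
    table = ((g_multi, len(group) - g_multi), (c_multi, len(comp) - c_multi))
    odds, p = fisher_exact(table, alternative="two-sided")
    return EnrichmentRecord(
        odds_ratio=float(odds),
        p_value=float(p),
        group_fraction=g_multi / len(group),
        complement_fraction=c_multi / len(comp) if comp else float("nan"),
        table=table,
    )


def overlay_expression(nodes: set[str], ann: AnnotationSet) -> pd.DataFrame:
    """One row per node with its log2FC (NaN when unmeasured, never zero) and
    per-species ortholog flags."""
    rows = []
    for n in sorted(nodes):
        row: dict = {"protein": n, "log2fc": ann.log2fc.get(n, float("nan"))}
        for sp in ann.species:
            row[f"ortholog_{sp}"] = ann.has_ortholog(n, sp)
        rows.append(row)
    columns = ["protein", "log2fc"] + [f"ortholog_{sp}" for sp in ann.species]
    return pd.DataFrame(rows, columns=columns)
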