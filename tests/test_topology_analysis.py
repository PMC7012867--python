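import math
import random

import numpy as np
import pytest

from antnet.io_formats import AnnotationSet, InteractionNetwork
from antnet.topology_analysis import (
    average_degree,
    betweenness,
    identify_bottlenecks,
    identify_hubs,
    multiloc_enrichment,
    overlay_expression,
    summarize_topology,
)

from oracles import brute_force_betweenness, hypergeom_fisher_two_sided


def _net(*edges):
    return InteractionNetwork.from_edges(edges)


# ---------------------------------------------------------------------------
# summary statistics


def test_triangle_summary():
    s = summarize_topology(_net(("a", "b"), ("b", "c"), ("a", "c")))
    assert s.clustering_coefficient == pytest.approx(1.0)
    assert s.mean_shortest_path == pytest.approx(1.0)
    assert s.diameter == 1
    assert s.avg_degree == pytest.approx(2.0)


def test_path_graph_summary():
    # pairs: (a,b)=1, (b,c)=1, (a,c)=2 -> mean 4/3
    s = summarize_topology(_net(("a", "b"), ("b", "c")))
    assert s.clustering_coefficient == pytest.approx(0.0)
    assert s.mean_shortest_path == pytest.approx(4 / 3)
    assert s.diameter == 2


def test_disconnected_pairs_excluded():
    s = summarize_topology(_net(("a", "b"), ("c", "d")))
    assert s.mean_shortest_path == pytest.approx(1.0)
    assert s.diameter == 1


def test_complete_graph_closed_forms():
    nodes = [f"n{i}" for i in range(8)]
    edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
    s = summarize_topology(InteractionNetwork.from_edges(edges))
    assert s.clustering_coefficient == pytest.approx(1.0)
    assert s.diameter == 1
    assert s.avg_degree == pytest.approx(7.0)


def test_degree_handshake(demo_bundle):
    s = summarize_topology(demo_bundle.mapped_network)
    assert sum(d * c for d, c in s.degree_distribution.items()) == 2 * s.n_edges
    assert s.avg_degree == pytest.approx(2 * s.n_edges / s.n_nodes)
    assert s.diameter >= s.mean_shortest_path


def test_empty_network_rejected():
    with pytest.raises(ValueError):
        summarize_topology(InteractionNetwork())


def test_printed_count_arithmetic():
    assert round(average_degree(13640, 3914), 3) == 6.970


# ---------------------------------------------------------------------------
# betweenness


def test_path_graph_betweenness():
    bc = betweenness(_net(("a", "b"), ("b", "c"), ("c", "d"))).bc
    assert bc["a"] == 0 and bc["d"] == 0
    assert bc["b"] == pytest.approx(2.0)
    assert bc["c"] == pytest.approx(2.0)


def test_star_betweenness_closed_form():
    k = 6
    edges = [("hub", f"leaf{i}") for i in range(k)]
    bc = betweenness(InteractionNetwork.from_edges(edges)).bc
    assert bc["hub"] == pytest.approx(k * (k - 1) / 2)
    assert all(bc[f"leaf{i}"] == 0 for i in range(k))


def test_clique_betweenness_zero():
    nodes = "abcde"
    edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
    assert all(v == 0 for v in betweenness(_net(*edges)).bc.values())


def test_ordered_pair_flag_doubles():
    net = _net(("a", "b"), ("b", "c"))
    assert betweenness(net, ordered_pairs=True).bc["b"] == pytest.approx(
        2 * betweenness(net).bc["b"]
    )


@pytest.mark.parametrize("seed", range(8))
def test_betweenness_matches_brute_force(seed):
    rng = random.Random(seed)
    n = rng.randint(5, 30)
    nodes = [f"n{i}" for i in range(n)]
    edges = {
        tuple(sorted(rng.sample(nodes, 2)))
        for _ in range(rng.randint(n, 3 * n))
    }
    net = InteractionNetwork.from_edges(edges, nodes)
    got = betweenness(net).bc
    expected = brute_force_betweenness(net.nodes, net.edges)
    for node in net.nodes:
        assert got[node] == pytest.approx(expected[node], abs=1e-9)


# ---------------------------------------------------------------------------
# hubs and bottlenecks


def test_hub_threshold():
    edges = [("hub", f"l{i}") for i in range(5)]
    net = InteractionNetwork.from_edges(edges)
    assert identify_hubs(net) == {"hub"}
    cycle = _net(("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"))
    assert identify_hubs(cycle) == set()
    assert identify_hubs(cycle, min_degree=1) == cycle.nodes


def test_bottleneck_top_fraction_and_ties():
    bc = betweenness(_net(("a", "b"), ("b", "c")))
    assert identify_bottlenecks(bc, top_fraction=1 / 3) == {"b"}
    assert identify_bottlenecks(bc, top_fraction=1.0) == {"a", "b", "c"}
    # all-equal BC: the boundary tie rule keeps everyone
    clique = _net(("a", "b"), ("b", "c"), ("a", "c"))
    assert identify_bottlenecks(betweenness(clique), top_fraction=0.2) == {"a", "b", "c"}


# ---------------------------------------------------------------------------
# multi-localization enrichment and expression overlay


def test_multiloc_extreme_proportions():
    net = _net(("g1", "c1"), ("g2", "c2"))
    ann = AnnotationSet(localizations={
        "g1": {"a", "b"}, "g2": {"a", "c"}, "c1": {"a"}, "c2": {"b"},
    })
    rec = multiloc_enrichment({"g1", "g2"}, net, ann)
    assert rec.group_fraction == pytest.approx(1.0)
    assert rec.complement_fraction == pytest.approx(0.0)


def test_multiloc_homogeneous_groups():
    net = _net(("a", "b"), ("c", "d"))
    ann = AnnotationSet(localizations={
        "a": {"x", "y"}, "b": {"x"}, "c": {"x", "y"}, "d": {"x"},
    })
    rec = multiloc_enrichment({"a", "b"}, net, ann)
    assert rec.odds_ratio == pytest.approx(1.0)
    assert rec.p_value == pytest.approx(1.0)


def test_multiloc_fisher_matches_oracle():
    # 110 nodes: group of 10 (7 multi), complement of 100 (56 multi)
    nodes = [f"n{i}" for i in range(110)]
    edges = [(nodes[i], nodes[i + 1]) for i in range(109)]
    net = InteractionNetwork.from_edges(edges)
    locs = {}
    for i, n in enumerate(nodes[:10]):
        locs[n] = {"a", "b"} if i < 7 else {"a"}
    for i, n in enumerate(nodes[10:]):
        locs[n] = {"a", "b"} if i < 56 else {"a"}
    rec = multiloc_enrichment(set(nodes[:10]), net, AnnotationSet(localizations=locs))
    assert rec.table == ((7, 3), (56, 44))
    assert rec.p_value == pytest.approx(hypergeom_fisher_two_sided(rec.table), rel=1e-6)


def test_multiloc_empty_group_rejected():
    with pytest.raises(ValueError):
        multiloc_enrichment(set(), _net(("a", "b")), AnnotationSet())


def test_overlay_expression_missing_is_nan():
    ann = AnnotationSet(
        log2fc={"p1": 2.3},
        ortholog_in={"p1": {"human": True}, "p2": {"human": False}},
        species=("human",),
    )
    table = overlay_expression({"p1", "p2"}, ann)
    row1 = table[table.protein == "p1"].iloc[0]
    assert row1.log2fc == pytest.approx(2.3) and bool(row1.ortholog_human)
    row2 = table[table.protein == "p2"].iloc[0]
    assert math.isnan(row2.log2fc)
    assert overlay_expression(set(), ann).empty
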