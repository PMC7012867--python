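import numpy as np
import pytest
from scipy import sparse

from antnet.confidence_scoring import (
    BandedScores,
    Clustering,
    _mcl_matrix,
    band_of,
    band_proportions,
    compare_band_counts,
    compare_score_distributions,
    mcl_cluster,
    score_interactions,
)
from antnet.io_formats import InteractionNetwork
from antnet.ppi_filters import apply_all_filters

from oracles import exact_mannwhitney_two_sided, hypergeom_fisher_two_sided


def _net(*edges):
    return InteractionNetwork.from_edges(edges)


# ---------------------------------------------------------------------------
# MCL


def test_disjoint_triangles_give_two_clusters():
    net = _net(("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z"))
    cl = mcl_cluster(net)
    assert cl.n_clusters() == 2
    assert cl.same_cluster("a", "c") and cl.same_cluster("x", "z")
    assert not cl.same_cluster("a", "x")


def test_k5_is_one_cluster():
    nodes = "abcde"
    edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
    assert mcl_cluster(_net(*edges)).n_clusters() == 1


def test_bridged_cliques_split_at_bridge():
    k4a = [(u, v) for i, u in enumerate("abcd") for v in "abcd"[i + 1:]]
    k4b = [(u, v) for i, u in enumerate("wxyz") for v in "wxyz"[i + 1:]]
    cl = mcl_cluster(_net(*k4a, *k4b, ("d", "w")), inflation=2.0)
    assert cl.n_clusters() == 2
    assert cl.same_cluster("a", "d") and cl.same_cluster("w", "z")
    assert not cl.same_cluster("d", "w")


def test_invalid_inflation_rejected():
    with pytest.raises(ValueError):
        mcl_cluster(_net(("a", "b")), inflation=1.0)


def test_mcl_matrix_stays_column_stochastic():
    rng = np.random.default_rng(0)
    n = 20
    a = (rng.random((n, n)) < 0.2).astype(float)
    a = np.triu(a, 1)
    a = a + a.T + np.eye(n)
    seen = []

    def check(m):
        seen.append(np.asarray(m.sum(axis=0)).ravel())

    _mcl_matrix(sparse.csr_matrix(a), inflation=1.5, on_iteration=check)
    assert seen, "no iterations recorded"
    for colsums in seen:
        assert np.allclose(colsums, 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# scoring


def test_isolated_edge_scores_one():
    net = _net(("u", "v"))
    cl = Clustering({"u": 0, "v": 0})
    scores = score_interactions(net, cl)
    assert scores.score[("u", "v")] == pytest.approx(1.0)
    assert scores.band[("u", "v")] == "high"


def test_clique_edges_score_one():
    nodes = "abcd"
    net = _net(*[(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]])
    cl = mcl_cluster(net)
    scores = score_interactions(net, cl)
    assert all(s == pytest.approx(1.0) for s in scores.score.values())


def test_bridge_between_triangles_scores_low():
    # hand computation: closed neighborhoods of the bridge ends share {u, v}
    # out of 6 nodes -> J = 1/3; different clusters -> score = 0.5/3
    net = _net(("a", "b"), ("a", "u"), ("b", "u"), ("x", "y"), ("x", "v"), ("y", "v"), ("u", "v"))
    cl = Clustering({"a": 0, "b": 0, "u": 0, "x": 1, "y": 1, "v": 1})
    scores = score_interactions(net, cl)
    assert scores.score[("u", "v")] == pytest.approx(1 / 6, abs=1e-4)
    assert scores.band[("u", "v")] == "low"


def test_score_monotone_in_common_neighbors():
    # same degrees, growing |N(u) & N(v)|
    base = [("u", "v"), ("u", "a"), ("v", "a")]
    more = base + [("u", "b"), ("v", "b")]
    cl = Clustering({n: 0 for n in "uvab"})
    s1 = score_interactions(_net(*base), Clustering({n: 0 for n in "uva"})).score[("u", "v")]
    s2 = score_interactions(_net(*more), cl).score[("u", "v")]
    assert s2 >= s1 - 1e-12


def test_node_missing_from_clustering_raises():
    with pytest.raises(ValueError, match="missing"):
        score_interactions(_net(("u", "v")), Clustering({"u": 0}))


def test_band_proportions_and_boundaries():
    s = BandedScores()
    for i, val in enumerate((0.1, 0.5, 0.9)):
        s.score[(f"a{i}", f"b{i}")] = val
        s.band[(f"a{i}", f"b{i}")] = band_of(val)
    assert band_proportions(s) == {"low": 1 / 3, "medium": 1 / 3, "high": 1 / 3}
    assert band_of(0.7) == "high" and band_of(0.3) == "medium"
    assert band_of(1.0) == "high" and band_of(0.0) == "low"
    with pytest.raises(ValueError):
        band_proportions(BandedScores())


# ---------------------------------------------------------------------------
# distribution comparisons, cross-checked against enumeration oracles


def _banded(vals):
    s = BandedScores()
    for i, v in enumerate(vals):
        s.score[(f"x{i}", f"y{i}")] = v
        s.band[(f"x{i}", f"y{i}")] = band_of(v)
    return s


def test_mannwhitney_identical_multisets():
    rec = compare_score_distributions(_banded([0.2, 0.5, 0.8]), _banded([0.2, 0.5, 0.8]))
    assert rec.p_value >= 0.99


def test_mannwhitney_exact_small_sample():
    rec = compare_score_distributions(_banded([0.1, 0.2, 0.3]), _banded([0.4, 0.5, 0.6]))
    oracle_p = exact_mannwhitney_two_sided([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
    assert oracle_p == pytest.approx(0.1)
    assert rec.p_value == pytest.approx(oracle_p)
    assert min(rec.u_statistic, rec.n1 * rec.n2 - rec.u_statistic) == 0


def test_mannwhitney_large_shift_is_significant():
    rng = np.random.default_rng(1)
    a = _banded(list(rng.normal(0.3, 0.05, 200).clip(0, 1)))
    b = _banded(list(rng.normal(0.7, 0.05, 200).clip(0, 1)))
    assert compare_score_distributions(a, b).p_value < 1e-10


def test_fisher_homogeneous_table():
    a = _banded([0.9] * 10 + [0.1] * 10)
    rec = compare_band_counts(a, a, "high")
    assert rec.odds_ratio == pytest.approx(1.0)
    assert rec.p_value == pytest.approx(1.0)


def test_fisher_matches_hypergeometric_enumeration():
    a = _banded([0.9] * 1 + [0.1] * 9)
    b = _banded([0.9] * 9 + [0.1] * 1)
    rec = compare_band_counts(a, b, "high")
    assert rec.table == ((1, 9), (9, 1))
    assert rec.p_value == pytest.approx(hypergeom_fisher_two_sided(rec.table), rel=1e-6)
    assert rec.p_value == pytest.approx(0.0011, abs=1e-4)


# ---------------------------------------------------------------------------
# planted-module separation


def test_intra_module_edges_outscore_noise_edges(demo_bundle):
    # dense planted modules plus sparse inter-module noise: score on the
    # unfiltered mapped network, where the planted structure is intact
    b = demo_bundle
    net = b.mapped_network
    cl = mcl_cluster(net, inflation=1.5)
    scores = score_interactions(net, cl)

    def module(protein):
        return b.truth.module_of.get(b.annotations.gene(protein))

    intra = [s for (u, v), s in scores.score.items()
             if module(u) is not None and module(u) == module(v)]
    noise = [s for (u, v), s in scores.score.items()
             if module(u) is not None and module(v) is not None
             and module(u) != module(v)]
    assert len(intra) + len(noise) >= 200
    assert np.mean(intra) > np.mean(noise)
    from scipy.stats import mannwhitneyu

    assert mannwhitneyu(intra, noise, alternative="greater").pvalue < 0.01
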