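import pytest

from antnet.functional_semantics import (
    build_nonppi_sets,
    compare_ppi_vs_nonppi,
    go_enrichment,
    semantic_similarity,
    term_similarity,
    truncate_to_level,
)
from antnet.io_formats import AnnotationSet, GoDag

from oracles import hypergeom_fisher_two_sided


def chain_dag(depth=6):
    """Root -> c1 -> ... -> c{depth} plus a parallel branch under the root."""
    dag = GoDag()
    dag.add_term("root")
    dag.roots["molecular_function"] = "root"
    prev = "root"
    for i in range(1, depth + 1):
        t = f"c{i}"
        dag.add_term(t)
        dag.add_parent(t, prev)
        prev = t
    prev = "root"
    for i in range(1, depth + 1):
        t = f"b{i}"
        dag.add_term(t)
        dag.add_parent(t, prev)
        prev = t
    return dag


# ---------------------------------------------------------------------------
# enrichment


def test_fg_equal_bg_gives_p_one():
    ann = AnnotationSet(go_terms={"p1": {"t1"}, "p2": {"t1", "t2"}})
    results = go_enrichment({"p1", "p2"}, {"p1", "p2"}, ann)
    assert all(r.p == pytest.approx(1.0) for r in results)


def test_identical_frequencies_not_significant():
    ann = AnnotationSet(go_terms={f"p{i}": {"t1"} for i in range(4)})
    ann.go_terms.update({f"q{i}": set() for i in range(4)})
    fg = {"p0", "p1", "q0", "q1"}
    bg = fg | {"p2", "p3", "q2", "q3"}
    results = go_enrichment(fg, bg, ann)
    (r,) = results
    assert r.p == pytest.approx(1.0)
    assert not r.significant


def test_enrichment_fisher_matches_oracle_and_fdr_bounds_p():
    # foreground 20 of 1000; term hits 10 fg, 50 elsewhere
    ann = AnnotationSet()
    bg = set()
    for i in range(1000):
        p = f"p{i}"
        bg.add(p)
        terms = set()
        if i < 10 or 20 <= i < 70:
            terms.add("tA")
        if i % 3 == 0:
            terms.add("tB")
        ann.go_terms[p] = terms
    fg = {f"p{i}" for i in range(20)}
    results = {r.term: r for r in go_enrichment(fg, bg, ann)}
    rec = results["tA"]
    table = ((rec.fg_count, rec.fg_total - rec.fg_count),
             (rec.bg_count - rec.fg_count,
              (rec.bg_total - rec.fg_total) - (rec.bg_count - rec.fg_count)))
    assert rec.p == pytest.approx(hypergeom_fisher_two_sided(table), rel=1e-6)
    assert rec.direction == "over"
    for r in results.values():
        assert r.fdr >= r.p - 1e-12


def test_fg_not_subset_of_bg_rejected():
    with pytest.raises(ValueError):
        go_enrichment({"a"}, {"b"}, AnnotationSet())


# ---------------------------------------------------------------------------
# level truncation


def test_deep_term_replaced_by_level_ancestor():
    dag = chain_dag(6)
    ann = AnnotationSet(go_terms={"p": {"c6"}})
    out = truncate_to_level(ann, dag, level=4)
    assert out.go_terms["p"] == {"c4"}


def test_shallow_term_kept():
    dag = chain_dag(6)
    ann = AnnotationSet(go_terms={"p": {"c2"}})
    assert truncate_to_level(ann, dag, level=4).go_terms["p"] == {"c2"}


def test_diamond_keeps_both_level_ancestors():
    dag = chain_dag(4)  # two depth-4 chains c4, b4
    dag.add_term("deep")
    dag.add_parent("deep", "c4")
    dag.add_parent("deep", "b4")
    ann = AnnotationSet(go_terms={"p": {"deep"}})
    assert truncate_to_level(ann, dag, level=4).go_terms["p"] == {"c4", "b4"}


def test_unknown_terms_dropped():
    dag = chain_dag(3)
    ann = AnnotationSet(go_terms={"p": {"c2", "GO:not_in_dag"}})
    assert truncate_to_level(ann, dag, level=4).go_terms["p"] == {"c2"}


# ---------------------------------------------------------------------------
# semantic similarity


def test_identical_annotation_sets_score_one():
    dag = chain_dag(5)
    ann = AnnotationSet(go_terms={"p1": {"c3", "b2"}, "p2": {"c3", "b2"}})
    assert semantic_similarity("p1", "p2", ann, dag) == pytest.approx(1.0)


def test_similarity_symmetric():
    dag = chain_dag(5)
    ann = AnnotationSet(go_terms={"p1": {"c3"}, "p2": {"b2", "c1"}})
    assert semantic_similarity("p1", "p2", ann, dag) == pytest.approx(
        semantic_similarity("p2", "p1", ann, dag)
    )


def test_disjoint_branches_score_low():
    # terms deep in different root branches share only the root
    dag = chain_dag(3)
    ann = AnnotationSet(go_terms={"p1": {"c3"}, "p2": {"b3"}})
    assert semantic_similarity("p1", "p2", ann, dag) < 0.4


def test_unannotated_protein_gives_missing():
    dag = chain_dag(3)
    ann = AnnotationSet(go_terms={"p1": {"c1"}})
    assert semantic_similarity("p1", "p2", ann, dag) is None


def test_removing_shared_ancestry_lowers_similarity():
    dag1 = chain_dag(4)
    sim_shared = term_similarity("c3", "c4", dag1)
    # re-root c-branch so that c3/c4 no longer share c1, c2
    dag2 = chain_dag(4)
    dag2.parents["c3"] = {("root", "is_a")}
    sim_less = term_similarity("c3", "c4", dag2)
    assert sim_less <= sim_shared


# ---------------------------------------------------------------------------
# non-PPI sets and the comparison


def test_nonppi_forced_outcome():
    sets = build_nonppi_sets({"a", "b", "c"}, {("a", "b")}, n_sets=3, set_size=2, seed=1)
    for s in sets:
        assert s == {("a", "c"), ("b", "c")}


def test_nonppi_all_pairs_excluded_raises():
    with pytest.raises(ValueError):
        build_nonppi_sets({"a", "b", "c"}, {("a", "b"), ("a", "c"), ("b", "c")},
                          n_sets=1, set_size=1, seed=1)


def test_nonppi_deterministic_and_disjoint_from_excluded():
    proteins = {f"p{i}" for i in range(30)}
    excluded = {("p0", "p1"), ("p2", "p3")}
    s1 = build_nonppi_sets(proteins, excluded, n_sets=5, set_size=10, seed=9)
    s2 = build_nonppi_sets(proteins, excluded, n_sets=5, set_size=10, seed=9)
    assert s1 == s2
    for s in s1:
        assert len(s) == 10
        assert not (s & excluded)


def test_compare_identical_scores_gives_p_near_one():
    dag = chain_dag(4)
    ann = AnnotationSet(go_terms={p: {"c3"} for p in "abcdef"})
    ppi = {("a", "b"), ("c", "d")}
    nonppi = [{("e", "f"), ("a", "c")}]
    comp = compare_ppi_vs_nonppi(ppi, nonppi, ann, dag)
    assert comp.p_values[0] > 0.9


def test_empty_nonppi_list_gives_means_only():
    dag = chain_dag(4)
    ann = AnnotationSet(go_terms={p: {"c3"} for p in "ab"})
    comp = compare_ppi_vs_nonppi({("a", "b")}, [], ann, dag)
    assert comp.ppi_mean == pytest.approx(1.0)
    assert comp.nonppi_score_sets == [] and comp.p_values == []
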