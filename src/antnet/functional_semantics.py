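"""GO over/under-representation, level truncation, DAG-based semantic
similarity of protein pairs, and the interacting-vs-random-pair comparison.

Semantic similarity follows the Wang graph-based measure: each annotation
term induces S-values over its ancestor closure, propagated multiplicatively
through is_a (weight 0.8) and part_of (weight 0.6) edges; a term pair scores
the summed S-values over shared ancestors relative to their semantic totals,
and a protein pair scores the best-match average over both annotation sets.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationSet, GoDag, canonical_pair

logger = logging.getLogger(__name__)

W_IS_A = 0.8
W_PART_OF = 0.6


@dataclass
class EnrichmentResult:
    term: str
    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    odds_ratio: float
    p: float
    fdr: float
    direction: str

    @property
    def significant(self) -> bool:
        return self.fdr < 0.05


def go_enrichment(fg: set[str], bg: set[str], ann: AnnotationSet) -> list[EnrichmentResult]:
    """Per-term two-tailed Fisher exact test of a foreground protein set
    against a background, with Benjamini-Hochberg FDR across all tested
    terms. Direction is over/under according to the odds ratio."""
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    fg_total, bg_total = len(fg), len(bg)
    terms: set[str] = set()
    for p in bg:
        terms |= ann.terms_of(p)
    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    for term in sorted(terms):
        fg_count = sum(1 for p in fg if term in ann.terms_of(p))
        bg_count = sum(1 for p in bg if term in ann.terms_of(p))
        table = (
            (fg_count, fg_total - fg_count),
            (bg_count - fg_count, (bg_total - fg_total) - (bg_count - fg_count)),
        )
        odds, p = fisher_exact(table, alternative="two-sided")
        fg_freq = fg_count / fg_total if fg_total else 0.0
        rest_total = bg_total - fg_total
        rest_freq = (bg_count - fg_count) / rest_total if rest_total else fg_freq
        direction = "over" if fg_freq >= rest_freq else "under"
        results.append(
            EnrichmentResult(term, fg_count, fg_total, bg_count, bg_total,
                             float(odds), float(p), 1.0, direction)
        )
        pvals.append(float(p))
    if pvals:
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, fdrs):
            r.fdr = float(q)
    return results


def truncate_to_level(ann: AnnotationSet, dag: GoDag, level: int = 4) -> AnnotationSet:
    """Replace each protein's terms by their ancestors at DAG depth ``level``
    (shortest is_a distance from the namespace root, root depth 0); shallower
    terms are kept as-is. Terms absent from the DAG are dropped with a
    warning."""
    depth_cache: dict[str, int] = {}

    def depth(t: str) -> int:
        if t not in depth_cache:
            depth_cache[t] = dag.depth(t)
        return depth_cache[t]

    new_terms: dict[str, set[str]] = {}
    dropped = 0
    for protein, terms in ann.go_terms.items():
        kept: set[str] = set()
        for t in terms:
            if t not in dag.terms:
                dropped += 1
                continue
            d = depth(t)
            if d <= level:
                kept.add(t)
            else:
                # every ancestor at exactly the requested depth is retained
                kept |= {a for a in dag.ancestors(t) if depth(a) == level}
        if kept:
            new_terms[protein] = kept
    if dropped:
        logger.warning("dropped %d annotation terms absent from the DAG", dropped)
    return AnnotationSet(
        domains=ann.domains,
        localizations=ann.localizations,
        gene_of=ann.gene_of,
        go_terms=new_terms,
        log2fc=ann.log2fc,
        ortholog_in=ann.ortholog_in,
        species=ann.species,
    )


# ---------------------------------------------------------------------------
# Wang-style semantic similarity


def _s_values(term: str, dag: GoDag, w_is_a: float, w_part_of: float) -> dict[str, float]:
    """Semantic contributions of a term's ancestor closure (term itself = 1;
    each ancestor takes the max product of edge weights along paths down)."""
    s = {term: 1.0}
    # process terms in decreasing S order so maxima propagate correctly
    frontier = [term]
    while frontier:
        frontier.sort(key=lambda t: -s[t])
        t = frontier.pop(0)
        for parent, rel in dag.parents.get(t, set()):
            w = w_is_a if rel == "is_a" else w_part_of
            cand = s[t] * w
            if cand > s.get(parent, 0.0):
                s[parent] = cand
                if parent not in frontier:
                    frontier.append(parent)
    return s


def term_similarity(
    t1: str, t2: str, dag: GoDag, w_is_a: float = W_IS_A, w_part_of: float = W_PART_OF
) -> float:
    """Wang similarity of two GO terms in [0, 1]."""
    s1 = _s_values(t1, dag, w_is_a, w_part_of)
    s2 = _s_values(t2, dag, w_is_a, w_part_of)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    num = sum(s1[t] + s2[t] for t in common)
    den = sum(s1.values()) + sum(s2.values())
    return num / den


def semantic_similarity(
    p1: str,
    p2: str,
    ann: AnnotationSet,
    dag: GoDag,
    w_is_a: float = W_IS_A,
    w_part_of: float = W_PART_OF,
) -> float | None:
    """Best-match-average similarity of two proteins' annotation sets.

    Symmetric; identical annotation sets score 1. Returns None when either
    protein has no usable annotation (excluded from aggregates, logged by the
    callers)."""
    terms1 = {t for t in ann.terms_of(p1) if t in dag.terms}
    terms2 = {t for t in ann.terms_of(p2) if t in dag.terms}
    if not terms1 or not terms2:
        return None
    sim: dict[tuple[str, str], float] = {}
    for a in terms1:
        for b in terms2:
            sim[(a, b)] = term_similarity(a, b, dag, w_is_a, w_part_of)
    best1 = sum(max(sim[(a, b)] for b in terms2) for a in terms1)
    best2 = sum(max(sim[(a, b)] for a in terms1) for b in terms2)
    return (best1 + best2) / (len(terms1) + len(terms2))


# ---------------------------------------------------------------------------
# PPI vs non-PPI comparison


def build_nonppi_sets(
    proteins: set[str],
    excluded: set[tuple[str, str]],
    n_sets: int = 30,
    set_size: int = 100,
    seed: int = 0,
) -> list[set[tuple[str, str]]]:
    """Random non-interacting pair sets: each set holds ``set_size`` distinct
    unordered pairs of annotated proteins, none present in ``excluded`` (the
    preliminary interactome), sampled without replacement within a set."""
    pool = sorted(proteins)
    excluded_canon = {canonical_pair(*e) for e in excluded}
    n_eligible = len(pool) * (len(pool) - 1) // 2 - sum(
        1 for e in excluded_canon if e[0] in proteins and e[1] in proteins
    )
    if n_eligible < set_size:
        raise ValueError(
            f"only {n_eligible} eligible pairs; cannot draw sets of {set_size}"
        )
    rng = random.Random(int(seed) % (2**31))
    sets: list[set[tuple[str, str]]] = []
    for _ in range(n_sets):
        chosen: set[tuple[str, str]] = set()
        while len(chosen) < set_size:
            a, b = rng.sample(pool, 2)
            pair = canonical_pair(a, b)
            if pair in excluded_canon or pair in chosen:
                continue
            chosen.add(pair)
        sets.append(chosen)
    return sets


@dataclass
class SimilarityComparison:
    ppi_scores: list[float]
    nonppi_score_sets: list[list[float]] = field(default_factory=list)
    u_statistics: list[float] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    n_unscored_ppi: int = 0

    @property
    def ppi_mean(self) -> float:
        return sum(self.ppi_scores) / len(self.ppi_scores)

    @property
    def nonppi_means(self) -> list[float]:
        return [sum(s) / len(s) for s in self.nonppi_score_sets]


def compare_ppi_vs_nonppi(
    ppi: set[tuple[str, str]],
    nonppi_sets: list[set[tuple[str, str]]],
    ann: AnnotationSet,
    dag: GoDag,
) -> SimilarityComparison:
    """Score every pair list with the semantic-similarity measure and run a
    Mann-Whitney U of the interacting pairs against each random set."""
    cache: dict[tuple[str, str], float | None] = {}

    def scores_of(pairs: set[tuple[str, str]]) -> tuple[list[float], int]:
        vals: list[float] = []
        unscored = 0
        for a, b in sorted(pairs):
            key = canonical_pair(a, b)
            if key not in cache:
                cache[key] = semantic_similarity(a, b, ann, dag)
            if cache[key] is None:
                unscored += 1
            else:
                vals.append(cache[key])
        return vals, unscored

    ppi_scores, n_unscored = scores_of(ppi)
    if n_unscored:
        logger.warning("%d interacting pairs had no usable annotation", n_unscored)
    comp = SimilarityComparison(ppi_scores=ppi_scores, n_unscored_ppi=n_unscored)
    for pairs in nonppi_sets:
        vals, _ = scores_of(pairs)
        comp.nonppi_score_sets.append(vals)
        if ppi_scores and vals:
            res = mannwhitneyu(ppi_scores, vals, alternative="two-sided")
            comp.u_statistics.append(float(res.statistic))
            comp.p_values.append(float(res.pvalue))
    return comp
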