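"""The three successive pruning steps applied to the preliminary interolog
network: domain-domain interaction (DDI) support, shared subcellular
localization, and isoform merging.

Each filter returns a new network; nodes left without edges are removed so
the node counts reported per stage reflect interacting proteins only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import (
    AnnotationSet,
    DdiReference,
    InteractionNetwork,
    OTHER_COMPARTMENT,
    canonical_pair,
)


def filter_by_ddi(
    net: InteractionNetwork, ann: AnnotationSet, ddi: DdiReference
) -> InteractionNetwork:
    """Keep edges whose endpoint domain sets contain a known interacting
    domain-family pair (homotypic pairs count). Every surviving edge gains
    ``ddi_supported=True``; edges with no domain evidence are removed, as are
    nodes that end up isolated."""
    out = InteractionNetwork()
    for a, b in net.edges:
        if ddi.supports(ann.domains_of(a), ann.domains_of(b)):
            attrs = dict(net.edge_attrs(a, b))
            attrs["ddi_supported"] = True
            out.add_edge(a, b, **attrs)
    return out


def filter_by_localization(net: InteractionNetwork, ann: AnnotationSet) -> InteractionNetwork:
    """Keep edges whose endpoints share at least one predicted compartment.

    Proteins without a prediction carry the single compartment ``other``;
    "other" matches only "other" (absence of a prediction is not evidence of
    co-localization with a predicted compartment). Kept edges record their
    ``shared_compartments``.
    """
    out = InteractionNetwork()
    for a, b in net.edges:
        shared = ann.localization_of(a) & ann.localization_of(b)
        if shared:
            attrs = dict(net.edge_attrs(a, b))
            attrs["shared_compartments"] = shared
            out.add_edge(a, b, **attrs)
    return out


@dataclass
class LocalizationMatrix:
    """Symmetric compartment x compartment PPI count table plus per-
    compartment protein totals."""

    counts: pd.DataFrame
    protein_totals: pd.Series


def localization_pair_matrix(net: InteractionNetwork, ann: AnnotationSet) -> LocalizationMatrix:
    """Cross-tabulate edges of a localization-filtered network by the
    compartment assignments of their endpoints.

    Each edge contributes one count to cell (c1, c2) for every unordered
    compartment pair with c1 in loc(u) and c2 in loc(v) — an edge between two
    doubly-localized proteins can increment up to four cells. The diagonal
    counts edges whose endpoints share that compartment; off-diagonal cells
    capture the cross-assignments of multi-localized proteins. Per-compartment
    protein totals (multi-localized proteins counted in each of their
    compartments) are reported alongside.
    """
    compartments: set[str] = set()
    for n in net.nodes:
        compartments |= ann.localization_of(n)
    labels = sorted(compartments)
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for u, v in net.edges:
        cells = set()
        for c1 in ann.localization_of(u):
            for c2 in ann.localization_of(v):
                cells.add(canonical_pair(c1, c2))
        for c1, c2 in cells:
            mat.loc[c1, c2] += 1
            if c1 != c2:
                mat.loc[c2, c1] += 1
    totals = pd.Series(
        {c: sum(1 for n in net.nodes if c in ann.localization_of(n)) for c in labels},
        dtype=int,
    )
    return LocalizationMatrix(counts=mat, protein_totals=totals)


def merge_isoforms(net: InteractionNetwork, ann: AnnotationSet) -> InteractionNetwork:
    """Collapse isoforms of the same gene to a single node.

    Nodes are relabeled to their gene; parallel edges merge permissively
    (``ddi_supported`` ORs, ``shared_compartments`` unions, provenance
    accumulates) and isoform-isoform self-edges are dropped and counted.
    """
    out = InteractionNetwork()
    for a, b in net.edges:
        out.add_edge(ann.gene(a), ann.gene(b), **net.edge_attrs(a, b))
    return out


def apply_all_filters(
    net: InteractionNetwork, ann: AnnotationSet, ddi: DdiReference
) -> dict[str, InteractionNetwork]:
    """Run DDI -> localization -> isoform merge; returns all four networks
    keyed ``preliminary``/``ddi``/``localization``/``final``."""
    ddi_net = filter_by_ddi(net, ann, ddi)
    loc_net = filter_by_localization(ddi_net, ann)
    final = merge_isoforms(loc_net, ann)
    return {"preliminary": net, "ddi": ddi_net, "localization": loc_net, "final": final}
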