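"""Readers, writers and in-memory containers for every table the pipeline touches.

All edge lists are canonicalized on ingest: each unordered protein pair is
stored once with the lexicographically smaller ID first, reversed duplicates
are collapsed, and self-loops are dropped (the downstream topology metrics
assume simple graphs). TSV files are UTF-8 with a header row; multi-valued
cells use ``|`` as separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: compartment label used for proteins with no localization prediction
OTHER_COMPARTMENT = "other"

NETWORK_ATTR_COLUMNS = ("ddi_supported", "shared_compartments", "confidence", "band", "template_edge")


class ParseError(ValueError):
    """A malformed input table row."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair in canonical (lexicographic) order."""
    return (a, b) if a <= b else (b, a)


class InteractionNetwork:
    """Simple undirected PPI graph with per-edge provenance/support/score.

    Thin wrapper over :class:`networkx.Graph` that enforces canonical edge
    storage (no self-loops, lexicographic pair order) and exposes the edge
    attributes the pipeline writes: ``ddi_supported``, ``shared_compartments``,
    ``confidence``, ``band``, ``template_edge``.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self.dropped_self_loops = 0

    # -- construction ------------------------------------------------------
    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def add_edge(self, a: str, b: str, **attrs) -> bool:
        """Add an edge; returns False (and counts) if it is a self-loop.

        Adding an existing edge merges attributes permissively:
        ``template_edge`` provenance accumulates into a set, ``ddi_supported``
        ORs, ``shared_compartments`` unions, scalar attrs are overwritten.
        """
        if a == b:
            self.dropped_self_loops += 1
            self.graph.add_node(a)
            return False
        u, v = canonical_pair(a, b)
        if self.graph.has_edge(u, v):
            data = self.graph.edges[u, v]
            for key, val in attrs.items():
                if key == "template_edge":
                    data.setdefault("template_edge", set())
                    data["template_edge"] |= _as_set(val)
                elif key == "ddi_supported":
                    data["ddi_supported"] = bool(data.get("ddi_supported")) or bool(val)
                elif key == "shared_compartments":
                    data.setdefault("shared_compartments", set())
                    data["shared_compartments"] |= set(val)
                else:
                    data[key] = val
        else:
            if "template_edge" in attrs:
                attrs = dict(attrs)
                attrs["template_edge"] = _as_set(attrs["template_edge"])
            self.graph.add_edge(u, v, **attrs)
        return True

    # -- views -------------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {canonical_pair(u, v) for u, v in self.graph.edges}

    def edge_attrs(self, a: str, b: str) -> dict:
        u, v = canonical_pair(a, b)
        return self.graph.edges[u, v]

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(*canonical_pair(a, b))

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def copy(self) -> "InteractionNetwork":
        out = InteractionNetwork()
        out.graph = self.graph.copy()
        out.dropped_self_loops = self.dropped_self_loops
        return out

    def drop_isolated_nodes(self) -> int:
        isolated = [n for n in self.graph.nodes if self.graph.degree[n] == 0]
        self.graph.remove_nodes_from(isolated)
        return len(isolated)

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"InteractionNetwork({self.n_nodes()} nodes, {self.n_edges()} edges)"

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()) -> "InteractionNetwork":
        net = cls()
        for n in nodes:
            net.add_node(n)
        for a, b in edges:
            net.add_edge(a, b)
        return net


def _as_set(val) -> set:
    if isinstance(val, (set, frozenset)):
        return set(val)
    if isinstance(val, tuple):
        return {val}
    return {val}


@dataclass
class AnnotationSet:
    """Per-protein annotations: domains, compartments, isoform grouping,
    GO terms, expression and per-species ortholog flags.

    ``gene_of`` is total on its domain via the identity default; proteins
    missing a localization prediction get ``{"other"}``.
    """

    domains: dict[str, set[str]] = field(default_factory=dict)
    localizations: dict[str, set[str]] = field(default_factory=dict)
    gene_of: dict[str, str] = field(default_factory=dict)
    go_terms: dict[str, set[str]] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    ortholog_in: dict[str, dict[str, bool]] = field(default_factory=dict)
    species: tuple[str, ...] = ()

    def domains_of(self, protein: str) -> set[str]:
        return self.domains.get(protein, set())

    def localization_of(self, protein: str) -> set[str]:
        locs = self.localizations.get(protein)
        return set(locs) if locs else {OTHER_COMPARTMENT}

    def gene(self, protein: str) -> str:
        return self.gene_of.get(protein, protein)

    def terms_of(self, protein: str) -> set[str]:
        return self.go_terms.get(protein, set())

    def has_ortholog(self, protein: str, species: str) -> bool:
        return bool(self.ortholog_in.get(protein, {}).get(species, False))

    def n_species_with_ortholog(self, protein: str) -> int:
        flags = self.ortholog_in.get(protein, {})
        return sum(bool(flags.get(s, False)) for s in self.species)


@dataclass
class DdiReference:
    """Non-redundant reference list of interacting domain-family pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def add(self, d1: str, d2: str) -> None:
        self.pairs.add(canonical_pair(d1, d2))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def supports(self, domains_a: set[str], domains_b: set[str]) -> bool:
        """True if any cross pair (incl. homotypic) is a known DDI."""
        for da in domains_a:
            for db in domains_b:
                if canonical_pair(da, db) in self.pairs:
                    return True
        return False


@dataclass
class GoDag:
    """A small GO DAG: is_a / part_of parent links plus per-namespace roots."""

    terms: set[str] = field(default_factory=set)
    parents: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    roots: dict[str, str] = field(default_factory=dict)
    namespace_of: dict[str, str] = field(default_factory=dict)

    def add_term(self, term: str, namespace: str = "molecular_function") -> None:
        self.terms.add(term)
        self.namespace_of[term] = namespace
        self.parents.setdefault(term, set())

    def add_parent(self, child: str, parent: str, relation: str = "is_a") -> None:
        if relation not in ("is_a", "part_of"):
            raise ParseError(f"unknown relation token: {relation!r}")
        self.parents.setdefault(child, set()).add((parent, relation))

    def parent_terms(self, term: str) -> set[str]:
        return {p for p, _ in self.parents.get(term, set())}

    def ancestors(self, term: str) -> set[str]:
        """All ancestors (excluding the term itself) via is_a/part_of."""
        seen: set[str] = set()
        stack = list(self.parent_terms(term))
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self.parent_terms(t))
        return seen

    def depth(self, term: str) -> int:
        """Shortest is_a path length to the namespace root (root depth 0)."""
        from collections import deque

        if term in self.roots.values():
            return 0
        queue = deque([(term, 0)])
        seen = {term}
        while queue:
            t, d = queue.popleft()
            for parent, rel in self.parents.get(t, set()):
                if rel != "is_a":
                    continue
                if parent in self.roots.values():
                    return d + 1
                if parent not in seen:
                    seen.add(parent)
                    queue.append((parent, d + 1))
        raise ValueError(f"term {term} does not reach a root via is_a")


# ---------------------------------------------------------------------------
# network I/O


def read_network(path: str | Path, format: str = "tsv") -> InteractionNetwork:
    """Read an edge list (TSV with header, or SIF ``A pp B``) into a
    canonicalized :class:`InteractionNetwork`.

    Duplicate and reversed-duplicate rows collapse; self-loop rows are dropped
    with a logged count. An empty file yields an empty network.
    """
    path = Path(path)
    net = InteractionNetwork()
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        return net
    if format == "sif":
        for i, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{i}: expected 3 whitespace-separated fields, got {len(parts)}")
            a, _type, b = parts
            net.add_edge(a, b)
    elif format == "tsv":
        header = lines[0].rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: TSV header needs >=2 columns")
        lower = [h.strip().lower() for h in header]
        # benchmark tables name their columns freely; sniff case-insensitively
        ia, ib = _sniff_protein_columns(lower)
        col = {name: idx for idx, name in enumerate(lower)}
        for i, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}:{i}: expected {len(header)} columns, got {len(parts)}")
            attrs = {}
            if "ddi_supported" in col and parts[col["ddi_supported"]] != "":
                attrs["ddi_supported"] = parts[col["ddi_supported"]].lower() in ("1", "true", "yes")
            if "shared_compartments" in col and parts[col["shared_compartments"]] != "":
                attrs["shared_compartments"] = set(parts[col["shared_compartments"]].split("|"))
            if "confidence" in col and parts[col["confidence"]] != "":
                attrs["confidence"] = float(parts[col["confidence"]])
            if "band" in col and parts[col["band"]] != "":
                attrs["band"] = parts[col["band"]]
            net.add_edge(parts[ia], parts[ib], **attrs)
    else:
        raise ValueError(f"unknown network format: {format!r}")
    if net.dropped_self_loops:
        logger.warning("%s: dropped %d self-loop rows", path, net.dropped_self_loops)
    return net


_PROTEIN_COL_SYNONYMS_A = ("proteina", "protein_a", "protein1", "node1", "source", "interactor_a", "gene1")
_PROTEIN_COL_SYNONYMS_B = ("proteinb", "protein_b", "protein2", "node2", "target", "interactor_b", "gene2")


def _sniff_protein_columns(lower_header: list[str]) -> tuple[int, int]:
    ia = ib = None
    for syn in _PROTEIN_COL_SYNONYMS_A:
        if syn in lower_header:
            ia = lower_header.index(syn)
            break
    for syn in _PROTEIN_COL_SYNONYMS_B:
        if syn in lower_header:
            ib = lower_header.index(syn)
            break
    if ia is None or ib is None:
        # fall back to the first two columns
        ia, ib = 0, 1
    return ia, ib


def write_network(net: InteractionNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write a network; rows sorted by (proteinA, proteinB) so re-reading
    round-trips to an identical network."""
    path = Path(path)
    rows = sorted(net.edges)
    if format == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for a, b in rows:
                fh.write(f"{a}\tpp\t{b}\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown network format: {format!r}")
    present: list[str] = []
    for attr in NETWORK_ATTR_COLUMNS:
        if any(attr in net.edge_attrs(a, b) for a, b in rows):
            present.append(attr)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(["proteinA", "proteinB", *present]) + "\n")
        for a, b in rows:
            data = net.edge_attrs(a, b)
            cells = [a, b]
            for attr in present:
                val = data.get(attr)
                if val is None:
                    cells.append("")
                elif attr == "shared_compartments":
                    cells.append("|".join(sorted(val)))
                elif attr == "template_edge":
                    cells.append("|".join(",".join(p) for p in sorted(val)))
                elif attr == "ddi_supported":
                    cells.append("1" if val else "0")
                elif attr == "confidence":
                    cells.append(f"{val:.6f}")
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# annotation tables


def _read_tsv_rows(path: Path) -> list[list[str]]:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        return []
    return [line.rstrip("\n").split("\t") for line in lines[1:] if line.strip()]


def read_annotations(paths: Mapping[str, str | Path], species: Iterable[str] = ()) -> AnnotationSet:
    """Merge the per-protein annotation tables into one :class:`AnnotationSet`.

    Recognised table names: ``domains``, ``localizations``, ``isoforms``
    (protein, gene), ``go`` (protein, term), ``expression`` (protein, log2fc),
    ``orthologs`` (protein + one 0/1 column per species). Multi-valued cells
    are pipe-separated; one-row-per-value is accepted too.
    """
    ann = AnnotationSet(species=tuple(species))
    if "domains" in paths:
        for row in _read_tsv_rows(Path(paths["domains"])):
            ann.domains.setdefault(row[0], set()).update(v for v in row[1].split("|") if v)
    if "localizations" in paths:
        for row in _read_tsv_rows(Path(paths["localizations"])):
            ann.localizations.setdefault(row[0], set()).update(v for v in row[1].split("|") if v)
    if "isoforms" in paths:
        for row in _read_tsv_rows(Path(paths["isoforms"])):
            protein, gene = row[0], row[1]
            if protein in ann.gene_of and ann.gene_of[protein] != gene:
                raise ParseError(f"conflicting gene_of rows for {protein}: {ann.gene_of[protein]} vs {gene}")
            ann.gene_of[protein] = gene
    if "go" in paths:
        for row in _read_tsv_rows(Path(paths["go"])):
            ann.go_terms.setdefault(row[0], set()).update(v for v in row[1].split("|") if v)
    if "expression" in paths:
        for row in _read_tsv_rows(Path(paths["expression"])):
            if row[1] != "":
                ann.log2fc[row[0]] = float(row[1])
    if "orthologs" in paths:
        path = Path(paths["orthologs"])
        lines = path.read_text(encoding="utf-8").splitlines()
        header = lines[0].rstrip("\n").split("\t")
        sp_cols = header[1:]
        if not ann.species:
            ann.species = tuple(sp_cols)
        for line in lines[1:]:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            ann.ortholog_in[row[0]] = {
                sp: row[i + 1].strip() in ("1", "true", "yes", "True")
                for i, sp in enumerate(sp_cols)
            }
    return ann


def write_annotations(ann: AnnotationSet, outdir: str | Path) -> dict[str, Path]:
    """Write every populated annotation table; returns the table→path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(name: str, header: list[str], rows: list[list[str]]) -> None:
        p = outdir / f"{name}.tsv"
        with p.open("w", encoding="utf-8") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        written[name] = p

    if ann.domains:
        _write("domains", ["protein", "domains"],
               [[p, "|".join(sorted(v))] for p, v in sorted(ann.domains.items())])
    if ann.localizations:
        _write("localizations", ["protein", "compartments"],
               [[p, "|".join(sorted(v))] for p, v in sorted(ann.localizations.items())])
    if ann.gene_of:
        _write("isoforms", ["protein", "gene"],
               [[p, g] for p, g in sorted(ann.gene_of.items())])
    if ann.go_terms:
        _write("go", ["protein", "terms"],
               [[p, "|".join(sorted(v))] for p, v in sorted(ann.go_terms.items())])
    if ann.log2fc:
        _write("expression", ["protein", "log2fc"],
               [[p, f"{v:.4f}"] for p, v in sorted(ann.log2fc.items())])
    if ann.ortholog_in:
        _write("orthologs", ["protein", *ann.species],
               [[p, *("1" if flags.get(s, False) else "0" for s in ann.species)]
                for p, flags in sorted(ann.ortholog_in.items())])
    return written


# ---------------------------------------------------------------------------
# DDI reference and GO DAG


def read_ddi_reference(path: str | Path) -> DdiReference:
    ref = DdiReference()
    for row in _read_tsv_rows(Path(path)):
        ref.add(row[0], row[1])
    return ref


def write_ddi_reference(ref: DdiReference, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("domainA\tdomainB\n")
        for d1, d2 in sorted(ref.pairs):
            fh.write(f"{d1}\t{d2}\n")


def read_go_dag(path: str | Path) -> GoDag:
    """Read an OBO file (id/name/namespace/is_a/relationship: part_of)."""
    graph = obonet.read_obo(str(path))
    dag = GoDag()
    for term, data in graph.nodes(data=True):
        dag.add_term(term, data.get("namespace", "molecular_function"))
    # obonet edges run child -> parent with the relation as the edge key
    for child, parent, rel in graph.edges(keys=True):
        if rel not in ("is_a", "part_of"):
            raise ParseError(f"unknown relation token in DAG file: {rel!r}")
        dag.add_parent(child, parent, rel)
    for term in dag.terms:
        if not dag.parent_terms(term):
            dag.roots[dag.namespace_of[term]] = term
    return dag


def write_go_dag(dag: GoDag, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: go\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            fh.write(f"namespace: {dag.namespace_of.get(term, 'molecular_function')}\n")
            for parent, rel in sorted(dag.parents.get(term, set())):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
            fh.write("\n")
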