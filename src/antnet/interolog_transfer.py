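"""Ortholog-set construction and interolog transfer.

The target-species ortholog set combines two orthology methods: seed
orthologs from method 1 (InParanoid-style reciprocal-best anchors) are taken
as-is, and non-seed pairs are admitted only when both method 1 and method 2
(OrthoMCL-style clustering) agree. Template interactions are then transferred
to every combination of the endpoints' target orthologs — the interolog
convention — keeping provenance of the originating template edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .io_formats import InteractionNetwork

ORIGIN_TAGS = ("method1_seed", "method1_all", "method2")


@dataclass
class OrthologMap:
    """(template protein, target protein) pairs with method-origin tags."""

    tags: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def add(self, template: str, target: str, origin: str) -> None:
        if origin not in ORIGIN_TAGS:
            raise ValueError(f"unknown origin tag: {origin!r}")
        self.tags.setdefault((template, target), set()).add(origin)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.tags)

    def __len__(self) -> int:
        return len(self.tags)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a TSV with columns template_id, target_id, origin."""
    omap = OrthologMap()
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        template, target, origin = line.rstrip("\n").split("\t")[:3]
        omap.add(template, target, origin)
    return omap


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("template_id\ttarget_id\torigin\n")
        for (template, target), tags in sorted(omap.tags.items()):
            for origin in sorted(tags):
                fh.write(f"{template}\t{target}\t{origin}\n")


def build_ortholog_set(omap: OrthologMap) -> set[tuple[str, str]]:
    """Seed orthologs plus method1/method2 consensus pairs.

    Pairs tagged only ``method2`` or only non-seed ``method1_all`` are
    excluded.
    """
    out: set[tuple[str, str]] = set()
    for pair, tags in omap.tags.items():
        if "method1_seed" in tags:
            out.add(pair)
        elif "method1_all" in tags and "method2" in tags:
            out.add(pair)
    return out


def map_interologs(
    template_net: InteractionNetwork, orth: Iterable[tuple[str, str]]
) -> InteractionNetwork:
    """Transfer every template edge to all target ortholog combinations.

    For a template edge (a, b), every (x, y) with (a, x) and (b, y) in the
    ortholog set becomes a target edge. The result is canonicalized: reversed
    duplicates collapse, would-be self-loops (heteromeric template pairs whose
    orthologs coincide) are dropped and counted. Each kept edge records its
    originating template edge(s) under ``template_edge``.
    """
    targets_of: dict[str, set[str]] = {}
    for template, target in orth:
        targets_of.setdefault(template, set()).add(target)
    out = InteractionNetwork()
    for a, b in sorted(template_net.edges):
        for x in sorted(targets_of.get(a, ())):
            for y in sorted(targets_of.get(b, ())):
                out.add_edge(x, y, template_edge=(a, b))
    return out
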