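#!/usr/bin/env python
"""Reconstruct the interactome: ortholog-set rule, interolog transfer, and
the three pruning filters.

Reads the bundle written by 01_simulate.py, builds the combined ortholog set
(method-1 seeds plus method-1/method-2 consensus), transfers template edges,
applies the DDI, co-localization and isoform filters, and writes the four
networks plus the compartment-pair count matrix.
"""

import json
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from antnet.interolog_transfer import build_ortholog_set, map_interologs, read_ortholog_map
from antnet.io_formats import read_annotations, read_ddi_reference, read_network, write_network
from antnet.ppi_filters import apply_all_filters, localization_pair_matrix

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = BASE / "bundle"
    template = read_network(bundle / "template_network.tsv")
    omap = read_ortholog_map(bundle / "ortholog_map.tsv")
    ann = read_annotations({
        name: bundle / f"{name}.tsv"
        for name in ("domains", "localizations", "isoforms", "go", "expression", "orthologs")
        if (bundle / f"{name}.tsv").exists()
    })
    ddi = read_ddi_reference(bundle / "ddi_reference.tsv")

    orth = build_ortholog_set(omap)
    print(f"combined ortholog set: {len(orth)} of {len(omap)} predicted pairs kept")
    preliminary = map_interologs(template, orth)
    print(f"interolog transfer: {preliminary.n_edges()} edges "
          f"({preliminary.dropped_self_loops} would-be self-loops dropped)")

    nets = apply_all_filters(preliminary, ann, ddi)
    counts = {}
    for name in ("preliminary", "ddi", "localization", "final"):
        write_network(nets[name], BASE / f"network_{name}.tsv")
        counts[name] = {"n_nodes": nets[name].n_nodes(), "n_edges": nets[name].n_edges()}
        print(f"  {name:<12} {counts[name]['n_nodes']:>5} nodes  "
              f"{counts[name]['n_edges']:>5} edges")
    mat = localization_pair_matrix(nets["localization"], ann)
    mat.counts.to_csv(BASE / "localization_matrix.tsv", sep="\t")
    (BASE / "network_counts.json").write_text(json.dumps(counts, indent=2))
    print(f"compartment-pair matrix and per-stage counts written to {BASE}")


if __name__ == "__main__":
    main()
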