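#!/usr/bin/env python
"""Topology of the final network: global statistics, betweenness centrality,
hubs (degree >= 5), bottlenecks (top 20% betweenness), multi-localization
enrichment of both groups, and the expression/ortholog overlay table.
"""

import json
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from antnet.io_formats import read_annotations, read_network
from antnet.topology_analysis import (
    betweenness,
    identify_bottlenecks,
    identify_hubs,
    multiloc_enrichment,
    overlay_expression,
    summarize_topology,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    net = read_network(BASE / "network_final.tsv")
    bundle = BASE / "bundle"
    ann = read_annotations({
        name: bundle / f"{name}.tsv"
        for name in ("localizations", "expression", "orthologs")
        if (bundle / f"{name}.tsv").exists()
    })

    s = summarize_topology(net)
    print(f"final network: {s.n_nodes} nodes, {s.n_edges} edges, "
          f"avg degree {s.avg_degree:.3f}")
    print(f"clustering coefficient {s.clustering_coefficient:.3f}, "
          f"mean shortest path {s.mean_shortest_path:.3f}, diameter {s.diameter}")
    (BASE / "topology_summary.json").write_text(json.dumps(s.as_dict(), indent=2))

    bc = betweenness(net)
    with (BASE / "centrality.tsv").open("w") as fh:
        fh.write("protein\tdegree\tbetweenness\n")
        for n in sorted(bc.bc, key=lambda x: -bc.bc[x]):
            fh.write(f"{n}\t{bc.degree[n]}\t{bc.bc[n]:.4f}\n")

    hubs = identify_hubs(net, min_degree=5)
    bottlenecks = identify_bottlenecks(bc, top_fraction=0.2)
    print(f"{len(hubs)} hubs (degree >= 5), {len(bottlenecks)} bottlenecks (top 20% BC)")
    for label, group in (("hubs", hubs), ("bottlenecks", bottlenecks)):
        if not group:
            continue
        rec = multiloc_enrichment(group, net, ann)
        print(f"  {label}: {rec.group_fraction:.0%} multi-localized vs "
              f"{rec.complement_fraction:.0%} elsewhere (Fisher p={rec.p_value:.3g})")
    overlay_expression(hubs | bottlenecks, ann).to_csv(
        BASE / "expression_overlay.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
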