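#!/usr/bin/env python
"""Functional validation: GO enrichment of the final network against the
full annotated background, and semantic-similarity separation of interacting
pairs from 30 random non-interacting pair sets.

Annotations are truncated to level-4 molecular-function terms first; the
non-interacting sets avoid every pair of the preliminary interactome.
"""

import json
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from antnet.functional_semantics import (
    build_nonppi_sets,
    compare_ppi_vs_nonppi,
    go_enrichment,
    truncate_to_level,
)
from antnet.io_formats import read_annotations, read_go_dag, read_network

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 13


def main() -> None:
    bundle = BASE / "bundle"
    final = read_network(BASE / "network_final.tsv")
    preliminary = read_network(BASE / "network_preliminary.tsv")
    ann = read_annotations({"go": bundle / "go.tsv", "isoforms": bundle / "isoforms.tsv"})
    dag = read_go_dag(bundle / "go_dag.obo")
    level_ann = truncate_to_level(ann, dag, level=4)

    bg = set(level_ann.go_terms)
    fg = final.nodes & bg
    results = go_enrichment(fg, bg | final.nodes, level_ann)
    sig = [r for r in results if r.significant]
    print(f"GO enrichment: {len(results)} level-4 terms tested, "
          f"{len(sig)} significant at FDR < 0.05 "
          f"({sum(r.direction == 'over' for r in sig)} over-represented)")
    with (BASE / "enrichment.tsv").open("w") as fh:
        fh.write("term\tfg_count\tfg_total\tbg_count\tbg_total\todds_ratio\tp\tfdr\tdirection\n")
        for r in sorted(results, key=lambda r: r.fdr):
            fh.write(f"{r.term}\t{r.fg_count}\t{r.fg_total}\t{r.bg_count}\t{r.bg_total}\t"
                     f"{r.odds_ratio:.4g}\t{r.p:.4g}\t{r.fdr:.4g}\t{r.direction}\n")

    annotated = set(level_ann.go_terms)
    ppi = {e for e in final.edges if e[0] in annotated and e[1] in annotated}
    nonppi = build_nonppi_sets(annotated, preliminary.edges, n_sets=30, set_size=100, seed=SEED)
    comp = compare_ppi_vs_nonppi(ppi, nonppi, level_ann, dag)
    n_sig = sum(1 for p in comp.p_values if p < 0.05)
    print(f"semantic similarity: PPI mean {comp.ppi_mean:.3f} over {len(comp.ppi_scores)} pairs; "
          f"non-PPI set means {min(comp.nonppi_means):.3f}-{max(comp.nonppi_means):.3f}; "
          f"{n_sig}/30 sets significantly lower (Mann-Whitney p < 0.05)")
    (BASE / "semantic_similarity.json").write_text(json.dumps({
        "ppi_mean": comp.ppi_mean,
        "nonppi_means": comp.nonppi_means,
        "p_values": comp.p_values,
        "n_unscored_ppi": comp.n_unscored_ppi,
    }, indent=2))


if __name__ == "__main__":
    main()
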