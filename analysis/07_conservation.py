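#!/usr/bin/env python
"""Cross-species conservation of the final network's proteins.

Conservation-by-degree profiles (exact and cumulative binning) with Spearman
correlations per species, interactome-vs-proteome ortholog-composition
chi-square tests, species-set membership counts and the lineage-specific
protein set.
"""

import json
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from antnet.conservation_analysis import (
    conservation_by_degree,
    interactome_vs_proteome_chisq,
    species_set_counts,
)
from antnet.io_formats import read_annotations, read_network

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = BASE / "bundle"
    final = read_network(BASE / "network_final.tsv")
    ann = read_annotations({"orthologs": bundle / "orthologs.tsv"})

    rows = []
    print("conservation by degree (exact binning):")
    for sp in ann.species:
        for mode in ("exact", "cumulative"):
            prof = conservation_by_degree(final, ann, sp, mode=mode)
            for _, r in prof.table.iterrows():
                rows.append((sp, mode, int(r.degree), int(r.n_proteins),
                             int(r.n_with_ortholog), f"{r.fraction:.4f}"))
            if mode == "exact":
                r_txt = f"{prof.spearman_r:.3f} (p={prof.spearman_p:.2g})" \
                    if prof.spearman_r is not None else "undefined"
                print(f"  {sp:<12} Spearman r = {r_txt}")
    with (BASE / "conservation.tsv").open("w") as fh:
        fh.write("species\tmode\tdegree\tn_proteins\tn_with_ortholog\tfraction\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    # interactome vs whole annotated gene set, per species
    all_genes = set(ann.ortholog_in)
    print("interactome vs full gene set (Yates chi-square):")
    for sp in ann.species:
        i_orth = sum(1 for n in final.nodes if ann.has_ortholog(n, sp))
        p_orth = sum(1 for g in all_genes if ann.has_ortholog(g, sp))
        rec = interactome_vs_proteome_chisq(i_orth, final.n_nodes(), p_orth, len(all_genes))
        print(f"  {sp:<12} X2={rec.statistic:8.3f}  p={rec.p_value:.3g}")

    counts = species_set_counts(final, ann)
    print("species-set counts:", dict(sorted(counts.counts.items())))
    print(f"{len(counts.ant_specific)} proteins "
          f"({len(counts.ant_specific) / final.n_nodes():.1%}) are lineage-specific")
    (BASE / "species_set_counts.json").write_text(json.dumps({
        "counts": {str(k): v for k, v in sorted(counts.counts.items())},
        "n_lineage_specific": len(counts.ant_specific),
    }, indent=2))


if __name__ == "__main__":
    main()
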