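"""Recompute published network statistics from the article's supplementary
datasheets, when a user supplies them.

The four reconstructed networks and the ortholog table are distributed as
supplementary downloads of the original study and are not shipped with this
package. Export them as TSV/SIF edge lists and tables into one directory
(column names are sniffed case-insensitively) and this module recomputes the
printed statistics: topology of the localization-supported network,
conservation-by-degree counts, the lineage-specific protein count and the
confidence-band split.
"""

from __future__ import annotations

from pathlib import Path

from .confidence_scoring import band_proportions, mcl_cluster, score_interactions
from .conservation_analysis import conservation_by_degree, species_set_counts
from .io_formats import AnnotationSet, read_annotations, read_network
from .topology_analysis import summarize_topology

LOCALIZATION_NETWORK_CANDIDATES = (
    "localization_network.tsv",
    "network_localization.tsv",
    "dataset3.tsv",
)
ORTHOLOG_TABLE_CANDIDATES = ("orthologs.tsv", "ortholog_table.tsv", "dataset7.tsv")


def find_input(directory: Path, candidates: tuple[str, ...]) -> Path | None:
    for name in candidates:
        for existing in directory.glob("*"):
            if existing.name.lower() == name:
                return existing
    return None


def run_supplementary_benchmarks(directory: str | Path) -> dict:
    """Compute every statistic the supplied tables allow; raises
    FileNotFoundError when the directory or the network table is missing."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no supplementary data directory at {directory}")
    net_path = find_input(directory, LOCALIZATION_NETWORK_CANDIDATES)
    if net_path is None:
        raise FileNotFoundError(
            f"no localization-supported network table found in {directory} "
            f"(looked for {', '.join(LOCALIZATION_NETWORK_CANDIDATES)})"
        )
    out: dict = {}
    net = read_network(net_path)
    summary = summarize_topology(net)
    out["topology"] = {
        "n_nodes": summary.n_nodes,
        "n_edges": summary.n_edges,
        "avg_degree": summary.avg_degree,
        "clustering_coefficient": summary.clustering_coefficient,
        "mean_shortest_path": summary.mean_shortest_path,
        "diameter": summary.diameter,
    }
    orth_path = find_input(directory, ORTHOLOG_TABLE_CANDIDATES)
    if orth_path is not None:
        ann = read_annotations({"orthologs": orth_path})
        counts = species_set_counts(net, ann)
        out["n_lineage_specific"] = len(counts.ant_specific)
        out["conservation"] = {}
        for sp in ann.species:
            prof = conservation_by_degree(net, ann, sp, mode="exact")
            row = prof.table[prof.table.degree == 2]
            out["conservation"][sp] = {
                "spearman_r": prof.spearman_r,
                "degree2_n": int(row.n_proteins.iloc[0]) if len(row) else None,
                "degree2_orthologs": int(row.n_with_ortholog.iloc[0]) if len(row) else None,
            }
    clustering = mcl_cluster(net, inflation=1.5)
    scores = score_interactions(net, clustering)
    out["band_proportions"] = band_proportions(scores)
    return out
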