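#!/usr/bin/env python
"""Confidence scoring and network-quality comparison across the four stages.

Runs Markov clustering (inflation 1.5) plus the cluster/neighborhood blend
score on every stage network, reports the low/medium/high band split, and
compares stages with Mann-Whitney (score distributions) and Fisher (band
membership) tests — the quality trend the successive filters should produce.
"""

import json
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from antnet.confidence_scoring import (
    band_density_table,
    band_proportions,
    compare_band_counts,
    compare_score_distributions,
    mcl_cluster,
    score_interactions,
)
from antnet.io_formats import read_network, write_network

BASE = Path(__file__).resolve().parent.parent / "results"
STAGES = ("preliminary", "ddi", "localization", "final")


def main() -> None:
    scored = {}
    report = {}
    for name in STAGES:
        net = read_network(BASE / f"network_{name}.tsv")
        clustering = mcl_cluster(net, inflation=1.5)
        scores = score_interactions(net, clustering, lambda_mix=0.5)
        scored[name] = scores
        props = band_proportions(scores)
        report[name] = {b: round(p, 4) for b, p in props.items()}
        print(f"{name:<12} {clustering.n_clusters():>4} clusters | "
              + "  ".join(f"{b}={props[b]:.1%}" for b in ("low", "medium", "high")))
        if name == "final":
            write_network(net, BASE / "network_final_scored.tsv")
            band_density_table(scores).to_csv(BASE / "band_densities.tsv", sep="\t", index=False)

    mw = compare_score_distributions(scored["preliminary"], scored["final"])
    fisher_high = compare_band_counts(scored["final"], scored["preliminary"], "high")
    fisher_low = compare_band_counts(scored["final"], scored["preliminary"], "low")
    print(f"Mann-Whitney preliminary vs final: U={mw.u_statistic:.0f}, p={mw.p_value:.3g}")
    print(f"Fisher high-band final vs preliminary: OR={fisher_high.odds_ratio:.2f}, "
          f"p={fisher_high.p_value:.3g}")
    print(f"Fisher low-band final vs preliminary: OR={fisher_low.odds_ratio:.2f}, "
          f"p={fisher_low.p_value:.3g}")
    report["tests"] = {
        "mannwhitney_preliminary_vs_final_p": mw.p_value,
        "fisher_high_band_p": fisher_high.p_value,
        "fisher_low_band_p": fisher_low.p_value,
    }
    (BASE / "confidence_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
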