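"""Evolutionary-conservation analyses of interactome proteins.

Conservation-by-degree profiles relate a protein's connectivity to whether it
has an ortholog in a given model species; two binning rules are provided:
``exact`` (proteins of exactly degree d) and ``cumulative`` (degree >= d, the
fraction-of-the-tail rule). Composition of the interactome's ortholog
complement versus the whole proteome is tested with a Yates-corrected
chi-square, and species-set counts partition proteins by how many species
carry an ortholog (zero = lineage-specific).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import chi2_contingency, spearmanr

from .io_formats import AnnotationSet, InteractionNetwork


@dataclass
class ConservationProfile:
    species: str
    binning_mode: str
    table: pd.DataFrame  # columns: degree, n_proteins, n_with_ortholog, fraction
    spearman_r: float | None
    spearman_p: float | None


def conservation_by_degree(
    net: InteractionNetwork,
    ann: AnnotationSet,
    species: str,
    mode: str = "exact",
    min_bin_size: int = 0,
) -> ConservationProfile:
    """Per-degree ortholog fractions plus a Spearman rank correlation of
    (degree, fraction).

    ``exact``: fraction = orthologous proteins of degree d / proteins of
    degree d. ``cumulative``: both counts over degree >= d. Degree bins with
    fewer than ``min_bin_size`` proteins are excluded from the correlation
    (0/1-noisy singleton bins). A constant fraction sequence leaves the
    correlation undefined (None)."""
    if species not in ann.species:
        raise ValueError(f"unknown species: {species!r}")
    if mode not in ("exact", "cumulative"):
        raise ValueError(f"unknown binning mode: {mode!r}")
    degree_of = {n: net.graph.degree[n] for n in net.nodes}
    degrees = sorted(set(degree_of.values()))
    rows = []
    for d in degrees:
        if mode == "exact":
            members = [n for n, dd in degree_of.items() if dd == d]
        else:
            members = [n for n, dd in degree_of.items() if dd >= d]
        n_orth = sum(1 for n in members if ann.has_ortholog(n, species))
        rows.append(
            {
                "degree": d,
                "n_proteins": len(members),
                "n_with_ortholog": n_orth,
                "fraction": n_orth / len(members) if members else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    corr_rows = table[table["n_proteins"] >= min_bin_size]
    r = p = None
    if len(corr_rows) >= 2 and corr_rows["fraction"].nunique() > 1:
        res = spearmanr(corr_rows["degree"], corr_rows["fraction"])
        r, p = float(res.statistic), float(res.pvalue)
    return ConservationProfile(species, mode, table, r, p)


@dataclass
class ChiSquareRecord:
    statistic: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def interactome_vs_proteome_chisq(
    interactome_orthologs: int,
    interactome_total: int,
    proteome_orthologs: int,
    proteome_total: int,
) -> ChiSquareRecord:
    """Yates-corrected 2x2 chi-square of ortholog composition: interactome
    proteins vs the whole proteome."""
    if interactome_orthologs > interactome_total or proteome_orthologs > proteome_total:
        raise ValueError("counts exceed totals")
    table = (
        (interactome_orthologs, interactome_total - interactome_orthologs),
        (proteome_orthologs, proteome_total - proteome_orthologs),
    )
    for row in table:
        if sum(row) == 0:
            raise ValueError("zero marginal in contingency table")
    for j in range(2):
        if table[0][j] + table[1][j] == 0:
            raise ValueError("zero marginal in contingency table")
    stat, p, _, _ = chi2_contingency(table, correction=True)
    return ChiSquareRecord(float(stat), float(p), table)


@dataclass
class SpeciesSetCounts:
    counts: dict[int, int] = field(default_factory=dict)
    ant_specific: set[str] = field(default_factory=set)


def species_set_counts(net: InteractionNetwork, ann: AnnotationSet) -> SpeciesSetCounts:
    """Partition interactome proteins by the number of species carrying an
    ortholog; proteins with no ortholog anywhere are the lineage-specific
    set."""
    out = SpeciesSetCounts()
    for n in net.nodes:
        k = ann.n_species_with_ortholog(n)
        out.counts[k] = out.counts.get(k, 0) + 1
        if k == 0:
            out.ant_specific.add(n)
    return out
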