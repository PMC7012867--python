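"""Seeded synthetic input bundles with planted ground truth.

The generator emulates every input the reconstruction pipeline consumes — a
template PPI network, two-method orthology tables, Pfam-style domain
assignments with a DDI reference, multi-compartment localizations, isoform
groups, a small GO DAG with annotations, per-species ortholog flags and
log2FC values — and records, per mapped target edge, whether it was planted
to survive the DDI and co-localization filters.

Two planting mechanisms make truth recovery exact rather than statistical:

* DDI support: every target protein carries one private domain; a planted
  supported edge contributes its endpoints' private-domain pair to the
  reference list. Shared decoy domains are assigned but never entered in the
  reference, so filter outcome == planted label, edge by edge.
* Co-localization: per-edge pass labels are drawn i.i.d. Bernoulli(p_coloc)
  and compartment sets are then built by constrained greedy coloring — each
  pass edge receives a compartment shared by its endpoints, chosen so that no
  fail edge's endpoints ever share one. When the declared vocabulary has no
  feasible color left an overflow label is minted (counted; rare at default
  sizes).

Survival counts after each filter are therefore binomially distributed with
the configured rates, independently by construction, so the closed-form
expectations of :func:`expected_survival` factorize.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .interolog_transfer import OrthologMap, build_ortholog_set, map_interologs, write_ortholog_map
from .io_formats import (
    AnnotationSet,
    DdiReference,
    GoDag,
    InteractionNetwork,
    canonical_pair,
    write_annotations,
    write_ddi_reference,
    write_go_dag,
    write_network,
)

COMPARTMENT_VOCABULARY = (
    "cytoplasm",
    "nucleus",
    "plasma_membrane",
    "mitochondrion",
    "golgi_apparatus",
    "endoplasmic_reticulum",
    "cytoskeleton",
    "extracellular",
    "peroxisome",
    "lysosome",
)

SPECIES_PANEL = (
    "anopheles",
    "arabidopsis",
    "celegans",
    "human",
    "mouse",
    "plasmodium",
    "yeast",
)


class ConfigError(ValueError):
    """An infeasible or invalid scenario configuration."""


@dataclass
class ScenarioConfig:
    """Generator parameters; defaults give a desk-scale scenario whose filter
    survival rates match the reconstruction's observed ones (~0.40 of mapped
    edges DDI-supported, ~0.66 of those co-localized)."""

    n_template_proteins: int = 500
    n_template_edges: int = 1500
    template_model: str = "planted_partition"  # or barabasi_albert / erdos_renyi
    n_modules: int = 8
    intra_module_edge_fraction: float = 0.9
    ortholog_coverage: float = 0.8
    multi_ortholog_rate: float = 0.15
    seed_fraction: float = 0.6
    consensus_fraction: float = 0.7
    p_ddi_support: float = 0.4
    p_coloc: float = 0.66
    n_compartments: int = 10
    multi_loc_rate: float = 0.5
    isoform_rate: float = 0.1
    n_go_terms: int = 200
    go_depth: int = 6
    go_terms_per_protein: int = 3
    n_species: int = 7
    lineage_specific_rate: float = 0.06
    rng_seed: int = 42

    def validate(self) -> None:
        for name in (
            "ortholog_coverage", "multi_ortholog_rate", "seed_fraction",
            "consensus_fraction", "p_ddi_support", "p_coloc",
            "multi_loc_rate", "isoform_rate", "intra_module_edge_fraction",
            "lineage_specific_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_template_proteins", "n_template_edges", "n_compartments",
            "n_go_terms", "go_depth", "n_species", "n_modules",
            "go_terms_per_protein",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        n = self.n_template_proteins
        if self.n_template_edges > n * (n - 1) // 2:
            raise ConfigError("n_template_edges exceeds n(n-1)/2")
        if self.template_model not in ("planted_partition", "barabasi_albert", "erdos_renyi"):
            raise ConfigError(f"unknown template model: {self.template_model!r}")
        if self.n_species > len(SPECIES_PANEL):
            raise ConfigError(f"at most {len(SPECIES_PANEL)} species supported")


@dataclass
class PlantedTruth:
    """Per-mapped-edge survival labels and planted module memberships."""

    ddi_pass: dict[tuple[str, str], bool] = field(default_factory=dict)
    loc_pass: dict[tuple[str, str], bool] = field(default_factory=dict)
    module_of: dict[str, int] = field(default_factory=dict)  # gene -> module
    overflow_compartments: int = 0


@dataclass
class SyntheticBundle:
    config: ScenarioConfig
    template_network: InteractionNetwork
    ortholog_map: OrthologMap
    annotations: AnnotationSet
    ddi_ref: DdiReference
    go_dag: GoDag
    truth: PlantedTruth
    mapped_network: InteractionNetwork


# ---------------------------------------------------------------------------


def _template_network(cfg: ScenarioConfig, rng: random.Random) -> tuple[InteractionNetwork, dict[str, int]]:
    n, e = cfg.n_template_proteins, cfg.n_template_edges
    names = [f"T{i:05d}" for i in range(n)]
    module_of_template: dict[str, int] = {}
    net = InteractionNetwork()
    for name in names:
        net.add_node(name)
    seed = rng.randrange(2**31)
    if cfg.template_model == "erdos_renyi":
        g = nx.gnm_random_graph(n, e, seed=seed)
        for a, b in g.edges:
            net.add_edge(names[a], names[b])
        for name in names:
            module_of_template[name] = 0
    elif cfg.template_model == "barabasi_albert":
        m = max(1, round(e / n))
        g = nx.barabasi_albert_graph(n, m, seed=seed)
        for a, b in g.edges:
            net.add_edge(names[a], names[b])
        for name in names:
            module_of_template[name] = 0
    else:  # planted partition: dense modules plus sparse inter-module noise
        k = cfg.n_modules
        for i, name in enumerate(names):
            module_of_template[name] = i % k
        members: dict[int, list[str]] = {}
        for name, mod in module_of_template.items():
            members.setdefault(mod, []).append(name)
        n_intra = round(e * cfg.intra_module_edge_fraction)
        local = random.Random(seed)
        added = 0
        guard = 0
        while added < n_intra and guard < 50 * e:
            guard += 1
            mod = local.randrange(k)
            grp = members[mod]
            if len(grp) < 2:
                continue
            a, b = local.sample(grp, 2)
            if not net.has_edge(a, b):
                net.add_edge(a, b)
                added += 1
        while added < e and guard < 100 * e:
            guard += 1
            a, b = local.sample(names, 2)
            if module_of_template[a] == module_of_template[b]:
                continue
            if not net.has_edge(a, b):
                net.add_edge(a, b)
                added += 1
    return net, module_of_template


def _orthology(
    cfg: ScenarioConfig, template_names: list[str], rng: random.Random
) -> tuple[OrthologMap, dict[str, str], dict[str, str]]:
    """Returns (ortholog map, gene_of for isoform proteins, gene -> template)."""
    omap = OrthologMap()
    gene_of: dict[str, str] = {}
    template_of_gene: dict[str, str] = {}
    gene_counter = 0
    for tname in template_names:
        if rng.random() >= cfg.ortholog_coverage:
            continue
        n_genes = 1 + (1 if rng.random() < cfg.multi_ortholog_rate else 0)
        for _ in range(n_genes):
            gene = f"G{gene_counter:05d}"
            gene_counter += 1
            template_of_gene[gene] = tname
            if rng.random() < cfg.isoform_rate:
                proteins = [f"{gene}.1", f"{gene}.2"]
                for p in proteins:
                    gene_of[p] = gene
            else:
                proteins = [gene]
            # one origin-tag draw per (template, gene); isoforms share it
            u = rng.random()
            if u < cfg.seed_fraction:
                tags = ("method1_seed", "method1_all")
            elif u < cfg.seed_fraction + (1 - cfg.seed_fraction) * cfg.consensus_fraction:
                tags = ("method1_all", "method2")
            else:  # excluded from the combined set
                tags = ("method1_all",) if rng.random() < 0.5 else ("method2",)
            for p in proteins:
                for tag in tags:
                    omap.add(tname, p, tag)
    return omap, gene_of, template_of_gene


def _plant_localizations(
    cfg: ScenarioConfig,
    mapped: InteractionNetwork,
    rng: random.Random,
    truth: PlantedTruth,
) -> dict[str, set[str]]:
    vocab = list(COMPARTMENT_VOCABULARY[: cfg.n_compartments])
    while len(vocab) < cfg.n_compartments:
        vocab.append(f"compartment_{len(vocab):02d}")
    loc: dict[str, set[str]] = {}
    fail_neighbors: dict[str, set[str]] = {}
    pass_edges: list[tuple[str, str]] = []
    for edge in sorted(mapped.edges):
        if truth.loc_pass[edge]:
            pass_edges.append(edge)
        else:
            u, v = edge
            fail_neighbors.setdefault(u, set()).add(v)
            fail_neighbors.setdefault(v, set()).add(u)

    def forbidden_for(protein: str) -> set[str]:
        out: set[str] = set()
        for w in fail_neighbors.get(protein, ()):  # no fail edge may share
            out |= loc.get(w, set())
        return out

    def pick_color(forbidden: set[str]) -> str:
        feasible = [c for c in vocab if c not in forbidden]
        if feasible:
            return rng.choice(feasible)
        truth.overflow_compartments += 1
        return f"compartment_overflow_{truth.overflow_compartments:03d}"

    rng.shuffle(pass_edges)
    for u, v in pass_edges:
        shared = loc.get(u, set()) & loc.get(v, set())
        if shared:
            continue  # already co-localized through an earlier pass edge
        c = pick_color(forbidden_for(u) | forbidden_for(v))
        loc.setdefault(u, set()).add(c)
        loc.setdefault(v, set()).add(c)
    # fail-only proteins still need a (non-"other") compartment so the
    # other-matches-other rule cannot resurrect a planted-fail edge
    for protein in sorted(fail_neighbors):
        if not loc.get(protein):
            loc[protein] = {pick_color(forbidden_for(protein))}
    # optional second compartments (multi-localized proteins), constraint-checked
    for protein in sorted(mapped.nodes):
        if protein in loc and rng.random() < cfg.multi_loc_rate:
            forb = forbidden_for(protein) | loc[protein]
            feasible = [c for c in vocab if c not in forb]
            if feasible:
                loc[protein].add(rng.choice(feasible))
    return loc


def _go_dag(cfg: ScenarioConfig, rng: random.Random) -> tuple[GoDag, dict[str, int]]:
    """Random rooted is_a tree plus sparse extra is_a edges; returns the DAG
    and each term's tree depth."""
    dag = GoDag()
    root = "GO:0000001"
    dag.add_term(root)
    dag.roots["molecular_function"] = root
    depth_of = {root: 0}
    terms = [root]
    counter = 2
    while len(terms) < cfg.n_go_terms:
        eligible = [t for t in terms if depth_of[t] < cfg.go_depth]
        parent = rng.choice(eligible)
        term = f"GO:{counter:07d}"
        counter += 1
        dag.add_term(term)
        dag.add_parent(term, parent, "is_a")
        depth_of[term] = depth_of[parent] + 1
        terms.append(term)
    # sparse extra edges to strictly shallower terms keep the graph acyclic
    for term in terms:
        if depth_of[term] >= 2 and rng.random() < 0.1:
            shallower = [t for t in terms if depth_of[t] < depth_of[term] - 1]
            if shallower:
                rel = "is_a" if rng.random() < 0.7 else "part_of"
                dag.add_parent(term, rng.choice(shallower), rel)
    return dag, depth_of


def generate_bundle(config: ScenarioConfig) -> SyntheticBundle:
    """Deterministically generate a complete input bundle from a scenario."""
    config.validate()
    rng = random.Random(config.rng_seed)
    template_net, module_of_template = _template_network(config, rng)
    template_names = sorted(template_net.nodes)
    omap, gene_of, template_of_gene = _orthology(config, template_names, rng)

    included = build_ortholog_set(omap)
    mapped = map_interologs(template_net, included)

    truth = PlantedTruth()
    for gene, tname in template_of_gene.items():
        truth.module_of[gene] = module_of_template[tname]

    ann = AnnotationSet(species=SPECIES_PANEL[: config.n_species])
    ann.gene_of.update(gene_of)

    # --- per-edge survival labels ------------------------------------------
    for edge in sorted(mapped.edges):
        truth.ddi_pass[edge] = rng.random() < config.p_ddi_support
        truth.loc_pass[edge] = rng.random() < config.p_coloc

    # --- domains + DDI reference (private-domain mechanism) ----------------
    ddi_ref = DdiReference()
    all_proteins = sorted(
        {p for _, p in omap.pairs} | set(gene_of) | set(template_of_gene)
    )
    private: dict[str, str] = {}
    for i, protein in enumerate(all_proteins):
        private[protein] = f"PF9{i:04d}"
        ann.domains[protein] = {private[protein]}
        for _ in range(rng.randint(0, 2)):  # shared decoys, never in the reference
            ann.domains[protein].add(f"PF1{rng.randrange(50):03d}")
    for edge, supported in truth.ddi_pass.items():
        if supported:
            ddi_ref.add(private[edge[0]], private[edge[1]])
    for _ in range(30):  # decoy reference pairs over never-assigned families
        ddi_ref.add(f"PF8{rng.randrange(500):04d}", f"PF8{rng.randrange(500):04d}")

    # --- localizations ------------------------------------------------------
    ann.localizations.update(_plant_localizations(config, mapped, rng, truth))

    # --- GO DAG + annotations ----------------------------------------------
    dag, depth_of = _go_dag(config, rng)
    deep_terms = sorted(t for t, d in depth_of.items() if d >= min(3, config.go_depth))
    n_modules = max(truth.module_of.values(), default=0) + 1
    module_pool: dict[int, list[str]] = {}
    if deep_terms:
        shuffled = deep_terms[:]
        rng.shuffle(shuffled)
        chunk = max(3, len(shuffled) // max(n_modules, 1))
        for m in range(n_modules):
            pool = shuffled[m * chunk : (m + 1) * chunk]
            module_pool[m] = pool if pool else shuffled
    for gene in sorted(template_of_gene):
        pool = module_pool.get(truth.module_of.get(gene, 0)) or deep_terms
        k = min(config.go_terms_per_protein, len(pool))
        terms = set(rng.sample(pool, k))
        if deep_terms and rng.random() < 0.3:  # cross-module noise term
            terms.add(rng.choice(deep_terms))
        ann.go_terms[gene] = terms
        for protein, g in gene_of.items():
            if g == gene:
                ann.go_terms[protein] = set(terms)

    # --- expression + ortholog flags ---------------------------------------
    for gene in sorted(template_of_gene):
        if rng.random() < 0.6:
            ann.log2fc[gene] = rng.gauss(0.0, 1.5)
    base_rates = [0.75, 0.35, 0.55, 0.7, 0.68, 0.25, 0.4]
    gene_degree: dict[str, int] = {}
    for node in mapped.nodes:
        gene = ann.gene(node)
        gene_degree[gene] = gene_degree.get(gene, 0) + mapped.graph.degree[node]
    for gene in sorted(template_of_gene):
        d = gene_degree.get(gene, 0)
        lineage_specific = rng.random() < config.lineage_specific_rate
        flags = {}
        for s_idx, sp in enumerate(ann.species):
            b = base_rates[s_idx % len(base_rates)]
            p = b + (1 - b) * (1 - math.exp(-0.08 * d))  # conservation grows with degree
            flags[sp] = (not lineage_specific) and rng.random() < p
        ann.ortholog_in[gene] = flags
        for protein, g in gene_of.items():
            if g == gene:
                ann.ortholog_in[protein] = dict(flags)

    return SyntheticBundle(
        config=config,
        template_network=template_net,
        ortholog_map=omap,
        annotations=ann,
        ddi_ref=ddi_ref,
        go_dag=dag,
        truth=truth,
        mapped_network=mapped,
    )


def expected_survival(config: ScenarioConfig, mapped: int | None = None) -> dict[str, float]:
    """Closed-form expected edge counts after each filter.

    With ``mapped`` given, the DDI/co-localization expectations condition on
    that mapped-edge count; otherwise the mapped count itself is approximated
    from the orthology parameters (per-endpoint expansion factor squared,
    ignoring collision dedup)."""
    config.validate()
    if mapped is None:
        p_incl = config.seed_fraction + (1 - config.seed_fraction) * config.consensus_fraction
        per_endpoint = (
            config.ortholog_coverage
            * p_incl
            * (1 + config.multi_ortholog_rate)
            * (1 + config.isoform_rate)
        )
        mapped_f = config.n_template_edges * per_endpoint**2
    else:
        mapped_f = float(mapped)
    after_ddi = mapped_f * config.p_ddi_support
    after_loc = after_ddi * config.p_coloc
    return {"mapped": mapped_f, "after_ddi": after_ddi, "after_loc": after_loc}


# ---------------------------------------------------------------------------


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the full bundle in the pipeline's on-disk schemas plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["template_network"] = outdir / "template_network.tsv"
    write_network(bundle.template_network, paths["template_network"])
    paths["orthologs"] = outdir / "ortholog_map.tsv"
    write_ortholog_map(bundle.ortholog_map, paths["orthologs"])
    paths.update(write_annotations(bundle.annotations, outdir))
    paths["ddi_reference"] = outdir / "ddi_reference.tsv"
    write_ddi_reference(bundle.ddi_ref, paths["ddi_reference"])
    paths["go_dag"] = outdir / "go_dag.obo"
    write_go_dag(bundle.go_dag, paths["go_dag"])
    truth_path = outdir / "truth.tsv"
    with truth_path.open("w", encoding="utf-8") as fh:
        fh.write("proteinA\tproteinB\tddi_pass\tloc_pass\n")
        for edge in sorted(bundle.truth.ddi_pass):
            a, b = edge
            fh.write(
                f"{a}\t{b}\t{int(bundle.truth.ddi_pass[edge])}\t{int(bundle.truth.loc_pass[edge])}\n"
            )
    paths["truth"] = truth_path
    return paths
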