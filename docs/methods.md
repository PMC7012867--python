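# Methods

`antnet` reconstructs a protein–protein interaction (PPI) network for a
target species by homology transfer and successive evidence-based pruning,
then validates the result with the standard battery used for inferred
interactomes: random-graph comparison, functional-coherence tests and
cross-species conservation. Because the full-scale reconstruction depends on
external interaction, domain and localization databases, the package ships a
synthetic-data generator whose bundles carry exact planted truth; every stage
is therefore testable end to end without any download.

## Reconstruction model

**Ortholog set.** Two orthology methods feed the transfer. Method 1
(InParanoid-style) distinguishes *seed* orthologs — reciprocal-best anchor
pairs — from co-orthologs; method 2 (OrthoMCL-style clustering) emits cluster
co-membership pairs. The combined set is: all method-1 seed pairs, plus pairs
supported by both methods. Pairs seen only by method 2, or only as non-seed
method-1 co-orthologs, are excluded. The rationale is precision: seeds are
the most reliable single-method calls, and two-method consensus substitutes
for seed status otherwise.

**Interolog transfer.** Each template edge (a, b) yields every target pair
(x, y) with x an accepted ortholog of a and y of b — the full cross-product,
as is conventional for interologs. The result is canonicalized: unordered
pairs stored once (lexicographically smaller ID first), reversed duplicates
merged, and would-be self-loops (heteromeric template pairs whose orthologs
coincide) dropped with a count. All downstream topology statistics assume a
simple graph, which is why self-loops are never admitted anywhere in the
pipeline. Template-edge provenance is kept per edge so redundancy remains
auditable.

**DDI filter.** An edge survives iff some pair of its endpoints' domain
families (homotypic pairs included) appears in the reference list of
interacting domain families. A protein with no domain assignment cannot
support any edge. Surviving edges carry `ddi_supported`; isolated nodes are
removed after each filter so per-stage node counts reflect interacting
proteins.

**Co-localization filter.** An edge survives iff the endpoints' predicted
compartment sets intersect; the shared compartments are recorded. Proteins
without a prediction carry the single pseudo-compartment `other`, and
`other` matches only `other`: absence of a prediction is not treated as
evidence of sharing, but two unpredicted proteins are not ruled out either
(they form their own row in the compartment-pair matrix). The compartment ×
compartment count matrix gives one contribution per compartment pair per
edge, so an edge between two doubly-localized proteins can increment up to
four cells; the diagonal counts edges sharing that compartment. The counting
convention for multi-localized proteins is not canonical across tools, so it
is fixed here and stated.

**Isoform merge.** Nodes are relabeled to their gene (identity where no
isoform mapping exists); parallel edges collapse with permissive attribute
merging (`ddi_supported` ORs, shared compartments union, provenance
accumulates) so the collapse never discards evidence, and isoform–isoform
edges drop as self-loops.

## Confidence scoring

Scoring follows the cluster-based confidence idea: interactions compatible
with the network's intrinsic modular structure are more credible. The
network is clustered with the Markov Cluster algorithm — self-loops of
weight 1 added (standard regularization), the adjacency matrix made
column-stochastic, then expansion (matrix squaring) alternating with
inflation (entrywise power, default 1.5, then column renormalization) until
the maximum entry change falls below 1e-6 (cap 200 iterations; entries below
1e-8 pruned to keep the matrix sparse). Clusters are read off attractor
rows, with overlapping attractor supports merged so the result is a
partition; the procedure is fully deterministic.

The published method this reconstructs states its two ingredients — module
co-membership and neighborhood interconnectedness — but not its exact
formula, so the score used here blends them explicitly:

    score(u, v) = λ·[cluster(u) = cluster(v)] + (1 − λ)·J(N[u], N[v])

with J the Jaccard index of closed neighborhoods and λ = 0.5 by default
(exposed as a parameter). Scores lie in [0, 1] and are banded low [0, 0.3) /
medium [0.3, 0.7) / high [0.7, 1]; boundary values go to the higher band
(the published banding gives only interval endpoints, so the boundary rule
is a logged, configurable constant). Because the formula is a
reconstruction, recovery of the published band split is treated as
approximate wherever it is compared. Stage-to-stage quality is compared with
a two-sided Mann–Whitney U on score distributions and two-sided Fisher exact
tests on band membership.

One caveat the demo run makes visible: on heavily filtered, sparse networks
many surviving components are tiny, and an isolated edge trivially scores 1
(its endpoints' closed neighborhoods coincide). The module-separation
property — intra-module edges outscoring inter-module noise edges — is
therefore asserted on the dense mapped network, where modular structure is
intact, not on the sparse final stage.

## Topology, hubs and bottlenecks

Global statistics follow the NetworkAnalyzer-style conventions: mean
shortest path and diameter over connected unordered pairs only; mean local
clustering with degree-<2 nodes contributing 0 (configurable, since tool
conventions vary); degree-distribution summarized by the least-squares slope
of log(count) vs log(degree) over non-empty bins. Betweenness centrality is
exact (Brandes accumulation), summed per unordered pair, with a flag for
ordered-pair doubling for cross-tool comparison; it is property-tested
against a brute-force all-shortest-paths oracle. Hubs are nodes of degree
≥ 5; bottlenecks the top 20% by betweenness, with boundary ties all
retained (determinism without arbitrary ID ordering). Multi-localization
(≥ 2 compartments) enrichment of either group uses a two-sided Fisher exact
test; the expression overlay reports absent log2FC values as missing, never
as zero.

## Random-graph comparison

Four reference ensembles are matched to the observed node and edge counts:
Erdős–Rényi G(n, m); Barabási–Albert with m = round(E/N) attachments per
node; Watts–Strogatz with ring degree k = 2·round(E/N) and rewiring
probability 0.1; and a degree-preserving double-edge swap of the observed
network (10·E swaps). For each model and metric (clustering coefficient,
mean shortest path, power-law slope as the degree-distribution scalar),
z = (observed − ensemble mean)/ensemble SD. The source study does not state
the BA/WS discretization, the rewiring probability, or the scalar used for
"degree distribution", so these edge-count-matched choices are package
defaults and the study's specific z values are not reproduction targets; the
self-consistency property (an ER graph scores |z| < 3 against its own
ensemble) is what is asserted.

## Functional validation

GO annotations are truncated to level 4 of the molecular-function namespace:
depth is the shortest is_a path from the namespace root (root depth 0, a
stated convention since "level" has no universal definition); deeper terms
are replaced by all their depth-4 ancestors, shallower terms kept.
Enrichment uses a per-term two-tailed Fisher exact test of foreground
(network proteins) against background, with Benjamini–Hochberg FDR across
terms and significance at FDR < 0.05; direction (over/under) is reported
separately from the two-tailed p.

Semantic similarity is a Wang-style graph measure: a term's S-value is 1 at
itself and decays multiplicatively through parent edges (is_a weight 0.8,
part_of weight 0.6, both configurable, taking the maximum over paths); a
term pair scores the shared-ancestor S-value mass relative to both semantic
totals; a protein pair scores the best-match average across both annotation
sets. It is symmetric, bounded in [0, 1], and exactly 1 on identical
annotation sets. The published analysis used the GOGO variant, whose exact
edge weighting is not reproduced here; the claim being validated —
interacting pairs are functionally closer than random pairs — is robust to
the weights. The comparison draws 30 random sets of 100 protein pairs from
annotated proteins, excluding every preliminary-network pair, and runs a
Mann–Whitney U of the interacting pairs' scores against each set;
unannotated pairs are excluded from aggregates and counted.

## Conservation

Conservation-by-degree supports two binning rules because the source
material uses both: *exact* (proteins of exactly degree d; used in the
worked degree-2 example) and *cumulative* (degree ≥ d, the stated
fraction-of-the-tail definition). Exact is the default for profile outputs
and both are emitted side by side. The profile's trend is summarized with a
Spearman rank correlation of (degree, fraction); constant fraction sequences
leave it undefined (reported as missing), and a minimum-bin-size flag
(default off) can exclude 0/1-noisy singleton bins. Interactome-vs-proteome
ortholog composition uses the 2×2 chi-square with Yates continuity
correction; species-set counts partition proteins by the number of species
with an ortholog, with the zero-species class reported as lineage-specific.

## Synthetic data: what is emulated, and what is not

The generator emulates the *inputs* of the reconstruction, not the biology
that produced them: a template network (Barabási–Albert, Erdős–Rényi, or a
planted-partition model with dense modules and sparse inter-module noise —
the latter is the default because module structure is what the confidence
score and the functional validation measure), many-to-many orthology with
tunable coverage (0.8), second-co-ortholog rate (0.15), seed fraction (0.6)
and two-method consensus fraction (0.7), two-isoform genes at rate 0.1, a
random rooted GO tree (200 terms, depth 6) with sparse extra is_a edges and
module-correlated annotations, per-species ortholog flags whose probability
rises with node degree (so conservation-by-degree has a planted positive
trend) with a 6% lineage-specific class, and log2FC values for 60% of genes.

Two mechanisms make filter truth exact rather than statistical. DDI: each
protein carries one private domain; a planted-supported edge contributes its
endpoints' private-domain pair to the reference, and shared decoy domains
are never entered there, so filter outcome equals the per-edge
Bernoulli(p_ddi = 0.4) draw exactly. Localization: per-edge
Bernoulli(p_coloc = 0.66) labels are drawn first, then compartments are
assigned by constrained greedy coloring — every pass edge gets a shared
compartment chosen so that no fail edge's endpoints ever share one, minting
an overflow label when the 10-compartment vocabulary is locally exhausted
(counted; a handful per default-size bundle). Fail-only proteins always
receive a real compartment so the `other`-matches-`other` rule cannot
resurrect a planted-fail edge. The two mechanisms are independent by
construction, so survival expectations factorize
(E[after_ddi] = mapped·p_ddi; E[after_loc] = mapped·p_ddi·p_coloc) and
observed counts are binomial around them. The default survival rates 0.4 and
0.66 mirror the stage-to-stage survival of the published reconstruction
(20544/51866 and 13640/20544).

What passing on synthetic bundles does *not* show: real orthology errors are
correlated with sequence divergence, real domain and localization evidence
are correlated with each other and with degree, real GO annotation is biased
toward studied proteins, and real interactomes are far larger (the demo
scenario is 500 template proteins). Synthetic results validate the
machinery's correctness and statistical behavior, not database-scale
biology.

## Numerical choices and degenerate inputs

- All randomness flows through Python's portable Mersenne Twister
  (`random.Random(seed)`) or seeded numpy `SeedSequence` spawns; identical
  seeds give byte-identical bundles across platforms. Derived seeds are kept
  below 2^31.
- MCL: convergence tolerance 1e-6, pruning 1e-8, self-loop weight 1;
  column sums are invariant to 1e-9 per iteration (property-tested).
- Empty networks are errors for summarization and clustering; empty files
  are valid empty networks for readers. Mann–Whitney/Fisher comparisons
  require non-empty inputs; an empty non-PPI set list yields means only.
- Zero ensemble SD in z-statistics reports signed infinity with a warning
  rather than raising (it legitimately occurs for e.g. tree-like BA
  ensembles whose clustering coefficient is identically 0).
- Problem sizes used by the shipped analyses and checks: demo scenario 500
  template proteins / 1500 edges; filter-survival recovery 20 seeds × 2000
  mapped edges; betweenness oracle checks on graphs of ≤ 40 nodes; random
  ensembles of 200 simulations per model.

## Known limitations

- The confidence formula is a reconstruction of a published method's stated
  ingredients, not its exact calibration; band splits are comparable only
  approximately.
- The level-depth convention, the compartment-matrix counting rule, and the
  bottleneck tie policy are all choices among defensible alternatives; each
  is a named, documented default.
- `expected_survival` approximates the mapped-edge count by an independence
  argument (per-endpoint expansion factor squared), ignoring dedup
  collisions; pass the realized mapped count for exact conditioning.
- The benchmark recomputation path (`analysis/08_supplementary_benchmarks.py`)
  requires the original study's supplementary datasheets, which are not
  redistributed with the package.
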