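# antnet

Interolog-based protein–protein interaction (PPI) network inference with
evidence filtering and a full validation battery.

Most organisms — the Florida carpenter ant *Camponotus floridanus* being the
motivating case — have no experimentally mapped interactome. A practical
route is homology transfer: take experimentally observed interactions from a
well-studied template species, map both partners to their orthologs in the
target species, and keep the transferred pair (an *interolog*) when
independent evidence supports it. `antnet` implements that pipeline for
computational biologists who want to build and stress-test such a network
from plain TSV tables:

1. **Ortholog set** — method-1 (InParanoid-style) *seed* orthologs plus
   pairs confirmed by both method 1 and method 2 (OrthoMCL-style).
2. **Interolog transfer** — every template edge expands over the orthologs
   of its endpoints; the result is a canonical simple graph with provenance.
3. **Three pruning filters** — keep an edge only if (i) its endpoints carry
   a known interacting domain-family pair (DDI support), (ii) they share a
   predicted subcellular compartment, and (iii) after isoforms of the same
   gene are merged into one node.
4. **Confidence scoring** — Markov clustering (inflation 1.5) plus
   neighborhood interconnectedness:
   `score(u,v) = λ·1[cluster(u)=cluster(v)] + (1−λ)·J(N[u],N[v])`,
   banded low [0, 0.3) / medium [0.3, 0.7) / high [0.7, 1].
5. **Validation** — topology summary and exact betweenness
   `BC(n) = Σ_{s≠n≠t} σ_st(n)/σ_st`; hub (degree ≥ 5) and bottleneck (top
   20% BC) calling with multi-localization Fisher tests; z-statistics
   against Erdős–Rényi, Barabási–Albert, Watts–Strogatz and
   degree-preserving-shuffle ensembles; GO enrichment (two-tailed Fisher,
   BH-FDR) and Wang-style GO semantic similarity of interacting vs random
   pairs; conservation-by-degree profiles with Spearman trends and
   chi-square composition tests.

A seeded synthetic-data generator produces complete input bundles with
*exact* planted truth (which edges should survive each filter, which module
each protein belongs to), so the whole pipeline is testable without any
external database. See `docs/methods.md` for the model details and the
generator's construction.

## Worked example

The numbered drivers under `analysis/` run the whole study on the demo
scenario (500 template proteins, 1500 edges, planted modules, seed 42) and
write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_reconstruct.py
python analysis/03_confidence.py
```

which prints:

```
mapped interolog network: 417 nodes, 1110 edges
expected survivors: 444 after DDI filter, 293 after co-localization filter
...
  preliminary    417 nodes   1110 edges
  ddi            362 nodes    451 edges
  localization   321 nodes    299 edges
  final          301 nodes    287 edges
...
preliminary    22 clusters | low=25.2%  medium=71.2%  high=3.6%
final          70 clusters | low=17.1%  medium=22.0%  high=61.0%
Mann-Whitney preliminary vs final: U=50772, p=4.5e-71
Fisher high-band final vs preliminary: OR=41.80, p=4.49e-104
```

Reading this: of 1110 transferred edges, 451 have domain-pair support and
299 of those also share a compartment (the closed-form expectations were 444
and 293 — survival is binomial around the configured rates 0.40 and 0.66);
merging isoforms leaves 287 edges among 301 genes. Filtering shifts the
confidence-score distribution upward — the high-confidence fraction rises
from 3.6% to 61.0% and both stage-comparison tests are decisive.
`analysis/06_function_semantics.py` then shows the functional-coherence
signature of a genuine interactome: interacting pairs score a mean semantic
similarity of 0.523 while all 30 random non-interacting sets score
0.422–0.471, every one significantly lower (Mann–Whitney p < 0.05).

The same stages are scriptable through the `antnet` CLI
(`antnet simulate|map|score|topology|randomcmp|run`); `antnet run --config
run.yaml --out results/` executes everything from one config and writes a
JSON manifest of per-stage counts.

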