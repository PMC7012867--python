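"""Reference random-graph ensembles and z-statistics.

Three classical models (Erdős–Rényi G(n, m), Barabási–Albert preferential
attachment, Watts–Strogatz small-world) plus a degree-preserving double-edge
swap of the observed network are parameterized to match the observed node and
(approximately, where the model discretizes) edge counts. For each model and
topology metric, z = (observed − ensemble mean) / ensemble SD over seeded
simulations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_formats import InteractionNetwork
from .topology_analysis import summarize_topology

logger = logging.getLogger(__name__)

MODELS = ("erdos_renyi", "barabasi_albert", "watts_strogatz", "degree_preserving_shuffle")
METRICS = ("clustering_coefficient", "mean_shortest_path", "degree_distribution_stat")


@dataclass
class ModelComparison:
    model: str
    metric: str
    observed: float
    ensemble_mean: float
    ensemble_sd: float
    z: float
    n_sims: int


def _from_nx(g: nx.Graph) -> InteractionNetwork:
    net = InteractionNetwork()
    for n in g.nodes:
        net.add_node(str(n))
    for a, b in g.edges:
        net.add_edge(str(a), str(b))
    return net


def generate_model(
    model: str,
    n_nodes: int,
    n_edges: int,
    params: dict | None = None,
    seed: int = 0,
    reference: InteractionNetwork | None = None,
) -> InteractionNetwork:
    """One seeded random network of the requested model.

    ER draws uniform G(n, m); BA uses m = round(n_edges/n_nodes) attachments
    per node; WS uses a ring lattice of k = 2*round(n_edges/n_nodes) with
    rewiring probability ``params['p']`` (default 0.1); the shuffle applies
    10*n_edges double-edge swaps to ``reference``, preserving every degree.
    Infeasible discretizations are adjusted with a logged warning.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    params = params or {}
    rng_seed = int(seed) % (2**31)
    if model == "erdos_renyi":
        max_edges = n_nodes * (n_nodes - 1) // 2
        if n_edges > max_edges:
            raise ValueError("more edges than a simple graph allows")
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=rng_seed)
        return _from_nx(g)
    if model == "barabasi_albert":
        m = max(1, round(n_edges / n_nodes))
        if m > n_nodes - 1:
            logger.warning("BA m=%d infeasible for n=%d; clamping to n-1", m, n_nodes)
            m = n_nodes - 1
        g = nx.barabasi_albert_graph(n_nodes, m, seed=rng_seed)
        return _from_nx(g)
    if model == "watts_strogatz":
        k = 2 * max(1, round(n_edges / n_nodes))
        if k >= n_nodes:
            logger.warning("WS k=%d infeasible for n=%d; clamping", k, n_nodes)
            k = n_nodes - 1 if (n_nodes - 1) % 2 == 0 else n_nodes - 2
        p = float(params.get("p", 0.1))
        g = nx.watts_strogatz_graph(n_nodes, k, p, seed=rng_seed)
        return _from_nx(g)
    if model == "degree_preserving_shuffle":
        if reference is None:
            raise ValueError("shuffle model needs the reference network")
        g = reference.graph.copy()
        n_swaps = 10 * g.number_of_edges()
        try:
            nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps, seed=rng_seed)
        except nx.NetworkXAlgorithmError:
            logger.warning("double-edge swap hit its retry bound; partial shuffle kept")
        return _from_nx(g)
    raise ValueError(f"unknown model: {model!r}")


def _metric_values(net: InteractionNetwork) -> dict[str, float]:
    s = summarize_topology(net)
    return {
        "clustering_coefficient": s.clustering_coefficient,
        "mean_shortest_path": s.mean_shortest_path,
        "degree_distribution_stat": s.powerlaw_slope,
    }


def compare_to_models(
    net: InteractionNetwork,
    n_sims: int = 1000,
    seed: int = 0,
    models: tuple[str, ...] = MODELS,
    ws_p: float = 0.1,
) -> list[ModelComparison]:
    """z-statistics of the observed network against each model ensemble.

    ``degree_distribution_stat`` is the power-law slope of the degree
    histogram — the scalar chosen to summarize "degree distribution".
    Reproducible given ``seed``; a zero ensemble SD yields z = ±inf with a
    warning.
    """
    if n_sims < 2:
        raise ValueError("need at least 2 simulations")
    observed = _metric_values(net)
    n, e = net.n_nodes(), net.n_edges()
    out: list[ModelComparison] = []
    root = np.random.SeedSequence(int(seed) % (2**31))
    for mi, model in enumerate(models):
        vals: dict[str, list[float]] = {m: [] for m in METRICS}
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(mi,))
        sim_seed_ints = child.generate_state(n_sims, dtype=np.uint32)
        for k in range(n_sims):
            g = generate_model(
                model, n, e, params={"p": ws_p},
                seed=int(sim_seed_ints[k]) % (2**31), reference=net,
            )
            mv = _metric_values(g)
            for metric in METRICS:
                vals[metric].append(mv[metric])
        for metric in METRICS:
            arr = np.array([v for v in vals[metric] if not math.isnan(v)], dtype=float)
            mean = float(arr.mean()) if arr.size else float("nan")
            sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
            obs = observed[metric]
            if sd and sd > 0 and not math.isnan(sd):
                z = (obs - mean) / sd
            else:
                logger.warning("zero ensemble SD for %s/%s; z reported as inf", model, metric)
                z = math.copysign(float("inf"), obs - mean) if obs != mean else 0.0
            out.append(
                ModelComparison(
                    model=model, metric=metric, observed=obs,
                    ensemble_mean=mean, ensemble_sd=sd, z=z, n_sims=int(arr.size),
                )
            )
    return out


def ring_lattice_clustering(k: int) -> float:
    """Closed-form clustering coefficient of the WS ring lattice (p = 0)."""
    return 3.0 * (k - 2) / (4.0 * (k - 1))
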