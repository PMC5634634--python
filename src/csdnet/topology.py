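"""Topology diagnostics, degree-preserving null models, reference-network
comparison, and gene-set enrichment.

The typed subnetworks have characteristic shapes: conserved-only (C)
networks tend to be assortative and clustered because strong correlations
are transitive, while differentiated-only (D) networks are approximately
bipartite — three genes cannot all be strongly negatively correlated, so
a D-network cannot contain closed triads and has zero clustering.  These
structural claims are checked against degree-preserving randomizations
(double edge swaps) rather than absolute expectations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .network import TypedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "NullComparison",
    "EnrichmentResult",
    "degree_assortativity",
    "max_kcore",
    "mean_clustering",
    "degree_preserving_rewire",
    "null_model_comparison",
    "edge_overlap_randomization",
    "mean_shortest_path_comparison",
    "intermediary_ranking",
    "hypergeometric_enrichment",
]


@dataclass(frozen=True)
class NullComparison:
    metric_name: str
    empirical: float
    null_mean: float
    null_sd: float
    z: float
    n_random: int
    seed: int
    degenerate: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size_in_background: int
    query_size: int
    background_size: int
    p_raw: float
    p_corrected: float
    fold: float


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, TypedNetwork) else net


def degree_assortativity(net) -> float:
    """Newman degree assortativity (Pearson correlation of excess degrees
    over both orientations of every edge).  NaN when degenerate (regular
    graph: zero variance at the edge ends)."""
    g = _as_graph(net)
    if g.number_of_edges() < 2:
        raise ValueError("need at least 2 edges for assortativity")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = nx.degree_assortativity_coefficient(g)
    return float(r)


def max_kcore(net) -> int:
    """Largest k with a non-empty k-core (iterative peeling)."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return max(nx.core_number(g).values())


def mean_clustering(net) -> float:
    """Average local clustering coefficient (degree<2 nodes count as 0)."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return float(nx.average_clustering(g))


def degree_preserving_rewire(net, swaps_per_edge: int = 10,
                             seed: int = 0) -> nx.Graph:
    """Randomize a graph by double edge swaps, preserving every degree.

    Each accepted swap replaces edges (a,b),(c,d) with (a,d),(c,b) when
    doing so creates no self-loop or parallel edge.  Attempts that would
    are simply skipped, so rigid graphs (a star, a triangle) come back
    unchanged.  Deterministic given the seed.
    """
    g = _as_graph(net).copy()
    E = g.number_of_edges()
    if E < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    target = swaps_per_edge * E
    max_attempts = 100 * target
    edges = list(g.edges())
    accepted = attempts = 0
    while accepted < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, E, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    if accepted < target:
        logger.debug("rewire: accepted %d of %d targeted swaps", accepted,
                     target)
    return g


_METRICS = {
    "assortativity": degree_assortativity,
    "max_kcore": max_kcore,
    "clustering": mean_clustering,
}


def null_model_comparison(net, metric: str, n_random: int = 100,
                          seed: int = 0, link_type: str | None = None,
                          swaps_per_edge: int = 10) -> NullComparison:
    """Compare a topology metric with its degree-preserving null.

    ``link_type`` restricts to the C-, S- or D-only subnetwork before
    comparing.  The null distribution is the metric over ``n_random``
    independent rewirings; z = (empirical - null mean)/null sd, flagged
    degenerate when the null sd is 0 (rigid degree sequence).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(net, TypedNetwork) and link_type is not None:
        net = net.subnetwork(link_type)
    fn = _METRICS[metric]
    empirical = float(fn(net))
    if not math.isfinite(empirical):
        raise ValueError(f"{metric} is degenerate on this network")
    null = np.empty(n_random)
    for i in range(n_random):
        null[i] = fn(degree_preserving_rewire(net, swaps_per_edge,
                                              seed=seed + i))
    finite = null[np.isfinite(null)]
    null_mean = float(finite.mean())
    null_sd = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
    degenerate = null_sd == 0.0
    z = float("nan") if degenerate else (empirical - null_mean) / null_sd
    return NullComparison(metric, empirical, null_mean, null_sd, z,
                          n_random, seed, degenerate)


def _canonical_pairs(edges) -> set[tuple[str, str]]:
    return {(a, b) if a < b else (b, a) for a, b in edges}


def edge_overlap_randomization(net_edges, reference_edges, node_pool,
                               n_random: int = 1000,
                               seed: int = 0) -> tuple[int, float, float]:
    """How surprising is the edge overlap with a reference network?

    The null keeps the observed network's size only: each replicate
    samples |V| genes from the pool and |E| distinct pairs among them
    uniformly, then counts pairs shared with the reference.  Returns
    (observed overlap, null mean, add-one empirical p for >= observed).
    """
    net_pairs = _canonical_pairs(net_edges)
    ref_pairs = _canonical_pairs(reference_edges)
    pool = sorted(set(node_pool))
    nodes = {g for pair in net_pairs for g in pair}
    if not nodes <= set(pool):
        raise ValueError("node pool must contain every network gene")
    V, E = len(nodes), len(net_pairs)
    observed = len(net_pairs & ref_pairs)

    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool)
    total = V * (V - 1) // 2
    if E > total:
        raise ValueError("more edges than possible pairs on |V| genes")
    iu, ju = np.triu_indices(V, k=1)
    null = np.empty(n_random)
    for rep in range(n_random):
        genes = pool_arr[rng.choice(len(pool_arr), size=V, replace=False)]
        idx = rng.choice(total, size=E, replace=False)
        count = 0
        for i, j in zip(iu[idx], ju[idx]):
            a, b = genes[i], genes[j]
            if ((a, b) if a < b else (b, a)) in ref_pairs:
                count += 1
        null[rep] = count
    p = (1 + int((null >= observed).sum())) / (n_random + 1)
    return observed, float(null.mean()), p


def mean_shortest_path_comparison(pairs, reference, n_samples: int = 1000,
                                  seed: int = 0):
    """Mean geodesic distance of gene pairs within a reference network,
    against same-size random samples of connected reference pairs.

    Pairs with an endpoint missing from the reference or in a different
    component are dropped (count logged).  Returns (mean distance,
    null mean, null sd, z).
    """
    ref = _as_graph(reference)
    comp_of: dict[str, int] = {}
    comp_nodes: list[list[str]] = []
    for ci, comp in enumerate(nx.connected_components(ref)):
        comp_nodes.append(sorted(comp))
        for node in comp:
            comp_of[node] = ci

    def distance(a, b) -> float:
        return nx.shortest_path_length(ref, a, b)

    usable = []
    dropped = 0
    for a, b in pairs:
        if a in comp_of and b in comp_of and comp_of[a] == comp_of[b] \
                and a != b:
            usable.append((a, b))
        else:
            dropped += 1
    if dropped:
        logger.info("shortest-path comparison: dropped %d unusable pairs",
                    dropped)
    if not usable:
        raise ValueError("no usable pair (endpoints absent or disconnected)")
    empirical = float(np.mean([distance(a, b) for a, b in usable]))

    # null: random connected pairs from the reference, weighted by the
    # number of connected pairs each component contributes
    rng = np.random.default_rng(seed)
    sizes = np.array([len(c) for c in comp_nodes], dtype=float)
    weights = sizes * (sizes - 1)
    if weights.sum() == 0:
        raise ValueError("reference network has no connected pairs")
    weights = weights / weights.sum()
    k = len(usable)
    means = np.empty(n_samples)
    for rep in range(n_samples):
        total = 0.0
        for _ in range(k):
            ci = rng.choice(len(comp_nodes), p=weights)
            i, j = rng.choice(len(comp_nodes[ci]), size=2, replace=False)
            total += distance(comp_nodes[ci][i], comp_nodes[ci][j])
        means[rep] = total / k
    null_mean = float(means.mean())
    null_sd = float(means.std(ddof=1))
    z = (empirical - null_mean) / null_sd if null_sd > 0 else float("nan")
    return empirical, null_mean, null_sd, z


def intermediary_ranking(pairs, reference, max_steps: int = 3):
    """Rank reference nodes by how many short shortest paths they mediate.

    For every input pair connected in the reference by shortest paths of
    length <= max_steps (directly linked pairs contribute nothing), every
    shortest path is enumerated and each internal node is counted once
    per path.  Returns a list of (gene, count), descending, ties by id.
    """
    ref = _as_graph(reference)
    counts: dict[str, int] = {}
    for a, b in pairs:
        if a not in ref or b not in ref or a == b:
            continue
        try:
            d = nx.shortest_path_length(ref, a, b)
        except nx.NetworkXNoPath:
            continue
        if d < 2 or d > max_steps:
            continue
        for path in nx.all_shortest_paths(ref, a, b):
            for node in path[1:-1]:
                counts[node] = counts.get(node, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def hypergeometric_enrichment(query, background, collections,
                              correction: str = "bonferroni"
                              ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a query gene set against
    named gene-set collections, Bonferroni-corrected over the sets tested.

    population = background, successes = set ∩ background, draws = query;
    p_raw = P(X >= overlap).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    n_tests = len(collections)
    results = []
    for name, members in collections.items():
        in_bg = set(members) & background
        overlap = len(query & in_bg)
        p_raw = float(stats.hypergeom.sf(overlap - 1, len(background),
                                         len(in_bg), len(query)))
        if correction == "bonferroni":
            p_corr = min(1.0, p_raw * n_tests)
        elif correction in (None, "none"):
            p_corr = p_raw
        else:
            raise ValueError(f"unknown correction {correction!r}")
        expected = len(query) * len(in_bg) / len(background)
        fold = overlap / expected if expected > 0 else float("nan")
        results.append(EnrichmentResult(
            set_name=name, overlap=overlap,
            set_size_in_background=len(in_bg), query_size=len(query),
            background_size=len(background), p_raw=p_raw,
            p_corrected=p_corr, fold=fold))
    results.sort(key=lambda r: (r.p_raw, r.set_name))
    return results
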