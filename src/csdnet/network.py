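"""The consolidated typed co-expression network and its node statistics.

Edges carry a type in {C, S, D} and the score that placed them above the
common importance level; nodes are exactly the genes with at least one
retained link.  Node homogeneity

    H_i = sum over t in {C,S,D} of (k_{t,i} / k_i)^2

distinguishes single-type nodes (H = 1) from mixed ones (minimum 1/3 at
an even three-way split; degree-2 nodes can only reach 1 or 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "TypedNetwork",
    "NodeSummary",
    "assemble_network",
    "homogeneity",
    "node_summaries",
    "venn_partition",
    "component_decomposition",
    "hub_report",
    "degree_class",
]

LINK_TYPES = ("C", "S", "D")


@dataclass
class TypedNetwork:
    """An undirected simple graph whose edges carry a CSD type and score."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_type_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(LINK_TYPES, 0)
        for _, _, t in self.graph.edges(data="type"):
            counts[t] += 1
        return counts

    def subnetwork(self, link_type: str) -> "TypedNetwork":
        """The subgraph carrying only edges of one type (isolates dropped)."""
        if link_type not in LINK_TYPES:
            raise ValueError(f"unknown link type {link_type!r}")
        keep = [(a, b) for a, b, t in self.graph.edges(data="type")
                if t == link_type]
        sub = nx.Graph()
        for a, b in keep:
            sub.add_edge(a, b, **self.graph.edges[a, b])
        return TypedNetwork(sub)

    def typed_edge_set(self) -> set[tuple[str, str, str]]:
        """Canonicalised (gene_a, gene_b, type) triples, gene_a < gene_b."""
        return {(min(a, b), max(a, b), t)
                for a, b, t in self.graph.edges(data="type")}


@dataclass(frozen=True)
class NodeSummary:
    gene: str
    k: int
    k_C: int
    k_S: int
    k_D: int
    H: float

    @property
    def fractions(self) -> tuple[float, float, float]:
        """(k_C/k, k_S/k, k_D/k), the coordinates for ternary binning."""
        return (self.k_C / self.k, self.k_S / self.k, self.k_D / self.k)


def assemble_network(typed_pairs: pd.DataFrame) -> TypedNetwork:
    """Build the consolidated network from classified pairs.

    Input columns: gene_a, gene_b, type, score (rho1/rho2 carried along
    if present).  Pairs are canonicalised; a pair appearing twice with
    the same type collapses to one edge, with conflicting types it is an
    error (classification assigns a unique type per pair).
    """
    g = nx.Graph()
    extra = [c for c in ("rho1", "rho2") if c in typed_pairs.columns]
    for row in typed_pairs.itertuples(index=False):
        a, b = sorted((row.gene_a, row.gene_b))
        if a == b:
            raise ValueError(f"self-loop on gene {a!r}")
        if row.type not in LINK_TYPES:
            raise ValueError(f"unknown link type {row.type!r}")
        if g.has_edge(a, b):
            if g.edges[a, b]["type"] != row.type:
                raise ValueError(
                    f"pair ({a}, {b}) appears with conflicting types")
            continue
        attrs = {"type": row.type, "score": float(row.score)}
        for c in extra:
            attrs[c] = float(getattr(row, c))
        g.add_edge(a, b, **attrs)
    return TypedNetwork(g)


def homogeneity(k_C: int, k_S: int, k_D: int) -> float:
    """Sum of squared per-type degree fractions; in [1/3, 1]."""
    k = k_C + k_S + k_D
    if k < 1:
        raise ValueError("homogeneity undefined for an isolated node")
    if min(k_C, k_S, k_D) < 0:
        raise ValueError("per-type degrees must be non-negative")
    return (k_C * k_C + k_S * k_S + k_D * k_D) / (k * k)


def _typed_degrees(net: TypedNetwork, gene: str) -> tuple[int, int, int]:
    counts = dict.fromkeys(LINK_TYPES, 0)
    for _, _, t in net.graph.edges(gene, data="type"):
        counts[t] += 1
    return counts["C"], counts["S"], counts["D"]


def node_summaries(net: TypedNetwork) -> list[NodeSummary]:
    """Per-node degree, per-type degrees and homogeneity, sorted by gene."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    out = []
    for gene in sorted(net.graph.nodes):
        kc, ks, kd = _typed_degrees(net, gene)
        out.append(NodeSummary(gene=gene, k=kc + ks + kd, k_C=kc, k_S=ks,
                               k_D=kd, H=homogeneity(kc, ks, kd)))
    return out


def venn_partition(summaries: list[NodeSummary]) -> dict[str, int]:
    """Counts of nodes by the combination of link types they carry.

    Keys: 'C', 'S', 'D' (single-type), 'CS', 'CD', 'SD', 'CSD'.  The
    counts sum to the node count.
    """
    counts = {key: 0 for key in ("C", "S", "D", "CS", "CD", "SD", "CSD")}
    for s in summaries:
        key = "".join(t for t, k in zip(LINK_TYPES, (s.k_C, s.k_S, s.k_D))
                      if k > 0)
        counts[key] += 1
    return counts


def component_decomposition(net: TypedNetwork) -> list[tuple[int, int]]:
    """(node count, edge count) per connected component, largest first.

    Ties break by edge count descending, then by the lexicographically
    smallest member gene.
    """
    comps = []
    for nodes in nx.connected_components(net.graph):
        sub = net.graph.subgraph(nodes)
        comps.append((sub.number_of_nodes(), sub.number_of_edges(),
                      min(nodes)))
    comps.sort(key=lambda c: (-c[0], -c[1], c[2]))
    return [(n, e) for n, e, _ in comps]


def degree_class(k: int) -> str:
    """'hub' for k > 10, 'intermediate' for 3 <= k <= 10, else 'low'."""
    if k > 10:
        return "hub"
    if k >= 3:
        return "intermediate"
    return "low"


def hub_report(net: TypedNetwork, top_n: int = 5) -> dict[str, pd.DataFrame]:
    """Top-n nodes per link type (ranked by that type's degree) + overall.

    Ties break by total degree descending, then by gene id.  Nodes with
    zero degree of a type never appear in that type's table.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    summaries = node_summaries(net)
    frame = pd.DataFrame([{
        "gene": s.gene, "k": s.k, "k_C": s.k_C, "k_S": s.k_S,
        "k_D": s.k_D, "H": s.H, "class": degree_class(s.k),
    } for s in summaries])
    tables: dict[str, pd.DataFrame] = {}
    for t in LINK_TYPES:
        col = f"k_{t}"
        sub = frame[frame[col] > 0].sort_values(
            [col, "k", "gene"], ascending=[False, False, True])
        tables[t] = sub.head(top_n).reset_index(drop=True)
    tables["overall"] = frame.sort_values(
        ["k", "gene"], ascending=[False, True]).head(top_n).reset_index(
        drop=True)
    return tables
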