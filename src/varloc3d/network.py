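"""Topology statistics for the protein-interaction network context.

The interaction network is an input: an undirected edge list over gene
symbols, with a boolean node attribute marking DNA-damage-response (DDR)
genes.  The statistics mirror standard NetworkAnalyzer outputs: node degree,
group-averaged degree, and closeness centrality (Wasserman-Faust
component-scaled form for disconnected graphs).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd


def build_network(edges: Iterable[tuple[str, str]],
                  is_ddr: Optional[Mapping[str, bool]] = None) -> nx.Graph:
    """Build an undirected simple graph; self-loops and duplicate edges are
    rejected."""
    g = nx.Graph()
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if g.has_edge(a, b):
            raise ValueError(f"duplicate edge {a!r}-{b!r}")
        g.add_edge(a, b)
    if is_ddr:
        for node, flag in is_ddr.items():
            if node in g:
                g.nodes[node]["is_ddr"] = bool(flag)
    return g


def degree_stats(net: nx.Graph, gene_set: Iterable[str],
                 within_set_only: bool = False) -> float:
    """Average node degree over a gene set.

    With ``within_set_only`` the degree counts only edges between members of
    the set (induced-subgraph degree); otherwise edges to any node count.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene_set must be nonempty")
    missing = [g for g in genes if g not in net]
    if missing:
        raise ValueError(f"genes not in network: {missing}")
    graph = net.subgraph(genes) if within_set_only else net
    return sum(graph.degree(g) for g in genes) / len(genes)


def closeness(net: nx.Graph, node: str) -> float:
    """Closeness centrality of one node in [0, 1].

    (n-1)/sum of shortest-path distances within the node's component, scaled
    by the component's share of the graph (Wasserman-Faust); isolated nodes
    get 0 by convention.
    """
    if node not in net:
        raise ValueError(f"node {node!r} not in network")
    return float(nx.closeness_centrality(net, u=node, wf_improved=True))


def closeness_all(net: nx.Graph) -> dict[str, float]:
    return {n: float(v) for n, v in
            nx.closeness_centrality(net, wf_improved=True).items()}


def network_summary(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, closeness and DDR flag as a tidy frame."""
    close = closeness_all(net)
    rows = [(n, net.degree(n), close[n], bool(net.nodes[n].get("is_ddr", False)))
            for n in net.nodes]
    return pd.DataFrame(rows, columns=["gene", "degree", "closeness", "is_ddr"])


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a TSV edge list with columns gene_a, gene_b."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [(str(r.gene_a), str(r.gene_b)) for r in df.itertuples(index=False)]


def read_node_attributes(path: str | Path) -> dict[str, bool]:
    """Read a TSV with columns gene, is_ddr."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(r.gene): bool(r.is_ddr) for r in df.itertuples(index=False)}
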