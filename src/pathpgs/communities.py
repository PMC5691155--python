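"""Gene-gene co-membership graphs and Louvain pathway communities.

Genes that appear together in annotation sets (pathways, GO terms) are
joined by edges weighted by the number of shared sets; Louvain modularity
optimisation then partitions the genes into pathway communities.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


def build_comembership(membership: dict[str, list[str]], binary: bool = False) -> nx.Graph:
    """Graph with one node per gene and edge weight = number of annotation
    sets containing both endpoints (or 1 if ``binary``). Genes duplicated
    within one set are deduplicated with a warning; no self-loops."""
    if not membership:
        raise ValueError("empty membership table")
    g = nx.Graph()
    for set_name, genes in membership.items():
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            log.warning("build_comembership: duplicate genes within set %r deduplicated", set_name)
        g.add_nodes_from(unique)
        for i in range(len(unique)):
            for j in range(i + 1, len(unique)):
                a, b = unique[i], unique[j]
                if g.has_edge(a, b):
                    if not binary:
                        g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, weight=1)
    return g


def detect_communities(graph: nx.Graph, seed: int = 0) -> tuple[list[set], float]:
    """Louvain partition of the co-membership graph; returns (communities,
    modularity Q). Deterministic given ``seed``. An edgeless graph yields
    all-singleton communities with Q = 0."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        return [{n} for n in graph.nodes], 0.0
    parts = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    q = modularity(graph, parts)
    return [set(p) for p in parts], q


def modularity(graph: nx.Graph, partition) -> float:
    """Weighted Newman modularity of a partition."""
    if graph.number_of_edges() == 0:
        return 0.0
    return float(nx.community.modularity(graph, partition, weight="weight"))


def partition_table(partition: list[set]) -> pd.DataFrame:
    rows = [
        {"gene": gene, "community": k}
        for k, comm in enumerate(sorted(partition, key=lambda c: (-len(c), min(map(str, c)))), start=1)
        for gene in sorted(map(str, comm))
    ]
    return pd.DataFrame(rows)


def write_edgelist(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in graph.edges(data=True):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1)}\n")
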