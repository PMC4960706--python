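"""Consensus centrality ranking of network nodes.

Degree, shortest-path betweenness (Brandes pair-dependency counts,
unnormalized, each unordered pair counted once), and harmonic closeness
(sum of reciprocal shortest-path distances, so disconnected graphs are
handled with 1/inf = 0) are each ranked descending with average ranks on
ties; the consensus centrality of a node is the mean of its three ranks,
and the top 5 % by consensus are the candidate key genes.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd
from scipy.stats import rankdata

__all__ = ["compute_centralities", "top_fraction"]


def compute_centralities(network: nx.Graph) -> pd.DataFrame:
    """Per-node centrality table with ranks and consensus.

    Columns: degree, betweenness, closeness, rank_degree,
    rank_betweenness, rank_closeness, consensus (1 = most central;
    ties get average ranks, so each rank column sums to N(N+1)/2).
    """
    if network.number_of_nodes() < 2:
        raise ValueError("need at least two nodes")
    nodes = list(network.nodes)
    degree = [network.degree(v) for v in nodes]
    btw = nx.betweenness_centrality(network, normalized=False)
    clo = nx.harmonic_centrality(network)
    table = pd.DataFrame(
        {
            "degree": degree,
            "betweenness": [btw[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )
    for col in ("degree", "betweenness", "closeness"):
        table[f"rank_{col}"] = rankdata(-table[col].to_numpy(), method="average")
    table["consensus"] = table[["rank_degree", "rank_betweenness", "rank_closeness"]].mean(axis=1)
    return table


def top_fraction(table: pd.DataFrame, fraction: float = 0.05) -> list:
    """The k most central genes, k = round(fraction * N) half away from zero.

    At least one gene is always returned.  Boundary ties are broken by
    (consensus, gene id) for determinism.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(table)
    k = max(1, int(math.floor(fraction * n + 0.5)))
    ordered = table.assign(_gene=table.index.astype(str)).sort_values(
        by=["consensus", "_gene"], kind="mergesort"
    )
    return list(ordered.index[:k])
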