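"""Correlation-threshold co-occurrence networks and their topology.

Edges connect variables (taxa, functional genes, environmental factors)
whose pairwise correlation passes |r| > 0.6 with a Benjamini–Hochberg
adjusted p < 0.05 over the whole family of tested pairs — the conventional
validity rule for microbial co-occurrence networks.  Negative associations
are kept with their sign; ``positive_only`` restores an r > threshold
reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .association import correlation_matrix


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    mean_degree: float
    mean_clustering: float
    modularity: float
    n_communities: int
    hubs: list[tuple[str, int]] = field(default_factory=list)


def build_network(
    X: pd.DataFrame,
    r_threshold: float = 0.6,
    alpha: float = 0.05,
    method: str = "pearson",
    node_kinds: dict[str, str] | None = None,
    positive_only: bool = False,
) -> nx.Graph:
    """Build the co-occurrence graph from a variables x samples frame.

    Zero-variance variables are excluded with a warning recorded on the
    graph.  All pairwise correlations are computed first; BH adjustment
    runs over the full family; an edge is kept iff |r| > ``r_threshold``
    (or r > threshold with ``positive_only``) and adjusted p < ``alpha``.
    """
    if X.shape[1] < 4:
        raise ValueError("need at least 4 samples to build a network")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 variables")
    variances = X.var(axis=1, ddof=0)
    constant = variances.index[variances == 0].tolist()
    kept = X.drop(index=constant)
    report = correlation_matrix(kept, method=method)

    G = nx.Graph()
    G.graph["r_threshold"] = r_threshold
    G.graph["alpha"] = alpha
    G.graph["method"] = method
    G.graph["excluded_constant"] = constant
    means = kept.mean(axis=1)
    for var in kept.index:
        kind = (node_kinds or {}).get(var, "variable")
        G.add_node(var, kind=kind, mean_abundance=float(means[var]))
    for row in report.itertuples(index=False):
        if np.isnan(row.r) or np.isnan(row.p_adj):
            continue
        strength = row.r if positive_only else abs(row.r)
        if strength > r_threshold and row.p_adj < alpha:
            G.add_edge(row.var_a, row.var_b, r=float(row.r),
                       p_adj=float(row.p_adj),
                       sign=1 if row.r > 0 else -1)
    return G


def topology(G: nx.Graph, n_hubs: int = 5) -> TopologySummary:
    """Degree/density/clustering/modularity summary; empty graphs give zeros."""
    n = G.number_of_nodes()
    e = G.number_of_edges()
    if n == 0 or e == 0:
        return TopologySummary(n_nodes=n, n_edges=e, density=0.0, mean_degree=0.0,
                               mean_clustering=0.0, modularity=0.0,
                               n_communities=0, hubs=[])
    degrees = dict(G.degree())
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    mean_degree = sum(degrees.values()) / n
    mean_clustering = nx.average_clustering(G)
    # sort node ids for a deterministic agglomeration order
    H = nx.Graph()
    H.add_nodes_from(sorted(G.nodes(), key=str))
    H.add_edges_from(sorted((tuple(sorted(edge, key=str)) for edge in G.edges()),
                            key=lambda ab: (str(ab[0]), str(ab[1]))))
    communities = nx.community.greedy_modularity_communities(H)
    modularity = nx.community.modularity(H, communities)
    hubs = sorted(degrees.items(), key=lambda kv: (-kv[1], str(kv[0])))[:n_hubs]
    return TopologySummary(n_nodes=n, n_edges=e, density=density,
                           mean_degree=mean_degree,
                           mean_clustering=mean_clustering,
                           modularity=float(modularity),
                           n_communities=len(communities),
                           hubs=[(str(k), int(v)) for k, v in hubs])


def edge_table(G: nx.Graph) -> pd.DataFrame:
    rows = [{"source": a, "target": b, "r": d["r"], "p_adj": d["p_adj"],
             "sign": d["sign"]} for a, b, d in G.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "r", "p_adj", "sign"])


def node_table(G: nx.Graph) -> pd.DataFrame:
    degrees = dict(G.degree())
    rows = [{"node": v, "kind": d.get("kind", "variable"),
             "mean_abundance": d.get("mean_abundance", np.nan),
             "degree": degrees[v]} for v, d in G.nodes(data=True)]
    return pd.DataFrame(rows, columns=["node", "kind", "mean_abundance", "degree"])


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)
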