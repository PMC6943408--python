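"""Spearman co-occurrence networks over the top-abundance genera.

Edges connect genus pairs whose Spearman correlation passes both a
significance cut (p <= p_cut, default 0.01) and a strength cut
(|rho| > rho_cut); the sign of rho is recorded on the edge. Topology
metrics mirror the usual co-occurrence workflow: average path length and
diameter on the largest connected component, global transitivity, greedy
modularity maximization (unsigned skeleton), per-node degree /
betweenness / closeness, major modules (> 10 nodes) and keystone taxa
(top betweenness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from mosscrust.community import OtuTable, aggregate_by_rank
from mosscrust.stats import spearman_matrix


def select_top_features(
    table: OtuTable,
    taxonomy: pd.DataFrame | None = None,
    rank: str = "genus",
    n: int = 50,
) -> pd.DataFrame:
    """Abundance matrix (samples x taxa) of the n largest-total taxa at *rank*.

    Ties at the cut keep the lexicographically smaller name. With fewer
    than n taxa, all are returned with a notice.
    """
    abundance = aggregate_by_rank(table, taxonomy, rank) if taxonomy is not None else table.counts
    totals = abundance.sum(axis=0)
    ordered = sorted(abundance.columns, key=lambda t: (-totals[t], t))
    if len(ordered) < n:
        warnings.warn(
            f"only {len(ordered)} taxa available at rank {rank!r}; requested top {n}",
            stacklevel=2,
        )
    return abundance[ordered[:n]]


@dataclass
class CoNetwork:
    graph: nx.Graph
    edges: pd.DataFrame  # source, target, rho, p, sign
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def n_positive(self) -> int:
        return int((self.edges["sign"] == "positive").sum())

    @property
    def n_negative(self) -> int:
        return int((self.edges["sign"] == "negative").sum())


def build_network(
    abundances: pd.DataFrame,
    rho_cut: float = 0.6,
    p_cut: float = 0.01,
    node_attrs: pd.DataFrame | None = None,
) -> CoNetwork:
    """Thresholded Spearman co-occurrence network.

    Keeps an edge iff p <= p_cut and |rho| > rho_cut. Constant taxa are
    excluded from correlation with a warning but remain as isolated
    nodes. ``node_attrs`` (taxa x attributes, e.g. phylum) is copied onto
    the nodes along with mean abundance.
    """
    if len(abundances) < 4:
        raise ValueError("need at least 4 samples for rank correlations")
    if not 0 < rho_cut < 1:
        raise ValueError("rho_cut must lie in (0, 1)")
    taxa = list(abundances.columns)
    const = [t for t in taxa if abundances[t].std() == 0]
    if const:
        warnings.warn(f"constant taxa excluded from correlation: {const}", stacklevel=2)
    active = [t for t in taxa if t not in const]
    G = nx.Graph()
    mean_ab = abundances.mean(axis=0)
    for t in taxa:
        attrs = {"abundance": float(mean_ab[t])}
        if node_attrs is not None and t in node_attrs.index:
            attrs.update(node_attrs.loc[t].to_dict())
        G.add_node(t, **attrs)
    rows = []
    if len(active) >= 2:
        rho, p = spearman_matrix(abundances[active])
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                r, pv = float(rho.loc[a, b]), float(p.loc[a, b])
                if pv <= p_cut and abs(r) > rho_cut:
                    sign = "positive" if r > 0 else "negative"
                    G.add_edge(a, b, rho=r, p=pv, sign=sign)
                    rows.append((a, b, r, pv, sign))
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])
    return CoNetwork(graph=G, edges=edges, dropped_constant=const)


@dataclass
class NetworkMetrics:
    average_path_length: float
    diameter: int
    transitivity: float
    modularity: float
    modules: list[set]
    major_modules: list[set]
    node_table: pd.DataFrame  # degree, betweenness, closeness, module
    keystone_taxa: list[str]
    largest_component_size: int
    component_sizes: list[int]


def network_metrics(
    net: CoNetwork, major_module_min: int = 10, keystone_k: int = 3
) -> NetworkMetrics:
    """Topology metrics of a co-occurrence network (unweighted edges).

    Path length and diameter are computed on the largest connected
    component; modules come from greedy modularity maximization on the
    unsigned skeleton; major modules have > ``major_module_min`` nodes;
    keystone taxa are the ``keystone_k`` nodes of highest betweenness
    (ties broken by degree, then name).
    """
    G = net.graph
    if G.number_of_edges() == 0:
        raise ValueError("network has no edges; metrics undefined")
    # restrict communities and paths to nodes that participate in edges
    G_active = G.subgraph([n for n in G if G.degree(n) > 0]).copy()
    components = sorted(nx.connected_components(G_active), key=len, reverse=True)
    giant = G_active.subgraph(components[0])
    apl = nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else 0.0
    diameter = nx.diameter(giant) if giant.number_of_nodes() > 1 else 0
    transitivity = nx.transitivity(G_active)
    communities = [set(c) for c in nx.community.greedy_modularity_communities(G_active)]
    modularity = nx.community.modularity(G_active, communities)
    major = [c for c in communities if len(c) > major_module_min]
    betweenness = nx.betweenness_centrality(G_active)
    closeness = nx.closeness_centrality(G_active)
    degree = dict(G_active.degree())
    module_of = {}
    for m, comm in enumerate(communities):
        for node in comm:
            module_of[node] = m
    node_table = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=float),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
            "module": pd.Series(module_of),
        }
    ).sort_index()
    ranked = sorted(
        node_table.index, key=lambda t: (-node_table.at[t, "betweenness"], -node_table.at[t, "degree"], t)
    )
    return NetworkMetrics(
        average_path_length=float(apl),
        diameter=int(diameter),
        transitivity=float(transitivity),
        modularity=float(modularity),
        modules=communities,
        major_modules=major,
        node_table=node_table,
        keystone_taxa=ranked[:keystone_k],
        largest_component_size=giant.number_of_nodes(),
        component_sizes=[len(c) for c in components],
    )


def write_graphml(net: CoNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
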