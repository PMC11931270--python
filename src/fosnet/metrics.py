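"""Node centralities, hub calls, and global network metrics.

Centralities follow the coactivation-network conventions: degree is the
number of regions significantly coactivated with a node, strength the sum
of |rho| over its incident edges, and betweenness the (unnormalized)
count of weighted shortest paths passing through the node, with edge
length 1/|rho| so stronger coactivation means shorter functional
distance.  Globally, transitivity (on the binarized graph) measures
segregation and weighted global efficiency (mean inverse shortest-path
length over ordered pairs, 1/inf = 0) measures integration.

A hub is operationalized as a node ranking in the top k (default 2, with
mid-rank ties) on at least two of the three centralities; ties that push
a rank beyond k yield no hub call for the nodes involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .network import CorrelationNetwork, to_graph

__all__ = [
    "NodeMetrics",
    "GlobalMetrics",
    "node_centralities",
    "global_metrics",
    "identify_hubs",
    "global_metrics_from_weights",
]


@dataclass(frozen=True)
class NodeMetrics:
    region: str
    degree: int
    strength: float
    betweenness: float
    rank_degree: float
    rank_strength: float
    rank_betweenness: float
    is_hub: bool

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "degree": self.degree,
            "strength": self.strength,
            "betweenness": self.betweenness,
            "rank_degree": self.rank_degree,
            "rank_strength": self.rank_strength,
            "rank_betweenness": self.rank_betweenness,
            "is_hub": self.is_hub,
        }


@dataclass(frozen=True)
class GlobalMetrics:
    """Global segregation/integration summary of one network.

    ``transitivity`` is 0 when the graph has no connected triples (the
    empty-graph convention, kept numeric so resampled distributions stay
    comparable); None only for graphs with < 2 nodes.
    """

    transitivity: float | None
    global_efficiency: float
    n_edges_pos: int
    n_edges_neg: int

    def to_dict(self) -> dict:
        return {
            "transitivity": self.transitivity,
            "global_efficiency": self.global_efficiency,
            "n_edges_pos": self.n_edges_pos,
            "n_edges_neg": self.n_edges_neg,
        }


def _descending_midranks(values: np.ndarray) -> np.ndarray:
    """Rank 1 = largest value, mid-ranks for ties."""
    return stats.rankdata(-np.asarray(values, dtype=float))


def node_centralities(net: CorrelationNetwork, hub_top_k: int = 2,
                      hub_min_metrics: int = 2,
                      normalized_betweenness: bool = False
                      ) -> list[NodeMetrics]:
    """Degree, strength, and weighted betweenness per region, with
    per-metric mid-ranks and the hub flag."""
    g = to_graph(net)
    betweenness = nx.betweenness_centrality(
        g, weight="length", normalized=normalized_betweenness)
    regions = list(net.regions)
    degree = np.array([g.degree(r) for r in regions], dtype=float)
    strength = np.array(
        [sum(abs(d["rho"]) for _, _, d in g.edges(r, data=True))
         for r in regions])
    btw = np.array([betweenness[r] for r in regions], dtype=float)
    rk_d = _descending_midranks(degree)
    rk_s = _descending_midranks(strength)
    rk_b = _descending_midranks(btw)
    hubs = _hub_flags(rk_d, rk_s, rk_b, hub_top_k, hub_min_metrics)
    return [
        NodeMetrics(region=r, degree=int(degree[i]),
                    strength=float(strength[i]), betweenness=float(btw[i]),
                    rank_degree=float(rk_d[i]), rank_strength=float(rk_s[i]),
                    rank_betweenness=float(rk_b[i]), is_hub=bool(hubs[i]))
        for i, r in enumerate(regions)
    ]


def _hub_flags(rk_d, rk_s, rk_b, top_k: int, min_metrics: int) -> np.ndarray:
    in_top = (np.vstack([rk_d, rk_s, rk_b]) <= top_k)
    return in_top.sum(axis=0) >= min_metrics


def identify_hubs(metrics: list[NodeMetrics]) -> set[str]:
    """Regions flagged as hubs by ``node_centralities``."""
    if len(metrics) < 3:
        raise ValueError("hub calls need at least 3 nodes")
    return {m.region for m in metrics if m.is_hub}


def _weight_matrix(net: CorrelationNetwork) -> np.ndarray:
    """|rho| adjacency over all regions (0 where no significant edge)."""
    n = len(net.regions)
    idx = {r: i for i, r in enumerate(net.regions)}
    w = np.zeros((n, n))
    for row in net.edges.itertuples(index=False):
        i, j = idx[row.region_i], idx[row.region_j]
        w[i, j] = w[j, i] = abs(row.rho)
    return w


def global_metrics_from_weights(w: np.ndarray,
                                n_pos: int = 0, n_neg: int = 0
                                ) -> GlobalMetrics:
    """Transitivity and weighted efficiency from a |rho| weight matrix.

    The dense-matrix path used by the resampling loops; identical in value
    to computing on the graph.
    """
    n = w.shape[0]
    if n < 2:
        return GlobalMetrics(transitivity=None, global_efficiency=0.0,
                             n_edges_pos=n_pos, n_edges_neg=n_neg)
    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    triples = float((k * (k - 1)).sum())
    closed = float(np.trace(a @ a @ a))
    transitivity = closed / triples if triples > 0 else 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & off, 1.0 / np.where(
            dist > 0, dist, np.inf), 0.0)
    efficiency = float(inv[off].sum() / (n * (n - 1)))
    return GlobalMetrics(transitivity=float(transitivity),
                         global_efficiency=efficiency,
                         n_edges_pos=n_pos, n_edges_neg=n_neg)


def global_metrics(net: CorrelationNetwork,
                   transitivity_variant: str = "binary") -> GlobalMetrics:
    """Global transitivity and efficiency of a thresholded network.

    ``transitivity_variant='onnela'`` replaces binary transitivity with
    the mean Onnela weighted clustering coefficient (weights |rho|).
    """
    w = _weight_matrix(net)
    out = global_metrics_from_weights(w, net.n_edges_pos, net.n_edges_neg)
    if transitivity_variant == "binary":
        return out
    if transitivity_variant == "onnela":
        g = to_graph(net)
        if g.number_of_nodes() < 2:
            onnela = None
        else:
            cc = nx.clustering(g, weight="weight")
            onnela = float(np.mean(list(cc.values())))
        return GlobalMetrics(transitivity=onnela,
                             global_efficiency=out.global_efficiency,
                             n_edges_pos=out.n_edges_pos,
                             n_edges_neg=out.n_edges_neg)
    raise ValueError(f"unknown transitivity variant {transitivity_variant!r}")
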