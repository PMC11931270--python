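"""Condition-specific coactivation networks from inter-regional Spearman
correlations.

Nodes are brain regions; an edge joins two regions whose c-Fos counts are
significantly rank-correlated across animals (two-sided p < alpha,
default 0.05, no multiple-comparison correction across the region pairs —
a Benjamini-Hochberg variant is available behind a flag).  Edges carry the
signed rho as weight; positive and negative edges are counted separately
because the headline result of this kind of analysis is the number of
significant positive coactivations.  Isolated nodes are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exact import spearman_matrix_exact
from .expression import benjamini_hochberg
from .tables import CountTable

__all__ = [
    "CorrelationNetwork",
    "spearman_matrix",
    "threshold_network",
    "build_network",
    "to_graph",
    "write_graphml",
]


@dataclass(frozen=True)
class CorrelationNetwork:
    """Symmetric rho/p matrices plus the thresholded signed edge list.

    ``edges`` has columns region_i, region_j, rho, p_value, sign with
    region_i preceding region_j in the node ordering.  Regions whose count
    column was constant have NaN rho/p and contribute no edges but remain
    as (isolated) nodes.
    """

    condition: str
    regions: tuple[str, ...]
    rho: pd.DataFrame = field(repr=False)
    p: pd.DataFrame = field(repr=False)
    alpha: float
    edges: pd.DataFrame = field(repr=False)
    n: int

    @property
    def n_edges_pos(self) -> int:
        return int((self.edges["sign"] == "positive").sum())

    @property
    def n_edges_neg(self) -> int:
        return int((self.edges["sign"] == "negative").sum())

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def spearman_matrix(table: CountTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p across regions.

    Mid-rank ties; exact permutation p for n <= 9 animals,
    t-approximation above.  Constant regions give NaN rows/columns.
    """
    if len(table.regions) < 2:
        raise ValueError("need at least 2 regions")
    rho, p = spearman_matrix_exact(table.values())
    regions = table.regions
    return (pd.DataFrame(rho, index=regions, columns=regions),
            pd.DataFrame(p, index=regions, columns=regions))


def threshold_network(rho: pd.DataFrame, p: pd.DataFrame, alpha: float,
                      condition: str = "", n: int = 0,
                      adjust: str | None = None) -> CorrelationNetwork:
    """Keep edges with p < alpha; each edge carries its signed rho.

    ``adjust='bh'`` thresholds Benjamini-Hochberg-adjusted p-values over
    the upper-triangle pairs instead of raw ones.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if list(rho.index) != list(rho.columns) or rho.shape != p.shape:
        raise ValueError("rho and p must be square with matching labels")
    regions = tuple(str(r) for r in rho.index)
    rho_v = rho.to_numpy(float)
    p_v = p.to_numpy(float)
    if not np.allclose(rho_v, rho_v.T, equal_nan=True):
        raise ValueError("rho matrix is not symmetric")
    iu, ju = np.triu_indices(len(regions), k=1)
    pair_p = p_v[iu, ju]
    if adjust == "bh":
        finite = np.isfinite(pair_p)
        adj = pair_p.copy()
        adj[finite] = benjamini_hochberg(pair_p[finite])
        pair_p = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    rows = []
    for i, j, pv in zip(iu, ju, pair_p):
        if np.isfinite(pv) and pv < alpha:
            r = rho_v[i, j]
            rows.append((regions[i], regions[j], float(r), float(pv),
                         "positive" if r >= 0 else "negative"))
    edges = pd.DataFrame(
        rows, columns=["region_i", "region_j", "rho", "p_value", "sign"])
    return CorrelationNetwork(condition=condition, regions=regions,
                              rho=rho, p=p, alpha=alpha, edges=edges, n=n)


def build_network(table: CountTable, alpha: float = 0.05,
                  adjust: str | None = None) -> CorrelationNetwork:
    """Count table -> Spearman matrices -> thresholded network."""
    rho, p = spearman_matrix(table)
    return threshold_network(rho, p, alpha, condition=table.condition,
                             n=table.n_subjects, adjust=adjust)


def to_graph(net: CorrelationNetwork) -> nx.Graph:
    """Undirected networkx graph with weight=|rho|, signed rho, and
    shortest-path length 1/|rho| on every edge; all regions as nodes."""
    g = nx.Graph(condition=net.condition, alpha=net.alpha)
    g.add_nodes_from(net.regions)
    for row in net.edges.itertuples(index=False):
        w = abs(row.rho)
        g.add_edge(row.region_i, row.region_j, rho=float(row.rho),
                   weight=float(w), sign=row.sign,
                   length=float(1.0 / w) if w > 0 else float("inf"),
                   p_value=float(row.p_value))
    return g


def write_graphml(net: CorrelationNetwork, path,
                  communities: dict[str, int] | None = None) -> None:
    """GraphML export with weight/sign (and optional community) attributes."""
    g = to_graph(net)
    if communities is not None:
        nx.set_node_attributes(g, communities, name="community")
    nx.write_graphml(g, path)
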