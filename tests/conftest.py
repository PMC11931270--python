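"""Shared fixtures: preset synthetic tables and hand-built networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import fosnet as f
from fosnet.network import CorrelationNetwork, threshold_network
from fosnet.simulate import SimConfig


def net_from_edges(nodes, edges: dict, condition: str = "toy"
                   ) -> CorrelationNetwork:
    """Build a CorrelationNetwork with exactly the given weighted edges.

    ``edges`` maps (u, v) -> rho; listed pairs get p=1e-6, all others p=1,
    so thresholding at alpha=0.05 reproduces the edge set exactly.
    """
    nodes = list(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    rho = np.eye(n)
    p = np.ones((n, n))
    np.fill_diagonal(p, 0.0)
    for (u, v), w in edges.items():
        i, j = idx[u], idx[v]
        rho[i, j] = rho[j, i] = w
        p[i, j] = p[j, i] = 1e-6
    rho_df = pd.DataFrame(rho, index=nodes, columns=nodes)
    p_df = pd.DataFrame(p, index=nodes, columns=nodes)
    return threshold_network(rho_df, p_df, alpha=0.05, condition=condition)


def random_weighted_net(rng: np.random.Generator, n_nodes: int,
                        p_edge: float = 0.6, unit: bool = False):
    """Random graph + the oracle-format edge dicts (lengths and weights)."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                w = 1.0 if unit else float(rng.uniform(0.2, 1.0))
                edges[(nodes[i], nodes[j])] = w
    net = net_from_edges(nodes, edges)
    lengths = {frozenset(k): 1.0 / w for k, w in edges.items()}
    weights = {frozenset(k): w for k, w in edges.items()}
    return net, nodes, lengths, weights


@pytest.fixture(scope="session")
def li_config() -> SimConfig:
    return f.li_preset(seed=11)


@pytest.fixture(scope="session")
def hi_config() -> SimConfig:
    return f.hi_preset(seed=11)


@pytest.fixture(scope="session")
def li_tables(li_config):
    return (f.generate_condition_counts(li_config, "LI"),
            f.generate_behavior(li_config, "LI"))


@pytest.fixture(scope="session")
def hi_tables(hi_config):
    return (f.generate_condition_counts(hi_config, "HI"),
            f.generate_behavior(hi_config, "HI"))


@pytest.fixture(scope="session")
def null_config() -> SimConfig:
    """Independent regions: empty block structure, rho_between = 0."""
    return SimConfig(block_structure={"IND": ()}, rho_within=0.5,
                     rho_between=0.0, seed=99)
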