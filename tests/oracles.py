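"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by exhaustive enumeration,
deliberately sharing no code path with the package: shortest paths by
path enumeration, permutation nulls by direct iteration, modularity by
scanning every set partition.  Slow by design; only run on tiny inputs.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------- graphs

def enumerate_paths(edges: dict, nodes, src, dst):
    """All simple paths src -> dst with their total lengths.

    ``edges`` maps frozenset({u, v}) -> length.
    """
    paths = []

    def walk(current, visited, length):
        if current == dst:
            paths.append((length, tuple(visited)))
            return
        for nxt in nodes:
            if nxt in visited:
                continue
            key = frozenset({current, nxt})
            if key in edges:
                walk(nxt, visited + [nxt], length + edges[key])

    walk(src, [src], 0.0)
    return paths


def brute_shortest_paths(edges: dict, nodes, src, dst):
    """(min length, list of minimal paths) or (inf, []) if disconnected."""
    paths = enumerate_paths(edges, nodes, src, dst)
    if not paths:
        return float("inf"), []
    best = min(length for length, _ in paths)
    minimal = [p for length, p in paths if abs(length - best) < 1e-9]
    return best, minimal


def brute_betweenness(edges: dict, nodes) -> dict:
    """Unnormalized betweenness with fractional credit for tied paths."""
    btw = {v: 0.0 for v in nodes}
    for src, dst in itertools.combinations(nodes, 2):
        best, minimal = brute_shortest_paths(edges, nodes, src, dst)
        if not minimal:
            continue
        for path in minimal:
            for mid in path[1:-1]:
                btw[mid] += 1.0 / len(minimal)
    return btw


def brute_global_efficiency(edges: dict, nodes) -> float:
    """Mean of 1/d over ordered pairs, 1/inf = 0."""
    n = len(nodes)
    if n < 2:
        return 0.0
    total = 0.0
    for src, dst in itertools.permutations(nodes, 2):
        best, minimal = brute_shortest_paths(edges, nodes, src, dst)
        if minimal:
            total += 1.0 / best
    return total / (n * (n - 1))


def brute_transitivity(edges: dict, nodes) -> float:
    """3 * triangles / connected triples on the binarized graph; 0 if no
    triples."""
    adj = {v: set() for v in nodes}
    for key in edges:
        u, v = tuple(key)
        adj[u].add(v)
        adj[v].add(u)
    triangles = 0
    for a, b, c in itertools.combinations(nodes, 3):
        if b in adj[a] and c in adj[a] and c in adj[b]:
            triangles += 1
    triples = sum(len(adj[v]) * (len(adj[v]) - 1) // 2 for v in nodes)
    if triples == 0:
        return 0.0
    return 3.0 * triangles / triples


def brute_strength(edges: dict, nodes) -> dict:
    s = {v: 0.0 for v in nodes}
    for key, length in edges.items():
        u, v = tuple(key)
        w = 1.0 / length  # tests build edges with length = 1/weight
        s[u] += w
        s[v] += w
    return s


# ------------------------------------------------------- rank statistics

def ranks_midrank(x) -> np.ndarray:
    """Mid-ranks computed by counting, independent of scipy.rankdata."""
    x = np.asarray(x, dtype=float)
    out = np.empty(x.size)
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        equal = np.sum(x == xi)
        out[i] = less + (equal + 1) / 2.0
    return out


def spearman_rho_direct(x, y) -> float:
    rx = ranks_midrank(x)
    ry = ranks_midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def brute_spearman_p(x, y) -> float:
    """Two-sided permutation p by iterating every ordering of y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(spearman_rho_direct(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_rho_direct(x, perm)) >= obs - 1e-9:
            count += 1
    return count / total


def brute_mannwhitney_u(a, b) -> float:
    """U by direct pair counting (half credit for ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def brute_mannwhitney_p(a, b) -> float:
    """Two-sided p by enumerating every split of the pooled values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = a.size
    mid = n_a * b.size / 2.0
    obs = abs(brute_mannwhitney_u(a, b) - mid)
    count = 0
    total = 0
    idx = range(pooled.size)
    for chosen in itertools.combinations(idx, n_a):
        rest = [i for i in idx if i not in chosen]
        u = brute_mannwhitney_u(pooled[list(chosen)], pooled[rest])
        total += 1
        if abs(u - mid) >= obs - 1e-9:
            count += 1
    return count / total


# ------------------------------------------------------------ modularity

def set_partitions(items):
    """Every partition of ``items`` into non-empty blocks (Bell number)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1:]
        yield [[first]] + partial


def modularity_direct(weights: dict, nodes, partition, resolution=1.0
                      ) -> float:
    """Newman weighted modularity with a resolution term, from scratch.

    ``weights`` maps frozenset({u, v}) -> positive weight.
    """
    two_m = 2.0 * sum(weights.values())
    if two_m == 0:
        return 0.0
    degree = {v: 0.0 for v in nodes}
    for key, w in weights.items():
        u, v = tuple(key)
        degree[u] += w
        degree[v] += w
    q = 0.0
    for block in partition:
        for u in block:
            for v in block:
                a_uv = weights.get(frozenset({u, v}), 0.0) if u != v else 0.0
                q += a_uv / two_m
                q -= resolution * degree[u] * degree[v] / (two_m * two_m)
    return q


def brute_max_modularity(weights: dict, nodes, resolution=1.0
                         ) -> tuple[float, list]:
    """Exhaustive modularity maximum over all set partitions."""
    best_q = -np.inf
    best_p = None
    for partition in set_partitions(list(nodes)):
        q = modularity_direct(weights, nodes, partition, resolution)
        if q > best_q:
            best_q = q
            best_p = partition
    return best_q, best_p
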