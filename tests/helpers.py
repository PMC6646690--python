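"""Independent oracles and small generators shared by the tests."""
from __future__ import annotations

import networkx as nx
import numpy as np


def brute_force_auc(labeled) -> float:
    """AUC by exhaustive pairwise counting over all (positive, negative)
    score pairs: concordant plus half the ties."""
    pos = [s for s, lab in labeled if lab == 1]
    neg = [s for s, lab in labeled if lab == 0]
    concordant = sum(1 for p in pos for n in neg if p > n)
    tied = sum(1 for p in pos for n in neg if p == n)
    return (concordant + 0.5 * tied) / (len(pos) * len(neg))


def solve_rwr(walk_edges, node_order, seeds, r):
    """Steady state by a dense linear solve written out longhand, independent
    of the package's matrix construction."""
    index = {n: i for i, n in enumerate(node_order)}
    n = len(node_order)
    A = np.zeros((n, n))
    deg = {u: 0 for u in node_order}
    for a, b in walk_edges:
        deg[a] += 1
        deg[b] += 1
    for a, b in walk_edges:
        A[index[a], index[b]] = 1.0 / deg[b]
        A[index[b], index[a]] = 1.0 / deg[a]
    p0 = np.zeros(n)
    for s in seeds:
        p0[index[s]] = 1.0 / len(seeds)
    return np.linalg.solve(np.eye(n) - (1.0 - r) * A, r * p0)


def random_connected_graph(rng: np.random.Generator, n_max: int = 50):
    """Random connected graph (spanning tree plus extra random edges) with
    string node names; returns (walk_edges, node_order, seeds)."""
    n = int(rng.integers(2, n_max + 1))
    tree = nx.random_labeled_tree(n, seed=int(rng.integers(2**31 - 1)))
    g = nx.Graph(tree)
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = rng.integers(0, n, size=2)
        if u != v:
            g.add_edge(int(u), int(v))
    node_order = tuple(f"N{i:03d}" for i in range(n))
    walk_edges = frozenset((f"N{u:03d}", f"N{v:03d}") for u, v in g.edges())
    n_seeds = int(rng.integers(1, n + 1))
    seeds = {f"N{i:03d}" for i in
             rng.choice(n, size=n_seeds, replace=False)}
    return walk_edges, node_order, seeds
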