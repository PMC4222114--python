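"""Random additive (tree-metric) matrices with known generating trees.

Independent oracle machinery for neighbor-joining tests: a random unrooted
binary tree with positive branch lengths is built by sequential leaf
attachment, its exact leaf-to-leaf path-length matrix is computed by graph
traversal, and its edges are exported as canonical bipartitions so a
reconstructed tree can be compared edge-for-edge.
"""

from __future__ import annotations

import random

import numpy as np


def random_additive_tree(n_leaves: int, rng: random.Random):
    """Return (adjacency, leaves): adjacency maps node -> {neighbor: length}."""
    adj: dict[str, dict[str, float]] = {}
    counter = [0]

    def add_edge(a: str, b: str, l: float) -> None:
        adj.setdefault(a, {})[b] = l
        adj.setdefault(b, {})[a] = l

    def new_internal() -> str:
        counter[0] += 1
        return f"I{counter[0]}"

    leaves = [f"L{i}" for i in range(n_leaves)]
    hub = new_internal()
    for lf in leaves[:3]:
        add_edge(hub, lf, rng.uniform(0.1, 1.0))
    for lf in leaves[3:]:
        edges = sorted((a, b) for a in adj for b in adj[a] if a < b)
        a, b = rng.choice(edges)
        l = adj[a][b]
        del adj[a][b]
        del adj[b][a]
        mid = new_internal()
        x = rng.uniform(0.2, 0.8) * l
        add_edge(a, mid, x)
        add_edge(mid, b, l - x)
        add_edge(mid, lf, rng.uniform(0.1, 1.0))
    return adj, leaves


def path_distance_matrix(adj, leaves) -> np.ndarray:
    dist_from: dict[str, dict[str, float]] = {}
    for s in leaves:
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, l in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + l
                    stack.append(v)
        dist_from[s] = dist
    n = len(leaves)
    M = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            M[i, j] = dist_from[a][b]
    return M


def true_edge_bipartitions(adj, leaves) -> dict[frozenset, float]:
    """Edge lengths keyed by the canonical bipartition side (the side not
    containing the lexicographically smallest leaf)."""
    ref = sorted(leaves)[0]
    all_set = frozenset(leaves)
    out: dict[frozenset, float] = {}
    for a in adj:
        for b in adj[a]:
            if not a < b:
                continue
            side = set()
            seen = {a, b}
            stack = [b]
            if b in leaves:
                side.add(b)
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
                        if v in leaves:
                            side.add(v)
            key = frozenset(side) if ref not in side else all_set - frozenset(side)
            out[key] = out.get(key, 0.0) + adj[a][b]
    return out
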