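"""Independent oracles for distance-based tree reconstruction tests.

Random unrooted binary trees with positive branch lengths, their induced
additive distance matrices and bipartitions, plus a brute-force
least-squares topology search for five leaves.  Everything here is kept
deliberately naive and separate from the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree; returns (adjacency, leaf labels).

    Adjacency maps node -> {neighbour: branch length}.  Leaves are
    strings "L00".."Lnn", internal nodes negative ints.
    """
    assert n_leaves >= 3
    leaves = [f"L{i:02d}" for i in range(n_leaves)]
    adj: dict = {}

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def disconnect(a, b):
        del adj[a][b]
        del adj[b][a]

    def blen():
        return float(rng.uniform(0.05, 1.0))

    nxt = [-1]
    connect(leaves[0], -1, blen())
    connect(leaves[1], -1, blen())
    connect(leaves[2], -1, blen())
    for leaf in leaves[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if str(a) < str(b)]
        a, b = edges[rng.integers(0, len(edges))]
        w = adj[a][b]
        nxt[0] -= 1
        mid = nxt[0]
        disconnect(a, b)
        split = float(rng.uniform(0.25, 0.75))
        connect(a, mid, w * split)
        connect(b, mid, w * (1 - split))
        connect(leaf, mid, blen())
    return adj, leaves


def tree_distances(adj: dict, leaves: list[str]) -> np.ndarray:
    n = len(leaves)
    D = np.zeros((n, n))
    for i, a in enumerate(leaves):
        dist = {a: 0.0}
        stack = [a]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, b in enumerate(leaves):
            D[i, j] = dist[b]
    return D


def tree_bipartitions(adj: dict, leaves: list[str]) -> set[frozenset]:
    """Non-trivial splits, canonicalised to exclude the smallest leaf."""
    smallest = min(leaves)
    total = set(leaves)
    out = set()
    for a in adj:
        for b in adj[a]:
            if not (str(a) < str(b)):
                continue
            seen = {a, b}
            stack = [b]
            side = set()
            while stack:
                u = stack.pop()
                if isinstance(u, str):
                    side.add(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if 1 < len(side) < len(total) - 1:
                if smallest in side:
                    side = total - side
                out.add(frozenset(side))
    return out


def five_leaf_topologies(leaves: list[str]):
    """All 15 unrooted binary topologies on five leaves.

    Each topology is ((a, b), (c, d), e): two cherries and the middle
    leaf.  Edge structure: a-x, b-x, c-y, d-y, e-z, x-z, y-z.
    """
    assert len(leaves) == 5
    tops = []
    for pair1 in itertools.combinations(leaves, 2):
        rest = [x for x in leaves if x not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            if pair1 > pair2:
                continue
            e = [x for x in rest if x not in pair2][0]
            tops.append((pair1, pair2, e))
    return tops


def least_squares_fit(topology, leaves: list[str], D: np.ndarray):
    """Fit the 7 branch lengths of a five-leaf topology by least squares.

    Returns (residual, fitted_lengths).  Branch order: a, b, c, d, e,
    x-z, y-z.
    """
    (a, b), (c, d), e = topology
    pend = {a: 0, b: 1, c: 2, d: 3, e: 4}
    XZ, YZ = 5, 6

    def path(u, v):
        row = np.zeros(7)
        row[pend[u]] += 1
        row[pend[v]] += 1
        cherry1 = {a, b}
        cherry2 = {c, d}
        side_u = 0 if u in cherry1 else (1 if u in cherry2 else 2)
        side_v = 0 if v in cherry1 else (1 if v in cherry2 else 2)
        if {side_u, side_v} == {0, 1}:
            row[XZ] += 1
            row[YZ] += 1
        elif {side_u, side_v} == {0, 2}:
            row[XZ] += 1
        elif {side_u, side_v} == {1, 2}:
            row[YZ] += 1
        # same cherry: pendants only
        return row

    rows, y = [], []
    idx = {x: i for i, x in enumerate(leaves)}
    for u, v in itertools.combinations(leaves, 2):
        rows.append(path(u, v))
        y.append(D[idx[u], idx[v]])
    A = np.array(rows)
    sol, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
    resid = float(((A @ sol - np.array(y)) ** 2).sum())
    return resid, sol


def topology_bipartitions(topology, leaves: list[str]) -> set[frozenset]:
    (a, b), (c, d), e = topology
    smallest = min(leaves)
    total = set(leaves)
    out = set()
    for side in ({a, b}, {c, d}):
        s = set(side)
        if smallest in s:
            s = total - s
        out.add(frozenset(s))
    return out
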