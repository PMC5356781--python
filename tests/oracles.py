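"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles — naive
enumeration, set-based Fitch, double-loop statistics — and shares no code
path with the package implementation it checks.
"""
from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Tuple

import numpy as np


# -- trees as raw edge lists ------------------------------------------------

def all_topologies(n: int) -> List[List[Tuple[int, int]]]:
    """All unrooted binary topologies on leaves 0..n-1, as edge lists.

    Internal nodes are numbered from n upward. Independent re-derivation by
    sequential leaf insertion.
    """
    if n == 2:
        return [[(0, 1)]]
    trees = [[(0, n), (1, n), (2, n)]]
    for leaf in range(3, n):
        new_internal = n + leaf - 2
        nxt = []
        for t in trees:
            for i in range(len(t)):
                u, v = t[i]
                nxt.append(t[:i] + t[i + 1:] +
                           [(u, new_internal), (v, new_internal),
                            (leaf, new_internal)])
        trees = nxt
    return trees


def random_topology(rng: np.random.Generator, n: int) -> List[Tuple[int, int]]:
    """One uniform random unrooted binary topology by random leaf insertion."""
    edges = [(0, n), (1, n), (2, n)]
    for leaf in range(3, n):
        new_internal = n + leaf - 2
        i = int(rng.integers(0, len(edges)))
        u, v = edges.pop(i)
        edges += [(u, new_internal), (v, new_internal), (leaf, new_internal)]
    return edges


def _orient(edges: List[Tuple[int, int]], root: int):
    """(parent map, postorder) for the tree rooted at ``root``."""
    adj: Dict[int, List[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    parent = {root: None}
    order = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        for nbr in adj[node]:
            if nbr != parent[node]:
                parent[nbr] = node
                stack.append(nbr)
    order.reverse()
    return adj, parent, order


def brute_force_wagner(edges: List[Tuple[int, int]],
                       leaf_states: Dict[int, Sequence[int]]) -> int:
    """Minimum ordered-character length by enumerating every internal-node
    state assignment, per character."""
    nodes = {x for e in edges for x in e}
    internals = sorted(nodes - set(leaf_states))
    n_char = len(next(iter(leaf_states.values())))
    smax = max(max(s) for s in leaf_states.values())
    total = 0
    if not internals:  # two leaves
        (a, b) = sorted(leaf_states)
        return int(np.abs(np.asarray(leaf_states[a]) -
                          np.asarray(leaf_states[b])).sum())
    grid = np.array(list(itertools.product(range(smax + 1),
                                           repeat=len(internals))), dtype=int)
    pos = {n: i for i, n in enumerate(internals)}
    for j in range(n_char):
        cost = np.zeros(len(grid), dtype=int)
        for u, v in edges:
            su = grid[:, pos[u]] if u in pos else np.full(len(grid),
                                                          leaf_states[u][j])
            sv = grid[:, pos[v]] if v in pos else np.full(len(grid),
                                                          leaf_states[v][j])
            cost += np.abs(su - sv)
        total += int(cost.min())
    return total


def fitch_length(edges: List[Tuple[int, int]],
                 leaf_states: Dict[int, Sequence[int]]) -> int:
    """Classic Fitch (unordered) parsimony length for binary characters,
    via set intersection/union on a leaf-rooted orientation."""
    root = min(leaf_states)
    adj, parent, order = _orient(edges, root)
    n_char = len(next(iter(leaf_states.values())))
    total = 0
    for j in range(n_char):
        sets: Dict[int, frozenset] = {}
        changes = 0
        for node in order:
            if node in leaf_states:
                sets[node] = frozenset([leaf_states[node][j]])
                continue
            kids = [n for n in adj[node] if n != parent[node]]
            cur = sets[kids[0]]
            for k in kids[1:]:
                inter = cur & sets[k]
                if inter:
                    cur = inter
                else:
                    cur = cur | sets[k]
                    changes += 1
            sets[node] = cur
        # root is a leaf: one more union step against its child
        child = [n for n in adj[root] if n != parent[root]][0]
        if leaf_states[root][j] not in sets[child]:
            changes += 1
        total += changes
    return total


# -- statistics -------------------------------------------------------------

def jt_statistic_naive(values: Sequence[float], ranks: Sequence[int]) -> float:
    t = 0.0
    for i, (vi, ri) in enumerate(zip(values, ranks)):
        for vj, rj in zip(values, ranks):
            if ri < rj:
                if vj > vi:
                    t += 1.0
                elif vj == vi:
                    t += 0.5
    return t


def jt_exhaustive_p(values: Sequence[float], ranks: Sequence[int]) -> float:
    """Exact one-sided trend p by enumerating every distinct assignment of
    the group labels to the observations."""
    obs = jt_statistic_naive(values, ranks)
    hits = total = 0
    for perm in sorted(set(itertools.permutations(tuple(ranks)))):
        total += 1
        if jt_statistic_naive(values, perm) >= obs - 1e-9:
            hits += 1
    return hits / total


def rank_sum_exhaustive_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided permutation p for the rank-sum statistic by
    enumerating all label splits."""
    pooled = list(a) + list(b)
    na = len(a)
    expected = na * len(b) / 2.0

    def u(xs, ys):
        t = 0.0
        for x in xs:
            for y in ys:
                if y > x:
                    t += 1.0
                elif y == x:
                    t += 0.5
        return t

    obs = abs(u(a, b) - expected)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u(xs, ys) - expected) >= obs - 1e-9:
            hits += 1
    return hits / total
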