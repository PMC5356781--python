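"""Wagner parsimony for ordered (additive) integer characters.

The cost of an edge is the absolute state difference |i - j|, so binary
characters reduce to Fitch parsimony. Lengths are computed by Farris
interval propagation on a tree rooted at an arbitrary leaf: each internal
node carries, per character, the closed interval of states attainable in a
minimal reconstruction of its subtree; when the two child intervals are
disjoint the gap between them is added to the length. This is exact for
additive characters on binary trees and is contract-equivalent to brute
force over all internal state assignments (which the test suite checks).

Tree search is exhaustive over all (2n-5)!! unrooted binary topologies —
per-patient taxon counts here are small (a handful of nodules plus the
cirrhotic background), so exactness is affordable and removes search
stochasticity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .matrix import CharacterMatrix, ROOT_TAXON
from .tree import PhyloTree, enumerate_topologies, DEFAULT_LEAF_CAP
from .types import ValidationError


def _leaf_states(tree: PhyloTree, matrix: CharacterMatrix) -> Dict[int, np.ndarray]:
    if set(tree.labels.values()) != set(matrix.taxa):
        raise ValidationError(
            f"tree leaves {sorted(tree.labels.values())} do not match "
            f"matrix taxa {sorted(matrix.taxa)}"
        )
    return {node: matrix.row(lab) for node, lab in tree.labels.items()}


def _farris_intervals(tree: PhyloTree, matrix: CharacterMatrix,
                      root_label: Optional[str] = None):
    """Down-pass of Farris optimization.

    Returns (root leaf, parent map, postorder, per-node [lo, hi] interval
    arrays, total length). Intervals are over all characters at once.
    """
    if not tree.is_binary:
        raise ValidationError("Wagner length requires an unrooted binary tree")
    states = _leaf_states(tree, matrix)
    root, parent, order = tree.rooted_orientation(root_label)
    lo: Dict[int, np.ndarray] = {}
    hi: Dict[int, np.ndarray] = {}
    total = 0
    for node in order:
        if node in tree.labels:
            lo[node] = hi[node] = states[node].astype(np.int64)
            continue
        kids = [n for n in tree.adj[node] if n != parent[node]]
        a, b = kids  # binary tree rooted at a leaf: exactly two children
        l = np.maximum(lo[a], lo[b])
        h = np.minimum(hi[a], hi[b])
        gap = l - h
        total += int(gap[gap > 0].sum())
        lo[node], hi[node] = np.minimum(l, h), np.maximum(l, h)
    if tree.n_leaves >= 3:
        child = tree.adj[root][0]
        s = states[root]
        total += int(np.maximum(np.maximum(lo[child] - s, s - hi[child]), 0).sum())
    else:  # two leaves: single edge, Manhattan distance
        a, b = tree.leaf_nodes
        total = int(np.abs(states[a] - states[b]).sum())
    return root, parent, order, lo, hi, total


def wagner_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Minimum total ordered-character changes of ``matrix`` on ``tree``."""
    return _farris_intervals(tree, matrix)[-1]


def assign_edge_changes(
    tree: PhyloTree, matrix: CharacterMatrix, root_label: Optional[str] = None
) -> PhyloTree:
    """Attach one minimal reconstruction's per-edge change counts.

    The tree is rooted at ``root_label`` (default: the NORMAL outgroup if
    present, else the first taxon) and each internal node receives, in
    preorder, the state in its down-pass interval closest to its parent's
    assigned state. For additive characters this parent-closest rule is
    length-preserving; ties do not arise because clipping to an interval is
    unique. The per-edge counts therefore sum to ``wagner_length``.
    """
    if root_label is None:
        root_label = ROOT_TAXON if ROOT_TAXON in matrix.taxa else matrix.taxa[0]
    if tree.n_leaves == 2:
        a, b = tree.leaf_nodes
        states = _leaf_states(tree, matrix)
        d = int(np.abs(states[a] - states[b]).sum())
        return PhyloTree([(a, b)], tree.labels, {frozenset((a, b)): d})
    root, parent, order, lo, hi, _total = _farris_intervals(tree, matrix, root_label)
    states = _leaf_states(tree, matrix)
    assigned: Dict[int, np.ndarray] = {}
    changes: Dict[frozenset, int] = {}
    for node in reversed(order):  # preorder: parents before children
        if node in tree.labels:
            assigned[node] = states[node].astype(np.int64)
        else:
            assigned[node] = np.clip(assigned[parent[node]], lo[node], hi[node])
        if parent[node] is not None:
            d = int(np.abs(assigned[node] - assigned[parent[node]]).sum())
            changes[frozenset((node, parent[node]))] = d
    return PhyloTree(
        [tuple(e) for e in tree.edges()], tree.labels, changes
    )


@dataclass
class MPTSet:
    """All maximum-parsimony (minimum-length) trees for one matrix."""

    trees: List[PhyloTree]
    length: int
    n_examined: int

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValidationError("MPT set cannot be empty")


def search_mpt(matrix: CharacterMatrix, cap: int = DEFAULT_LEAF_CAP) -> MPTSet:
    """Exhaustive Wagner-parsimony search over all unrooted binary
    topologies on the matrix taxa; returns every minimizer."""
    n = matrix.n_taxa
    if n < 2:
        raise ValidationError("need at least 2 taxa")
    if n == 2:
        tree = next(enumerate_topologies(matrix.taxa))
        scored = assign_edge_changes(tree, matrix)
        return MPTSet([scored], scored.length, 1)
    best: List[PhyloTree] = []
    best_len: Optional[int] = None
    examined = 0
    for topo in enumerate_topologies(matrix.taxa, cap=cap):
        examined += 1
        length = wagner_length(topo, matrix)
        if best_len is None or length < best_len:
            best_len = length
            best = [topo]
        elif length == best_len:
            best.append(topo)
    return MPTSet(
        [assign_edge_changes(t, matrix) for t in best], int(best_len), examined
    )
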