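"""Unrooted leaf-labeled trees: construction, enumeration, bipartitions,
strict consensus, and Newick rendering.

Trees are stored as plain adjacency over integer node ids with a label map
for the leaves. Internal nodes of a binary unrooted tree have degree 3;
strict-consensus trees may be multifurcating. Per-edge change counts (set
by the parsimony module) are keyed by the frozenset of the edge's two node
ids.
"""
from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

from .types import ValidationError

Edge = FrozenSet[int]

#: hard cap on exhaustive topology enumeration; (2n-5)!! explodes beyond this
DEFAULT_LEAF_CAP = 10


class PhyloTree:
    def __init__(
        self,
        edges: Iterable[Tuple[int, int]],
        labels: Dict[int, str],
        edge_changes: Optional[Dict[Edge, int]] = None,
    ):
        self.adj: Dict[int, List[int]] = {}
        self._edges: List[Edge] = []
        for u, v in edges:
            if u == v:
                raise ValidationError("self-loop edge")
            self.adj.setdefault(u, []).append(v)
            self.adj.setdefault(v, []).append(u)
            self._edges.append(frozenset((u, v)))
        self.labels = dict(labels)
        self.edge_changes = dict(edge_changes) if edge_changes is not None else None
        self._validate()

    def _validate(self) -> None:
        if len(set(self.labels.values())) != len(self.labels):
            raise ValidationError("duplicate leaf labels")
        for node, nbrs in self.adj.items():
            deg = len(nbrs)
            if node in self.labels:
                if deg != 1:
                    raise ValidationError(f"labeled leaf {node} has degree {deg}")
            elif deg < 3 and len(self.adj) > 2:
                raise ValidationError(f"internal node {node} has degree {deg} < 3")
        # connectivity
        if self.adj:
            seen = set()
            stack = [next(iter(self.adj))]
            while stack:
                n = stack.pop()
                if n in seen:
                    continue
                seen.add(n)
                stack.extend(self.adj[n])
            if seen != set(self.adj):
                raise ValidationError("tree is not connected")

    # -- basic accessors ---------------------------------------------------

    @property
    def leaf_nodes(self) -> List[int]:
        return sorted(self.labels)

    @property
    def leaf_labels(self) -> List[str]:
        return [self.labels[n] for n in self.leaf_nodes]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def edges(self) -> List[Edge]:
        return list(self._edges)

    @property
    def is_binary(self) -> bool:
        return all(
            len(nbrs) == 3 for n, nbrs in self.adj.items() if n not in self.labels
        ) or self.n_leaves == 2

    @property
    def length(self) -> Optional[int]:
        if self.edge_changes is None:
            return None
        return sum(self.edge_changes.values())

    def node_by_label(self, label: str) -> int:
        for n, lab in self.labels.items():
            if lab == label:
                return n
        raise KeyError(label)

    # -- topology comparison ----------------------------------------------

    def _leafset_under(self, child: int, parent: int) -> FrozenSet[str]:
        """Labels of leaves on ``child``'s side of edge (parent, child)."""
        out = set()
        stack = [(child, parent)]
        while stack:
            node, par = stack.pop()
            if node in self.labels:
                out.add(self.labels[node])
            for nbr in self.adj[node]:
                if nbr != par:
                    stack.append((nbr, node))
        return frozenset(out)

    def bipartitions(self, nontrivial: bool = True) -> FrozenSet[FrozenSet[str]]:
        """Canonical bipartition set: for each edge, the leaf-label side not
        containing the lexicographically smallest label."""
        all_labels = frozenset(self.labels.values())
        ref = min(all_labels)
        out = set()
        for e in self._edges:
            u, v = tuple(e)
            side = self._leafset_under(u, v)
            if ref in side:
                side = all_labels - side
            if nontrivial and (len(side) < 2 or len(side) > len(all_labels) - 2):
                continue
            out.add(side)
        return frozenset(out)

    def same_topology(self, other: "PhyloTree") -> bool:
        return (
            frozenset(self.labels.values()) == frozenset(other.labels.values())
            and self.bipartitions() == other.bipartitions()
        )

    # -- rooting and rendering --------------------------------------------

    def rooted_orientation(self, root_label: Optional[str] = None):
        """Return (root_node, parent_map, postorder list) with the tree
        oriented away from the leaf named ``root_label`` (default: the
        lexicographically smallest leaf label)."""
        if root_label is None:
            root_label = min(self.labels.values())
        root = self.node_by_label(root_label)
        parent: Dict[int, Optional[int]] = {root: None}
        order: List[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            order.append(node)
            for nbr in self.adj[node]:
                if nbr != parent[node]:
                    parent[nbr] = node
                    stack.append(nbr)
        order.reverse()  # postorder: children before parents
        return root, parent, order

    def newick(self, root_label: Optional[str] = None, lengths: bool = True) -> str:
        """Serialize to Newick, displayed from the internal node adjacent to
        the root leaf (the root leaf appears as the first child). Branch
        lengths are per-edge change counts when attached."""
        if self.n_leaves < 2:
            raise ValidationError("need >= 2 leaves to serialize")
        use_lengths = lengths and self.edge_changes is not None

        def blen(u: int, v: int) -> str:
            if not use_lengths:
                return ""
            return f":{self.edge_changes.get(frozenset((u, v)), 0):g}"

        if self.n_leaves == 2:
            a, b = self.leaf_nodes
            e = frozenset((a, b))
            c = self.edge_changes.get(e, 0) if use_lengths else None
            if use_lengths:
                return f"({self.labels[a]}:0,{self.labels[b]}:{c:g});"
            return f"({self.labels[a]},{self.labels[b]});"

        if root_label is None:
            root_label = min(self.labels.values())
        root_leaf = self.node_by_label(root_label)
        anchor = self.adj[root_leaf][0]

        def render(node: int, par: int) -> str:
            if node in self.labels:
                return self.labels[node] + blen(node, par)
            parts = [render(nbr, node) for nbr in self.adj[node] if nbr != par]
            return "(" + ",".join(parts) + ")" + blen(node, par)

        children = [render(root_leaf, anchor)]
        children += [render(nbr, anchor) for nbr in self.adj[anchor] if nbr != root_leaf]
        return "(" + ",".join(children) + ");"


def enumerate_topologies(
    labels: Sequence[str], cap: int = DEFAULT_LEAF_CAP
) -> Iterator[PhyloTree]:
    """Yield every unrooted binary topology on ``labels`` exactly once.

    Generation is by stepwise leaf addition: the k-th leaf is attached to
    each edge of each (k-1)-leaf topology, which produces each topology once
    and gives the classic (2n-5)!! count.
    """
    n = len(labels)
    if n < 2:
        raise ValidationError("need at least 2 leaves")
    if n > cap:
        raise ValidationError(
            f"{n} leaves exceeds the exhaustive-enumeration cap of {cap}; "
            f"raise the cap explicitly if this size is intentional"
        )
    label_map = dict(enumerate(labels))
    if n == 2:
        yield PhyloTree([(0, 1)], label_map)
        return

    def gen(k: int) -> Iterator[List[Tuple[int, int]]]:
        if k == 3:
            yield [(0, n), (1, n), (2, n)]
            return
        new_internal = n + k - 3
        new_leaf = k - 1
        for edges in gen(k - 1):
            for i in range(len(edges)):
                u, v = edges[i]
                yield edges[:i] + edges[i + 1:] + [
                    (u, new_internal),
                    (v, new_internal),
                    (new_leaf, new_internal),
                ]

    for edges in gen(n):
        yield PhyloTree(edges, label_map)


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Strict consensus: the (possibly multifurcating) tree whose
    bipartitions are exactly those shared by every input tree."""
    if not trees:
        raise ValidationError("empty tree list")
    leafset = frozenset(trees[0].labels.values())
    for t in trees[1:]:
        if frozenset(t.labels.values()) != leafset:
            raise ValidationError("trees have mismatched leaf sets")
    shared = trees[0].bipartitions()
    for t in trees[1:]:
        shared = shared & t.bipartitions()

    labels = sorted(leafset)
    label_node = {lab: i for i, lab in enumerate(labels)}
    center = len(labels)
    next_id = center + 1
    # children of the center: (node id, leaf-label set it spans)
    children: List[Tuple[int, FrozenSet[str]]] = [
        (label_node[lab], frozenset([lab])) for lab in labels
    ]
    edges: List[Tuple[int, int]] = []
    # nested grouping: smaller bipartition sides first
    for bip in sorted(shared, key=len):
        inside = [(nid, ls) for nid, ls in children if ls <= bip]
        covered = frozenset().union(*(ls for _, ls in inside)) if inside else frozenset()
        if covered != bip:  # incompatible with groups built so far (cannot happen
            continue        # for bipartitions drawn from a single tree's set)
        node = next_id
        next_id += 1
        for nid, _ in inside:
            edges.append((nid, node))
        children = [(nid, ls) for nid, ls in children if not ls <= bip]
        children.append((node, bip))
    for nid, _ in children:
        edges.append((nid, center))
    return PhyloTree(edges, {label_node[lab]: lab for lab in labels})
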