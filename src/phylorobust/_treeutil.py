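"""Low-level tree algorithms shared across modules.

Everything here works on the *unrooted* topology of a dendropy tree: a
rooted bifurcation at the seed node is merged into a single edge first, so
metrics and bipartitions do not depend on where the file happened to root
the tree.  Bipartitions are represented as integer bitmasks over a caller
supplied label -> bit index mapping, canonicalized as ``min(mask, full ^
mask)`` so that a split and its complement compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class Edge:
    """One edge of the unrooted topology.

    ``mask`` is the leaf bitmask of the side that was below the edge in the
    traversal; ``length`` the branch length (0 when absent in the file);
    ``head_id``/``tail_id`` index into the adjacency table, head on the mask
    side.
    """

    mask: int
    length: float
    head_id: int
    tail_id: int


@dataclass
class UnrootedView:
    labels: list[str]
    index: dict[str, int]
    full_mask: int
    edges: list[Edge]
    adjacency: dict[int, list[tuple[int, float]]]
    leaf_node_ids: dict[str, int]

    def split_masks(self, *, include_trivial: bool = True) -> set[int]:
        out = set()
        for e in self.edges:
            pop = bin(e.mask).count("1")
            if not include_trivial and not (2 <= pop <= len(self.labels) - 2):
                continue
            out.add(canonical(e.mask, self.full_mask))
        return out


def canonical(mask: int, full: int) -> int:
    other = full & ~mask
    return mask if mask < other else other


def unrooted_view(
    tree: dendropy.Tree,
    index: dict[str, int] | None = None,
    *,
    merge_root: bool = True,
) -> UnrootedView:
    """Build adjacency + edge/bipartition tables for the unrooted topology.

    With ``merge_root=True`` a rooted bifurcation at the seed is merged into
    one edge (topology-invariant metrics); ``merge_root=False`` keeps the
    two root edges distinct, which outgroup rooting needs so that the
    outgroup's own stem edge retains its written length.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    if index is None:
        index = {l: i for i, l in enumerate(sorted(labels))}
    full_mask = 0
    for l in labels:
        full_mask |= 1 << index[l]

    seed = tree.seed_node
    children = seed.child_nodes()
    merge = merge_root and len(children) == 2  # rooted bifurcation -> one edge

    node_ids: dict[int, int] = {}

    def nid(node) -> int:
        key = id(node)
        if key not in node_ids:
            node_ids[key] = len(node_ids)
        return node_ids[key]

    adjacency: dict[int, list[tuple[int, float]]] = {}
    edges: list[Edge] = []

    def add_adj(a: int, b: int, ln: float) -> None:
        adjacency.setdefault(a, []).append((b, ln))
        adjacency.setdefault(b, []).append((a, ln))

    masks: dict[int, int] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            masks[id(nd)] = 1 << index[nd.taxon.label]
        else:
            m = 0
            for ch in nd.child_nodes():
                m |= masks[id(ch)]
            masks[id(nd)] = m

    for nd in tree.preorder_node_iter():
        if nd is seed:
            continue
        parent = nd.parent_node
        ln = nd.edge.length or 0.0
        if merge and parent is seed:
            continue  # handled below as a single merged edge
        add_adj(nid(parent), nid(nd), ln)
        edges.append(Edge(mask=masks[id(nd)], length=ln, head_id=nid(nd), tail_id=nid(parent)))

    if merge:
        u, v = children
        ln = (u.edge.length or 0.0) + (v.edge.length or 0.0)
        add_adj(nid(u), nid(v), ln)
        edges.append(Edge(mask=masks[id(u)], length=ln, head_id=nid(u), tail_id=nid(v)))

    leaf_node_ids = {lf.taxon.label: nid(lf) for lf in leaves}
    # make sure isolated (single-node) adjacency entries exist
    for l, i in leaf_node_ids.items():
        adjacency.setdefault(i, [])
    return UnrootedView(
        labels=labels,
        index=index,
        full_mask=full_mask,
        edges=edges,
        adjacency=adjacency,
        leaf_node_ids=leaf_node_ids,
    )


def _distances_from(view: UnrootedView, start: int, *, unit: bool, blocked=None) -> dict[int, float]:
    """Dijkstra-free tree distance by DFS (trees have unique paths)."""
    dist = {start: 0.0}
    stack = [start]
    while stack:
        a = stack.pop()
        for b, ln in view.adjacency[a]:
            if b in dist:
                continue
            if blocked is not None and (a, b) in blocked:
                continue
            dist[b] = dist[a] + (1.0 if unit else ln)
            stack.append(b)
    return dist


def leaf_distance_matrix(
    tree: dendropy.Tree, index: dict[str, int], *, unit: bool = False
) -> np.ndarray:
    """(n, n) path-length matrix over the label universe ``index``.

    Entries for labels absent from the tree are NaN.
    """
    n = len(index)
    D = np.full((n, n), np.nan)
    view = unrooted_view(tree, index)
    for label, node_id in view.leaf_node_ids.items():
        d = _distances_from(view, node_id, unit=unit)
        i = index[label]
        D[i, i] = 0.0
        for other, oid in view.leaf_node_ids.items():
            D[i, index[other]] = d[oid]
    return D


def tree_length(tree: dendropy.Tree) -> float:
    view = unrooted_view(tree)
    return float(sum(e.length for e in view.edges))


def internal_length(tree: dendropy.Tree) -> float:
    view = unrooted_view(tree)
    n = len(view.labels)
    return float(
        sum(e.length for e in view.edges if 2 <= bin(e.mask).count("1") <= n - 2)
    )


def find_split_edge(view: UnrootedView, mask: int) -> Edge | None:
    """Edge realizing the given split; prefers the edge whose below-side is
    exactly ``mask`` (the clade's own stem) over a complement match."""
    want = canonical(mask, view.full_mask)
    fallback = None
    for e in view.edges:
        if e.mask == mask:
            return e
        if canonical(e.mask, view.full_mask) == want and fallback is None:
            fallback = e
    return fallback


def root_to_tip_from_edge(view: UnrootedView, edge: Edge) -> dict[str, float]:
    """Distances from the midpoint of ``edge`` to every leaf label."""
    by_node = _root_to_tip_node_distances(view, edge.head_id, edge.tail_id, edge.length)
    return {label: by_node[nid] for label, nid in view.leaf_node_ids.items()}


def _root_to_tip_node_distances(
    view: UnrootedView, head_id: int, tail_id: int, length: float
) -> dict[int, float]:
    half = length / 2.0
    blocked = {(head_id, tail_id), (tail_id, head_id)}
    d_head = _distances_from(view, head_id, unit=False, blocked=blocked)
    d_tail = _distances_from(view, tail_id, unit=False, blocked=blocked)
    out: dict[int, float] = {}
    for node, d in d_head.items():
        out[node] = d + half
    for node, d in d_tail.items():
        out[node] = d + half
    return out


def prune_taxa(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Copy of ``tree`` with the given leaves removed.

    Degree-2 nodes created by the pruning are suppressed and their branch
    lengths summed (dendropy semantics).
    """
    t = tree.clone(depth=1)
    labels = [l for l in labels]
    if labels:
        taxa = [t.taxon_namespace.get_taxon(l) for l in labels]
        missing = [l for l, tx in zip(labels, taxa) if tx is None]
        if missing:
            raise ValueError(f"taxa not in tree: {missing}")
        t.prune_taxa(taxa, suppress_unifurcations=True)
    return t


def regraft_leaf(tree: dendropy.Tree, label: str, rng: np.random.Generator) -> dendropy.Tree:
    """Prune leaf ``label`` and reattach it at the midpoint of a random edge."""
    leaf_nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    if label not in leaf_nodes:
        raise ValueError(f"taxon not in tree: {label!r}")
    pendant = leaf_nodes[label].edge.length or 0.0
    t = prune_taxa(tree, [label])
    # candidate attachment edges: every non-seed node's subtending edge
    nodes = [nd for nd in t.preorder_node_iter() if nd.parent_node is not None]
    target = nodes[int(rng.integers(len(nodes)))]
    parent = target.parent_node
    ln = target.edge.length or 0.0
    parent.remove_child(target)
    knee = parent.new_child(edge_length=ln / 2.0)
    target.edge.length = ln / 2.0
    knee.add_child(target)
    taxon = t.taxon_namespace.get_taxon(label)
    if taxon is None:
        taxon = t.taxon_namespace.new_taxon(label)
    knee.new_child(taxon=taxon, edge_length=pendant)
    return t
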