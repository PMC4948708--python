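"""Comparison-driven layout algorithms.

Best-corresponding rooting, branch-swap leaf ordering, viewport-driven
collapsing, path expansion, leaf search and cross-tree highlighting.  All
operations are functional: they return new trees / new :class:`VizState`
instances and never mutate their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .comparison import CladeScorer, ComparisonResult, bcn_fast, compare, prepare_pair
from .errors import LeafSetMismatchError, StructureError, ValidationError
from .tree_model import Tree, TreeNode, reroot

_TIE_EPS = 1e-12


@dataclass
class VizState:
    """Collapsed / highlighted node sets plus viewport parameters.

    A node in ``collapsed`` is itself visible (drawn as a triangle stub);
    its descendants are hidden.  Visible and hidden node sets always
    partition the tree's nodes.
    """

    collapsed: Set[TreeNode] = field(default_factory=set)
    highlighted: Set[TreeNode] = field(default_factory=set)
    viewport: Tuple[int, int] = (1024, 768)
    label_height_px: int = 12

    def copy(self) -> "VizState":
        return VizState(
            set(self.collapsed), set(self.highlighted), self.viewport, self.label_height_px
        )


def visible_nodes(tree: Tree, state: VizState) -> List[TreeNode]:
    """Nodes reachable from the root without descending into a collapsed
    node, in display (preorder) order."""
    out: List[TreeNode] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        out.append(node)
        if node not in state.collapsed:
            stack.extend(reversed(node.children))
    return out


def hidden_nodes(tree: Tree, state: VizState) -> List[TreeNode]:
    vis = set(visible_nodes(tree, state))
    return [n for n in tree.root.preorder() if n not in vis]


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------


def _visible_rows_at_depth(tree: Tree, d: int) -> int:
    # rows = leaves at depth <= d plus collapsed stubs (internal nodes) at depth d
    rows = 0
    for node, depth in tree.depths().items():
        if node.is_leaf and depth <= d:
            rows += 1
        elif not node.is_leaf and depth == d:
            rows += 1
    return rows


def estimate_collapse_depth(tree: Tree, state: VizState) -> int:
    """Largest depth d >= 1 such that the visible rows (leaves plus stubs)
    still fit into the viewport height at one label height per row; 1 when
    even the shallowest view overflows."""
    width, height = state.viewport
    if width <= 0 or height <= 0 or state.label_height_px <= 0:
        raise ValidationError("viewport dimensions and label height must be positive")
    max_depth = max(max(tree.depths().values()), 1)
    best = 1
    for d in range(1, max_depth + 1):
        if _visible_rows_at_depth(tree, d) * state.label_height_px <= height:
            best = d
        else:
            break
    return best


def collapse_at_depth(tree: Tree, state: VizState, d: int) -> VizState:
    """Collapse every internal node sitting exactly at depth ``d``."""
    if d < 1:
        raise ValidationError("collapse depth must be >= 1")
    new = state.copy()
    new.collapsed = {
        node for node, depth in tree.depths().items() if depth == d and not node.is_leaf
    }
    return new


def expand_path_to(tree: Tree, state: VizState, target: TreeNode) -> VizState:
    """Expand exactly the collapsed strict ancestors of ``target`` so that
    it becomes visible; no other collapsed node is touched."""
    if not tree.contains(target):
        raise StructureError("target node is not part of the tree")
    ancestors = set(target.ancestors())
    new = state.copy()
    new.collapsed = {n for n in state.collapsed if n not in ancestors}
    return new


def search_leaf(tree: Tree, query_label: str) -> List[TreeNode]:
    """Root-to-leaf path for an exact label match; empty list if absent."""
    leaf = tree.find_leaf(query_label)
    if leaf is None:
        return []
    path = [leaf, *leaf.ancestors()]
    path.reverse()
    return path


# ---------------------------------------------------------------------------
# best rooting
# ---------------------------------------------------------------------------


def _rooting_aggregates(
    reference: Tree, query: Tree
) -> Tuple[float, List[Tuple[Tuple[TreeNode, TreeNode], float]]]:
    """Aggregate BCN score of every rooting of ``query`` against
    ``reference``, computed with one pair of sweeps over the unrooted tree.

    For each directed edge (u -> v) of the unrooted topology, A(u->v) sums
    the best clade score of every internal vertex on v's side (each scored
    on its away-from-u leaf set); rooting on edge {u,v} then has aggregate
    (A(u->v) + A(v->u)) / (count(u->v) + count(v->u)) — exactly the mean
    BCN score over internal non-root nodes of the rerooted tree.
    """
    scorer = CladeScorer(reference)
    root = query.root
    n = len(query.leaf_index)
    full = (1 << n) - 1
    binary_root = len(root.children) == 2

    adj: Dict[TreeNode, List[TreeNode]] = {}
    rooted_edges: List[Tuple[TreeNode, TreeNode]] = []
    for node in query.root.preorder():
        if node.parent is None:
            continue
        rooted_edges.append((node.parent, node))
        if binary_root and node.parent is root:
            continue
        adj.setdefault(node.parent, []).append(node)
        adj.setdefault(node, []).append(node.parent)
    if binary_root:
        c1, c2 = root.children
        adj.setdefault(c1, []).append(c2)
        adj.setdefault(c2, []).append(c1)

    def side_fp(u: TreeNode, v: TreeNode) -> int:
        # leaf set on v's side of the edge {u, v}
        if v.parent is u:
            return v.fingerprint
        return full ^ u.fingerprint

    def val(u: TreeNode, v: TreeNode) -> Tuple[float, int]:
        fp = side_fp(u, v)
        if fp.bit_count() < 2:
            return 0.0, 0
        return scorer.best_score(fp), 1

    if not adj:  # <= 2 leaves: nothing to aggregate over
        cur = compare(query, reference).aggregate
        return cur, []

    anchor = root.children[0] if binary_root else root
    parent0: Dict[TreeNode, Optional[TreeNode]] = {}
    order: List[TreeNode] = []
    stack: List[Tuple[TreeNode, Optional[TreeNode]]] = [(anchor, None)]
    while stack:
        v, pu = stack.pop()
        parent0[v] = pu
        order.append(v)
        for w in adj[v]:
            if w is not pu:
                stack.append((w, v))

    A: Dict[Tuple[int, int], float] = {}
    C: Dict[Tuple[int, int], int] = {}
    for v in reversed(order):  # downward directed edges, children first
        pu = parent0[v]
        if pu is None:
            continue
        s, cnt = val(pu, v)
        for w in adj[v]:
            if w is not pu:
                s += A[(id(v), id(w))]
                cnt += C[(id(v), id(w))]
        A[(id(pu), id(v))] = s
        C[(id(pu), id(v))] = cnt
    for v in order[1:]:  # upward directed edges, parents first
        pu = parent0[v]
        s, cnt = val(v, pu)
        for x in adj[pu]:
            if x is v:
                continue
            s += A[(id(pu), id(x))]
            cnt += C[(id(pu), id(x))]
        A[(id(v), id(pu))] = s
        C[(id(v), id(pu))] = cnt

    def edge_agg(u: TreeNode, v: TreeNode) -> float:
        s = A[(id(u), id(v))] + A[(id(v), id(u))]
        cnt = C[(id(u), id(v))] + C[(id(v), id(u))]
        return s / cnt if cnt else 1.0

    if binary_root:
        c1, c2 = root.children
        current = edge_agg(c1, c2)
    else:
        s = sum(A[(id(root), id(c))] for c in root.children)
        cnt = sum(C[(id(root), id(c))] for c in root.children)
        current = s / cnt if cnt else 1.0

    candidates = [
        ((p, c), edge_agg(p, c))
        for p, c in rooted_edges
        if not (binary_root and p is root)
    ]
    return current, candidates


def best_rooting(reference: Tree, query: Tree) -> Tree:
    """Reroot ``query`` on the edge maximizing the aggregate BCN score
    against ``reference``; the current rooting is kept when already optimal,
    and ties go to the edge whose child has the smallest preorder index."""
    prepare_pair(query, reference)
    if any(len(n.children) == 1 for n in query.root.preorder()):
        return _best_rooting_naive(reference, query)
    current, candidates = _rooting_aggregates(reference, query)
    best_edge = None
    best = current
    for edge, agg in candidates:  # already ordered by child preorder index
        if agg > best + _TIE_EPS:
            best = agg
            best_edge = edge
    if best_edge is None:
        return query
    return reroot(query, best_edge)


def _best_rooting_naive(reference: Tree, query: Tree) -> Tree:
    """Literal enumeration: reroot on every edge and run a full comparison.
    Reference implementation for the shared-sweep version above."""
    prepare_pair(query, reference)
    best_tree = None
    best = compare(query, reference).aggregate
    for edge in query.edges():
        candidate = reroot(query, edge)
        agg = compare(candidate, reference).aggregate
        if agg > best + _TIE_EPS:
            best = agg
            best_tree = candidate
    return best_tree if best_tree is not None else query


# ---------------------------------------------------------------------------
# leaf-order optimization
# ---------------------------------------------------------------------------


def _count_inversions(seq: List[int]) -> int:
    # merge-sort inversion count
    if len(seq) < 2:
        return 0
    mid = len(seq) // 2
    left, right = seq[:mid], seq[mid:]
    inv = _count_inversions(left) + _count_inversions(right)
    merged = []
    i = j = 0
    while i < len(left) and j < len(right):
        if left[i] <= right[j]:
            merged.append(left[i])
            i += 1
        else:
            merged.append(right[j])
            j += 1
            inv += len(left) - i
    seq[:] = merged + left[i:] + right[j:]
    return inv


def leaf_order_distance(reference: Tree, query: Tree) -> int:
    """Number of discordant leaf pairs (Kendall-tau distance) between the
    display leaf orders of the two trees."""
    if reference.leaf_labels() != query.leaf_labels():
        l1, l2 = reference.leaf_labels(), query.leaf_labels()
        raise LeafSetMismatchError(sorted(l1 - l2), sorted(l2 - l1))
    rank = {leaf.label: i for i, leaf in enumerate(reference.leaves())}
    seq = [rank[leaf.label] for leaf in query.leaves()]
    return _count_inversions(seq)


def optimize_leaf_order(reference: Tree, query: Tree) -> Tree:
    """Permute children of ``query``'s internal nodes (barycenter heuristic:
    order children by mean reference-rank of their leaves, bottom-up) to
    reduce the discordant-pair objective.  Topology is unchanged and the
    objective never increases; on same-topology pairs it reaches 0."""
    if reference.leaf_labels() != query.leaf_labels():
        l1, l2 = reference.leaf_labels(), query.leaf_labels()
        raise LeafSetMismatchError(sorted(l1 - l2), sorted(l2 - l1))
    rank = {leaf.label: i for i, leaf in enumerate(reference.leaves())}
    before = leaf_order_distance(reference, query)
    result = query.copy()
    rank_sum: Dict[TreeNode, Tuple[float, int]] = {}
    for node in result.root.postorder():
        if node.is_leaf:
            rank_sum[node] = (float(rank[node.label]), 1)
        else:
            keyed = sorted(
                node.children,
                key=lambda c: (rank_sum[c][0] / rank_sum[c][1], c.preorder_index),
            )
            node.children = keyed
            total = sum(rank_sum[c][0] for c in keyed)
            count = sum(rank_sum[c][1] for c in keyed)
            rank_sum[node] = (total, count)
    result.rebuild()
    if leaf_order_distance(reference, result) > before:
        return query.copy()
    return result


# ---------------------------------------------------------------------------
# highlighting
# ---------------------------------------------------------------------------


def highlight_subtree(
    t1: Tree,
    t2: Tree,
    cmp: ComparisonResult,
    node: TreeNode,
    state1: VizState,
    state2: VizState,
) -> Tuple[VizState, VizState]:
    """Highlight ``node``'s subtree in tree 1 and its BCN's subtree in
    tree 2, expanding any collapsed ancestors so the BCN becomes visible.
    The BCN is computed lazily when ``cmp`` does not cover ``node`` yet."""
    if not t1.contains(node):
        raise StructureError("node is not part of the first tree")
    if node not in cmp.bcn:
        extra = bcn_fast(t1, t2, restrict_to=[node])
        cmp.scores.update(extra.scores)
        cmp.bcn.update(extra.bcn)
    counterpart = cmp.bcn[node]
    new1 = state1.copy()
    new1.highlighted |= set(node.preorder())
    new2 = state2.copy()
    new2.highlighted |= set(counterpart.preorder())
    new2 = expand_path_to(t2, new2, counterpart)
    return new1, new2
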