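"""Core rooted-tree data structures and structural operations.

Trees are rooted and ordered; polytomies and (when parsed from permissive
Newick) unary internal nodes are allowed.  Every node can carry a *leaf
fingerprint*: a bitset over a leaf index (label -> bit position), stored as
an arbitrary-precision integer so that intersection and union cardinalities
of leaf sets reduce to machine-word ``&``/``|`` plus a popcount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

from .errors import StructureError, ValidationError


class TreeNode:
    """A single node: label, branch length, support, ordered children.

    ``branch_length`` / ``support`` are ``None`` when absent in the source;
    absence is distinct from zero.  ``fingerprint`` is only meaningful after
    :func:`compute_fingerprints` has been run over the enclosing tree.
    """

    __slots__ = (
        "label",
        "length",
        "support",
        "children",
        "parent",
        "preorder_index",
        "fingerprint",
        "fp_size",
        "index_token",
        "annotations",
    )

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
        children: Optional[Iterable["TreeNode"]] = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: List[TreeNode] = list(children) if children is not None else []
        self.parent: Optional[TreeNode] = None
        self.preorder_index: int = -1
        self.fingerprint: int = 0
        self.fp_size: int = 0
        self.index_token: Optional[object] = None
        self.annotations: Dict[str, str] = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        """Yield this node and all descendants, parent before children,
        children in display order (top to bottom)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        """Yield all descendants before their parents (children in order)."""
        out: List[TreeNode] = []
        stack: List[TreeNode] = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> List["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def ancestors(self) -> Iterator["TreeNode"]:
        """Yield parent, grandparent, ... up to and including the root."""
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<TreeNode {self.label!r} {kind} pre={self.preorder_index}>"


class Tree:
    """A rooted tree plus a stable bijection leaf label -> integer index.

    Construction validates that every leaf carries a unique, non-empty label
    and (re)assigns parent pointers and preorder numbering.
    """

    __slots__ = ("root", "leaf_index", "index_token")

    def __init__(self, root: TreeNode, leaf_index: Optional[Mapping[str, int]] = None):
        self.root = root
        self.index_token: Optional[object] = None
        self.rebuild()
        leaves = self.leaves()
        seen: Dict[str, TreeNode] = {}
        for leaf in leaves:
            if leaf.label is None or leaf.label == "":
                raise ValidationError("tree contains an unlabeled leaf")
            if leaf.label in seen:
                raise ValidationError(f"duplicate leaf label: {leaf.label!r}")
            seen[leaf.label] = leaf
        if leaf_index is None:
            self.leaf_index: Dict[str, int] = {
                leaf.label: i for i, leaf in enumerate(leaves)
            }
        else:
            if set(leaf_index) != set(seen):
                raise ValidationError("leaf_index does not cover exactly the tree's leaves")
            self.leaf_index = dict(leaf_index)

    # -- bookkeeping ---------------------------------------------------

    def rebuild(self) -> None:
        """Reassign parent pointers and preorder indices; invalidates any
        previously computed fingerprints."""
        self.root.parent = None
        for i, node in enumerate(self.root.preorder()):
            node.preorder_index = i
            for child in node.children:
                child.parent = node
        self.index_token = None

    # -- accessors -----------------------------------------------------

    def nodes(self) -> List[TreeNode]:
        return list(self.root.preorder())

    def leaves(self) -> List[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> FrozenSet[str]:
        return frozenset(leaf.label for leaf in self.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_index)

    def edges(self) -> List[Tuple[TreeNode, TreeNode]]:
        """All (parent, child) pairs in preorder of the child."""
        return [(n.parent, n) for n in self.root.preorder() if n.parent is not None]

    def find_leaf(self, label: str) -> Optional[TreeNode]:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        return None

    def contains(self, node: TreeNode) -> bool:
        while node.parent is not None:
            node = node.parent
        return node is self.root

    def depths(self) -> Dict[TreeNode, int]:
        """Edge-count depth per node; the root has depth 0."""
        depth = {self.root: 0}
        for node in self.root.preorder():
            for child in node.children:
                depth[child] = depth[node] + 1
        return depth

    # -- copying -------------------------------------------------------

    def copy_with_map(self) -> Tuple["Tree", Dict[int, TreeNode]]:
        """Deep copy; returns the copy and a map id(old node) -> new node."""
        mapping: Dict[int, TreeNode] = {}

        def shallow(n: TreeNode) -> TreeNode:
            c = TreeNode(n.label, n.length, n.support)
            c.annotations = dict(n.annotations)
            mapping[id(n)] = c
            return c

        new_root = shallow(self.root)
        stack = [(self.root, new_root)]
        while stack:
            old, new = stack.pop()
            for child in old.children:
                nc = shallow(child)
                new.children.append(nc)
                stack.append((child, nc))
        return Tree(new_root, leaf_index=self.leaf_index), mapping

    def copy(self) -> "Tree":
        return self.copy_with_map()[0]


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------


def compute_fingerprints(
    tree: Tree,
    leaf_index: Optional[Mapping[str, int]] = None,
    token: Optional[object] = None,
) -> Tree:
    """Fill in every node's leaf-set bitset in one post-order pass.

    ``leaf_index`` defaults to the tree's own index; pass a shared index and
    a shared ``token`` to make two trees' fingerprints comparable.
    """
    index = tree.leaf_index if leaf_index is None else leaf_index
    tok = token if token is not None else object()
    for node in tree.root.postorder():
        if node.is_leaf:
            try:
                node.fingerprint = 1 << index[node.label]
            except KeyError:
                raise ValidationError(
                    f"leaf label {node.label!r} missing from the leaf index"
                ) from None
        else:
            fp = 0
            for child in node.children:
                fp |= child.fingerprint
            node.fingerprint = fp
        node.fp_size = node.fingerprint.bit_count()
        node.index_token = tok
    tree.index_token = tok
    return tree


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Split:
    """A non-trivial bipartition of the leaf index, canonicalized so that
    the bit of leaf 0 is on the unrepresented side."""

    side: int
    n_leaves: int


def splits(tree: Tree, leaf_index: Optional[Mapping[str, int]] = None) -> FrozenSet[Split]:
    """The set of non-trivial splits (one per internal edge).

    Two trees on the same leaf index have equal unrooted topology iff their
    split sets are equal.  Does not disturb stored fingerprints.
    """
    index = tree.leaf_index if leaf_index is None else leaf_index
    n = len(index)
    full = (1 << n) - 1
    fp: Dict[int, int] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            fp[id(node)] = 1 << index[node.label]
        else:
            acc = 0
            for child in node.children:
                acc |= fp[id(child)]
            fp[id(node)] = acc
    out = set()
    for node in tree.root.preorder():
        if node.parent is None or node.is_leaf:
            continue
        side = fp[id(node)]
        if side & 1:
            side = full ^ side
        size = side.bit_count()
        if 2 <= size <= n - 2:
            out.add(Split(side, n))
    return frozenset(out)


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------


def swap_children(node: TreeNode, permutation: Sequence[int]) -> TreeNode:
    """Reorder ``node``'s children in place by the given permutation."""
    perm = list(permutation)
    if sorted(perm) != list(range(len(node.children))):
        raise StructureError(
            f"invalid permutation {perm!r} for a node with {len(node.children)} children"
        )
    node.children = [node.children[i] for i in perm]
    return node


def _combine_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None:
        return b
    if b is None:
        return a
    return a + b


def reroot(tree: Tree, edge: Tuple[TreeNode, TreeNode]) -> Tree:
    """Return a new tree rooted on ``edge`` = (parent, child) of ``tree``.

    The new root subdivides the edge at its midpoint (both halves ``None``
    when the length is absent).  A former root left with a single child is
    suppressed and its two incident branch lengths summed.  The unrooted
    topology (split set) and all leaf-to-leaf path lengths are preserved.
    """
    parent, child = edge
    new_tree, mapping = tree.copy_with_map()
    p = mapping.get(id(parent))
    c = mapping.get(id(child))
    if p is None or c is None or c.parent is not p:
        raise StructureError("edge is not part of the tree")

    if c.length is None:
        half = None
    else:
        half = c.length / 2.0
    edge_support = c.support

    # ancestor chain from p up to the old root, recording each node's
    # (length, support) for the edge to its former parent before mutation
    chain = [p]
    while chain[-1].parent is not None:
        chain.append(chain[-1].parent)
    old_len = [a.length for a in chain]
    old_sup = [a.support for a in chain]

    p.children.remove(c)
    for i in range(len(chain) - 1):
        a, b = chain[i], chain[i + 1]
        b.children.remove(a)
        a.children.append(b)
    for i in range(1, len(chain)):
        chain[i].length = old_len[i - 1]
        chain[i].support = old_sup[i - 1]

    new_root = TreeNode()
    c.length = half
    c.support = edge_support
    p.length = half
    p.support = edge_support
    new_root.children = [c, p]

    old_root = chain[-1]
    if len(old_root.children) == 1:
        only = old_root.children[0]
        holder = chain[-2] if len(chain) >= 2 else new_root
        idx = holder.children.index(old_root)
        only.length = _combine_lengths(only.length, old_root.length)
        if only.support is None:
            only.support = old_root.support
        holder.children[idx] = only

    result = Tree(new_root, leaf_index=tree.leaf_index)
    return result


# ---------------------------------------------------------------------------
# distances (test/oracle utility)
# ---------------------------------------------------------------------------


def leaf_distances(tree: Tree) -> Dict[FrozenSet[str], float]:
    """Path length between every pair of leaves (absent lengths count 0)."""
    root = tree.root
    dist_to_root: Dict[int, float] = {id(root): 0.0}
    anc_sets: Dict[int, set] = {id(root): {id(root)}}
    for node in root.preorder():
        for child in node.children:
            step = child.length if child.length is not None else 0.0
            dist_to_root[id(child)] = dist_to_root[id(node)] + step
            anc_sets[id(child)] = anc_sets[id(node)] | {id(child)}
    depthmap = {id(n): d for n, d in tree.depths().items()}
    leaves = tree.leaves()
    out: Dict[FrozenSet[str], float] = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            common = anc_sets[id(a)] & anc_sets[id(b)]
            lca = max(common, key=lambda nid: depthmap[nid])
            d = dist_to_root[id(a)] + dist_to_root[id(b)] - 2.0 * dist_to_root[lca]
            out[frozenset((a.label, b.label))] = d
    return out
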