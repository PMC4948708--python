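"""Per-node leaf-set similarity between two trees on the same taxa.

For every node ``n`` of one tree the *best corresponding node* (BCN) in the
other tree is the node ``m`` maximizing the Jaccard similarity of the leaf
sets below ``n`` and ``m``.  Two interchangeable implementations exist:

* :func:`bcn_oracle` — exhaustive O(n^2) pairing; slow, obviously correct.
* :func:`bcn_fast` — for each query node, walks from the matching leaves of
  the other tree toward its root, accumulating intersection counts, so only
  ancestors of shared leaves are ever scored.  Supports lazy evaluation of
  a restricted node set.

Ties in the argmax are broken deterministically: larger intersection first,
then smaller candidate leaf set, then smaller preorder index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, Tuple

import numpy as np

from .errors import LeafSetMismatchError, ValidationError
from .tree_model import Tree, TreeNode, compute_fingerprints


def prepare_pair(t1: Tree, t2: Tree) -> None:
    """Validate identical leaf-label sets and compute both trees'
    fingerprints over one shared leaf index (sorted labels)."""
    if (
        t1.index_token is not None
        and t1.index_token is t2.index_token
    ):
        return
    l1, l2 = t1.leaf_labels(), t2.leaf_labels()
    if l1 != l2:
        raise LeafSetMismatchError(sorted(l1 - l2), sorted(l2 - l1))
    index = {label: i for i, label in enumerate(sorted(l1))}
    token = object()
    compute_fingerprints(t1, index, token)
    compute_fingerprints(t2, index, token)


def similarity(a: TreeNode, b: TreeNode) -> float:
    """Jaccard index |L(a) & L(b)| / |L(a) | L(b)| of two leaf fingerprints."""
    if a.index_token is None or a.index_token is not b.index_token:
        raise ValidationError("fingerprints were not computed over a shared leaf index")
    inter = (a.fingerprint & b.fingerprint).bit_count()
    union = a.fp_size + b.fp_size - inter
    return inter / union


@dataclass
class ComparisonResult:
    """Scores and BCN mappings for (a subset of) the nodes of two trees."""

    tree1: Tree
    tree2: Tree
    scores: Dict[TreeNode, float] = field(default_factory=dict)
    bcn: Dict[TreeNode, TreeNode] = field(default_factory=dict)
    aggregate: Optional[float] = None

    @property
    def computed_nodes(self) -> Set[TreeNode]:
        return set(self.scores)

    def score(self, node: TreeNode) -> float:
        return self.scores[node]

    def bcn_of(self, node: TreeNode) -> TreeNode:
        return self.bcn[node]


def _aggregate_over(t1: Tree, scores: Dict[TreeNode, float]) -> float:
    vals = [
        scores[n]
        for n in t1.root.preorder()
        if n.parent is not None and not n.is_leaf
    ]
    return sum(vals) / len(vals) if vals else 1.0


def _argmax_key(score: float, inter: int, m: TreeNode) -> Tuple[float, int, int, int]:
    return (score, inter, -m.fp_size, -m.preorder_index)


def bcn_oracle(t1: Tree, t2: Tree) -> ComparisonResult:
    """Exhaustive all-pairs BCN computation (correctness reference)."""
    prepare_pair(t1, t2)
    result = ComparisonResult(t1, t2)
    for src, dst in ((t1, t2), (t2, t1)):
        dst_nodes = list(dst.root.preorder())
        for n in src.root.preorder():
            best = None
            best_key = None
            fp_n = n.fingerprint
            size_n = n.fp_size
            for m in dst_nodes:
                inter = (fp_n & m.fingerprint).bit_count()
                s = inter / (size_n + m.fp_size - inter)
                key = _argmax_key(s, inter, m)
                if best_key is None or key > best_key:
                    best_key = key
                    best = m
            result.scores[n] = best_key[0]
            result.bcn[n] = best
    result.aggregate = _aggregate_over(t1, result.scores)
    return result


def _leaves_under(node: TreeNode) -> Iterable[TreeNode]:
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def _best_in_other(node: TreeNode, other_leaf: Dict[str, TreeNode]) -> Tuple[TreeNode, float]:
    # One upward pass per leaf below `node`: every visited node of the other
    # tree is an ancestor of a shared leaf, and its visit count equals the
    # intersection cardinality.
    counts: Dict[TreeNode, int] = {}
    for leaf in _leaves_under(node):
        m = other_leaf[leaf.label]
        while m is not None:
            counts[m] = counts.get(m, 0) + 1
            m = m.parent
    size_n = node.fp_size
    best = None
    best_key = None
    for m, inter in counts.items():
        s = inter / (size_n + m.fp_size - inter)
        key = _argmax_key(s, inter, m)
        if best_key is None or key > best_key:
            best_key = key
            best = m
    return best, best_key[0]


def bcn_fast(
    t1: Tree,
    t2: Tree,
    restrict_to: Optional[Iterable[TreeNode]] = None,
) -> ComparisonResult:
    """Optimized BCN computation; identical output to :func:`bcn_oracle`.

    With ``restrict_to`` only the listed nodes (from either tree) are
    scored and no aggregate is produced — the lazy-evaluation contract used
    by the renderer, which only needs scores for currently visible nodes.
    """
    prepare_pair(t1, t2)
    leaf1 = {leaf.label: leaf for leaf in t1.leaves()}
    leaf2 = {leaf.label: leaf for leaf in t2.leaves()}
    result = ComparisonResult(t1, t2)

    if restrict_to is None:
        for n in t1.root.preorder():
            m, s = _best_in_other(n, leaf2)
            result.scores[n] = s
            result.bcn[n] = m
        for n in t2.root.preorder():
            m, s = _best_in_other(n, leaf1)
            result.scores[n] = s
            result.bcn[n] = m
        result.aggregate = _aggregate_over(t1, result.scores)
        return result

    ids1 = {id(n) for n in t1.root.preorder()}
    ids2 = {id(n) for n in t2.root.preorder()}
    for n in restrict_to:
        if id(n) in ids1:
            lookup = leaf2
        elif id(n) in ids2:
            lookup = leaf1
        else:
            raise ValidationError("restrict_to contains a node from neither tree")
        m, s = _best_in_other(n, lookup)
        result.scores[n] = s
        result.bcn[n] = m
    return result


def compare(t1: Tree, t2: Tree) -> ComparisonResult:
    """Full two-directional BCN comparison (optimized path)."""
    return bcn_fast(t1, t2)


class CladeScorer:
    """Vectorized "best Jaccard score against any clade of a fixed tree".

    Fingerprints of the fixed tree are packed into a uint64 matrix once, so
    each query costs one bitwise AND + popcount sweep in numpy.  Used by the
    rooting search, which evaluates thousands of candidate clades.
    """

    def __init__(self, tree: Tree):
        if tree.index_token is None:
            raise ValidationError("fingerprints must be computed before building a scorer")
        nodes = list(tree.root.preorder())
        n_bits = len(tree.leaf_index)
        self.words = max(1, (n_bits + 63) // 64)
        mat = np.empty((len(nodes), self.words), dtype=np.uint64)
        for i, n in enumerate(nodes):
            mat[i] = np.frombuffer(
                n.fingerprint.to_bytes(self.words * 8, "little"), dtype=np.uint64
            )
        self._mat = mat
        self._sizes = np.array([n.fp_size for n in nodes], dtype=np.int64)

    def best_score(self, fingerprint: int) -> float:
        q = np.frombuffer(
            fingerprint.to_bytes(self.words * 8, "little"), dtype=np.uint64
        )
        inter = np.bitwise_count(self._mat & q).sum(axis=1).astype(np.int64)
        union = fingerprint.bit_count() + self._sizes - inter
        return float((inter / union).max())
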