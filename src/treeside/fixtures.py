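"""Seeded synthetic trees and controlled perturbations.

Everything here is a pure function of its integer seed, so tests and the
acceptance script need no stored fixture files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Tuple

from .errors import ValidationError
from .tree_model import Tree, TreeNode, reroot, swap_children


def _labels(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"T{i:0{width}d}" for i in range(1, n + 1)]


def random_tree(n_leaves: int, seed: int, with_lengths: bool = False) -> Tree:
    """Binary rooted tree by seeded random sequential leaf attachment;
    optional branch lengths from a unit-mean exponential."""
    if n_leaves < 1:
        raise ValidationError("n_leaves must be >= 1")
    rng = random.Random(seed)
    labels = _labels(n_leaves)
    root = TreeNode(label=labels[0])
    parent: dict = {}
    attachable: List[TreeNode] = [root]
    for label in labels[1:]:
        target = rng.choice(attachable)
        leaf = TreeNode(label=label)
        inner = TreeNode(children=[target, leaf])
        holder = parent.get(id(target))
        if holder is None:
            root = inner
        else:
            holder.children[holder.children.index(target)] = inner
            parent[id(inner)] = holder
        parent[id(target)] = inner
        parent[id(leaf)] = inner
        attachable.append(leaf)
        attachable.append(inner)
    tree = Tree(root)
    if with_lengths:
        for node in tree.root.preorder():
            if node.parent is not None:
                node.length = rng.expovariate(1.0)
    return tree


def balanced_tree(n_leaves: int) -> Tree:
    """Perfectly balanced binary tree; ``n_leaves`` must be a power of two."""
    if n_leaves < 1 or n_leaves & (n_leaves - 1):
        raise ValidationError("n_leaves must be a positive power of two")
    nodes: List[TreeNode] = [TreeNode(label=lab) for lab in _labels(n_leaves)]
    while len(nodes) > 1:
        nodes = [
            TreeNode(children=[nodes[i], nodes[i + 1]])
            for i in range(0, len(nodes), 2)
        ]
    return Tree(nodes[0])


def _nni_candidates(tree: Tree) -> List[Tuple[TreeNode, TreeNode]]:
    # rooted edges (p, c) that sit on an internal edge of the unrooted tree
    root = tree.root
    binary_root = len(root.children) == 2
    out = []
    for p, c in tree.edges():
        if c.is_leaf:
            continue
        if p is root and binary_root:
            sibling = root.children[1] if c is root.children[0] else root.children[0]
            if sibling.is_leaf:
                continue
        out.append((p, c))
    return out


def apply_nni(tree: Tree, count: int, seed: int) -> Tree:
    """Apply ``count`` seeded nearest-neighbor interchanges on random
    internal edges of a copy of ``tree``; the leaf set is unchanged and any
    single NNI changes the split set."""
    if tree.n_leaves < 4:
        raise ValidationError("NNI requires a tree with at least 4 leaves")
    result = tree.copy()
    rng = random.Random(seed)
    for _ in range(count):
        candidates = _nni_candidates(result)
        p, c = candidates[rng.randrange(len(candidates))]
        root = result.root
        if p is root and len(root.children) == 2:
            # the unrooted edge joins c with its (internal) sibling: swap a
            # child of each across the suppressed root
            sibling = root.children[1] if c is root.children[0] else root.children[0]
            ci = rng.randrange(len(c.children))
            si = rng.randrange(len(sibling.children))
            c.children[ci], sibling.children[si] = sibling.children[si], c.children[ci]
        else:
            others = [i for i, s in enumerate(p.children) if s is not c]
            si = others[rng.randrange(len(others))]
            ci = rng.randrange(len(c.children))
            c.children[ci], p.children[si] = p.children[si], c.children[ci]
        result.rebuild()
    return result


def random_reroot(tree: Tree, seed: int) -> Tree:
    """Reroot a copy on a uniformly chosen edge."""
    edges = tree.edges()
    if not edges:
        return tree.copy()
    rng = random.Random(seed)
    return reroot(tree, edges[rng.randrange(len(edges))])


def shuffle_children(tree: Tree, seed: int) -> Tree:
    """Seeded random permutation of every internal node's children."""
    result = tree.copy()
    rng = random.Random(seed)
    for node in result.root.preorder():
        if not node.is_leaf:
            perm = list(range(len(node.children)))
            rng.shuffle(perm)
            swap_children(node, perm)
    result.rebuild()
    return result


@dataclass(frozen=True)
class PerturbationPlan:
    """Deterministic recipe: NNIs, then optional random reroot, then
    optional child-order shuffles, all driven by one seed."""

    n_nni: int = 0
    reroot: bool = False
    shuffle_children: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_nni < 0:
            raise ValidationError("n_nni must be >= 0")


def perturb(tree: Tree, plan: PerturbationPlan) -> Tree:
    rng = random.Random(plan.seed)
    sub = [rng.randrange(2**32) for _ in range(3)]
    result = tree.copy()
    if plan.n_nni:
        result = apply_nni(result, plan.n_nni, sub[0])
    if plan.reroot:
        result = random_reroot(result, sub[1])
    if plan.shuffle_children:
        result = shuffle_children(result, sub[2])
    return result
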