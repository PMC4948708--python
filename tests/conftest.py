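import pytest

from treeside import Tree, parse_newick
from treeside.tree_model import TreeNode


@pytest.fixture
def quartet() -> Tree:
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def quartet_alt() -> Tree:
    return parse_newick("((A,C),(B,D));")


@pytest.fixture
def caterpillar() -> Tree:
    return parse_newick("(A,(B,(C,D)));")


def leafset(node: TreeNode) -> frozenset:
    return frozenset(leaf.label for leaf in node.leaves())


def node_by_leafset(tree: Tree, labels) -> TreeNode:
    want = frozenset(labels)
    for node in tree.root.preorder():
        if leafset(node) == want:
            return node
    raise AssertionError(f"no node with leaf set {sorted(want)}")


def clade_sets(tree: Tree):
    """Leaf sets of all internal non-root nodes (rooted topology signature)."""
    return {
        leafset(n)
        for n in tree.root.preorder()
        if n.parent is not None and not n.is_leaf
    }
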