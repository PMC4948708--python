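"""Newick reading/writing, plus an NHX-style extended dialect.

The extended dialect carries visualization state (collapsed / highlighted
flags, viewport geometry) and per-node comparison scores inside
``[&&NHX:key=value:...]`` comment blocks attached after the branch length,
so any plain Newick parser that skips bracketed comments reads the same
topology.

Quoted labels use single quotes with doubled-quote escaping; unquoted
labels may not contain structural characters.  Numeric unquoted internal
labels are interpreted as support values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple, Union

from .errors import NewickParseError
from .layout_ops import VizState
from .tree_model import Tree, TreeNode

_UNQUOTED_FORBIDDEN = set("(),:;[]'")
_NUMBER_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")

#: fixed emission order for extended tags
_TAG_ORDER = ("collapsed", "highlighted", "score", "vw", "vh", "lh")


@dataclass
class NewickDocument:
    """A Newick string plus its dialect ("plain" or "extended")."""

    text: str
    dialect: str = "plain"


def _is_number(s: str) -> bool:
    return _NUMBER_RE.fullmatch(s) is not None


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.n = len(text)

    def fail(self, message: str) -> None:
        raise NewickParseError(message, offset=self.pos)

    def skip_ws(self) -> None:
        while self.pos < self.n and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < self.n else ""

    def parse(self) -> TreeNode:
        self.skip_ws()
        if self.peek() == "" or self.peek() == ";":
            self.fail("empty tree")
        root = self.subtree()
        self.skip_ws()
        if self.peek() != ";":
            self.fail("expected ';' at end of tree")
        self.pos += 1
        self.skip_ws()
        if self.pos != self.n:
            self.fail("trailing characters after ';'")
        return root

    def subtree(self) -> TreeNode:
        self.skip_ws()
        if self.peek() == "(":
            self.pos += 1
            children = [self.subtree()]
            self.skip_ws()
            while self.peek() == ",":
                self.pos += 1
                children.append(self.subtree())
                self.skip_ws()
            if self.peek() != ")":
                self.fail("expected ',' or ')'")
            self.pos += 1
            node = TreeNode(children=children)
            self.trailer(node, internal=True)
        else:
            node = TreeNode()
            self.trailer(node, internal=False)
            if node.label is None:
                self.fail("expected a leaf label")
        return node

    def trailer(self, node: TreeNode, internal: bool) -> None:
        self.skip_ws()
        label, quoted = self.label()
        if label is not None:
            if internal and not quoted and _is_number(label):
                node.support = float(label)
            else:
                node.label = label
        self.comments(node)
        self.skip_ws()
        if self.peek() == ":":
            self.pos += 1
            self.skip_ws()
            node.length = self.number()
        self.comments(node)

    def label(self) -> Tuple[Optional[str], bool]:
        if self.peek() == "'":
            self.pos += 1
            out = []
            while True:
                if self.pos >= self.n:
                    self.fail("unterminated quoted label")
                ch = self.text[self.pos]
                if ch == "'":
                    if self.pos + 1 < self.n and self.text[self.pos + 1] == "'":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    break
                out.append(ch)
                self.pos += 1
            return "".join(out), True
        start = self.pos
        while (
            self.pos < self.n
            and self.text[self.pos] not in _UNQUOTED_FORBIDDEN
            and not self.text[self.pos].isspace()
        ):
            self.pos += 1
        if self.pos == start:
            return None, False
        return self.text[start : self.pos], False

    def number(self) -> float:
        m = _NUMBER_RE.match(self.text, self.pos)
        if m is None:
            self.fail("expected a branch length")
        self.pos = m.end()
        return float(m.group())

    def comments(self, node: TreeNode) -> None:
        while True:
            self.skip_ws()
            if self.peek() != "[":
                return
            end = self.text.find("]", self.pos)
            if end < 0:
                self.fail("unterminated comment")
            body = self.text[self.pos + 1 : end]
            if body.startswith("&&NHX:"):
                for pair in body[len("&&NHX:") :].split(":"):
                    if not pair:
                        continue
                    key, _, value = pair.partition("=")
                    node.annotations[key] = value
            self.pos = end + 1


def parse_newick(doc: Union[str, NewickDocument]) -> Tree:
    """Parse plain or extended Newick into a :class:`Tree`.

    Raises :class:`NewickParseError` (with character offset) on malformed
    text and :class:`ValidationError` on duplicate leaf labels.
    """
    text = doc.text if isinstance(doc, NewickDocument) else doc
    root = _Parser(text).parse()
    return Tree(root)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _format_float(x: float) -> str:
    return format(x, ".10g")


def _emit_label(label: str) -> str:
    if label == "" or any(ch in _UNQUOTED_FORBIDDEN or ch.isspace() for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(
    tree: Tree,
    include_state: bool = False,
    state: Optional[VizState] = None,
    scores: Optional[Mapping[TreeNode, float]] = None,
) -> NewickDocument:
    """Serialize a tree; with ``include_state`` the extended dialect embeds
    per-node collapsed/highlighted flags, optional scores and (on the root)
    viewport geometry.  ``parse_newick(write_newick(t, ...))`` reproduces
    topology, labels, lengths, supports and state."""

    def tags_for(node: TreeNode, is_root: bool) -> str:
        if not include_state:
            return ""
        tags: Dict[str, str] = {}
        if state is not None:
            if node in state.collapsed:
                tags["collapsed"] = "1"
            if node in state.highlighted:
                tags["highlighted"] = "1"
            if is_root:
                tags["vw"] = str(state.viewport[0])
                tags["vh"] = str(state.viewport[1])
                tags["lh"] = str(state.label_height_px)
        if scores is not None and node in scores:
            tags["score"] = _format_float(scores[node])
        if not tags:
            return ""
        body = ":".join(f"{k}={tags[k]}" for k in _TAG_ORDER if k in tags)
        return f"[&&NHX:{body}]"

    def emit(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            s = _emit_label(node.label or "")
        else:
            s = "(" + ",".join(emit(c, False) for c in node.children) + ")"
            if node.support is not None:
                s += _format_float(node.support)
            elif node.label is not None:
                s += _emit_label(node.label)
        if node.length is not None:
            s += ":" + _format_float(node.length)
        return s + tags_for(node, is_root)

    text = emit(tree.root, True) + ";"
    return NewickDocument(text, "extended" if include_state else "plain")


def extract_state(
    tree: Tree,
    default_viewport: Tuple[int, int] = (1024, 768),
    default_label_height: int = 12,
) -> VizState:
    """Rebuild a :class:`VizState` from annotations left by the parser."""
    collapsed = set()
    highlighted = set()
    for node in tree.root.preorder():
        if node.annotations.get("collapsed") == "1":
            collapsed.add(node)
        if node.annotations.get("highlighted") == "1":
            highlighted.add(node)
    ann = tree.root.annotations
    viewport = (
        int(ann.get("vw", default_viewport[0])),
        int(ann.get("vh", default_viewport[1])),
    )
    label_height = int(ann.get("lh", default_label_height))
    return VizState(collapsed, highlighted, viewport, label_height)


def extract_scores(tree: Tree) -> Dict[TreeNode, float]:
    """Per-node similarity scores carried by extended annotations."""
    return {
        node: float(node.annotations["score"])
        for node in tree.root.preorder()
        if "score" in node.annotations
    }
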