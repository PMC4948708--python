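"""Deterministic static SVG rendering of one tree or two trees side by side.

Rectangular cladogram layout (phylogram optional): visible leaves and
collapsed-subtree stubs occupy evenly spaced rows, internal nodes sit at the
mean of their children's rows, collapsed subtrees are drawn as triangles.
In compare mode each visible node's glyph carries a ``bin-K`` CSS class
derived from its best-corresponding-node score on a low-to-high
yellow-to-blue ramp; highlight, selection and search-path overlays are
plain CSS classes, so output is testable as text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple
from xml.sax.saxutils import escape

from .comparison import ComparisonResult
from .errors import ValidationError
from .layout_ops import VizState, visible_nodes
from .tree_model import Tree, TreeNode

#: 9-class sequential yellow -> blue ramp (ColorBrewer YlGnBu)
DEFAULT_SCHEME: Tuple[str, ...] = (
    "#ffffd9",
    "#edf8b1",
    "#c7e9b4",
    "#7fcdbb",
    "#41b6c4",
    "#1d91c0",
    "#225ea8",
    "#253494",
    "#081d58",
)


@dataclass(frozen=True)
class RenderSpec:
    viewport: Tuple[int, int] = (960, 640)
    label_height_px: int = 12
    color_bins: int = 9
    scheme: Tuple[str, ...] = DEFAULT_SCHEME
    highlight_color: str = "#33a02c"
    selection_color: str = "#e31a1c"
    search_color: str = "#ff7f00"
    phylogram: bool = False

    def __post_init__(self):
        if self.color_bins != len(self.scheme):
            raise ValidationError("color_bins must equal the number of scheme colors")
        if self.color_bins < 3:
            raise ValidationError("need at least 3 color bins")


def color_bin(score: float, spec: RenderSpec) -> int:
    """Uniform binning of a similarity score onto the color ramp."""
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"score {score!r} outside [0, 1]")
    return min(int(score * spec.color_bins), spec.color_bins - 1)


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def layout_rect(
    tree: Tree,
    state: VizState,
    spec: RenderSpec,
    mirrored: bool = False,
    width: Optional[float] = None,
    x_offset: float = 0.0,
) -> Dict[TreeNode, Tuple[float, float]]:
    """Rectangular layout of the visible nodes.

    Rows (visible leaves and collapsed stubs) are evenly spaced over the
    viewport height; x grows with depth (or cumulative branch length in
    phylogram mode).  ``mirrored`` reflects x for the right-hand tree of a
    pair.  Traversal never descends into collapsed nodes.
    """
    w = float(width if width is not None else spec.viewport[0])
    h = float(spec.viewport[1])
    vis = visible_nodes(tree, state)
    rows = [n for n in vis if n.is_leaf or n in state.collapsed]
    row_h = h / max(len(rows), 1)

    ys: Dict[TreeNode, float] = {}
    for i, node in enumerate(rows):
        ys[node] = (i + 0.5) * row_h
    row_set = set(rows)
    for node in reversed(vis):  # children before parents in reversed preorder
        if node in row_set:
            continue
        child_ys = [ys[c] for c in node.children]
        ys[node] = sum(child_ys) / len(child_ys)

    xs: Dict[TreeNode, float] = {}
    if spec.phylogram:
        xs[tree.root] = 0.0
        for node in vis:
            for child in node.children:
                if child in ys:
                    step = child.length if child.length is not None else 0.0
                    xs[child] = xs[node] + step
    else:
        depth = {tree.root: 0.0}
        for node in vis:
            for child in node.children:
                if child in ys:
                    depth[child] = depth[node] + 1.0
        xs = depth

    max_x = max((xs[n] for n in rows), default=0.0)
    max_x = max(max_x, 1e-9)
    label_chars = max((len(n.label or "") for n in rows if n.is_leaf), default=0)
    reserve = label_chars * spec.label_height_px * 0.62 + 10.0
    pad = 8.0
    inner = max(w - pad - reserve, 10.0)

    out: Dict[TreeNode, Tuple[float, float]] = {}
    for node in vis:
        x = pad + (xs[node] / max_x) * inner
        if mirrored:
            x = w - x
        out[node] = (x + x_offset, ys[node])
    return out


def _stylesheet(spec: RenderSpec) -> str:
    rules = [
        ".edge{fill:none;stroke:#555555;stroke-width:1}",
        ".node{fill:#888888;stroke:none}",
        f".leaf-label{{font-family:monospace;font-size:{spec.label_height_px}px}}",
        ".collapsed-stub{stroke:#777777}",
        f".edge.highlight{{stroke:{spec.highlight_color};stroke-width:2.5}}",
        f".node.highlight{{fill:{spec.highlight_color}}}",
        f".node.selected{{fill:{spec.selection_color};stroke:{spec.selection_color}}}",
        f".edge.search-path{{stroke:{spec.search_color};stroke-width:2.5}}",
    ]
    for i, color in enumerate(spec.scheme):
        rules.append(f".bin-{i}{{fill:{color}}}")
    return "".join(rules)


def _count_leaves(node: TreeNode) -> int:
    return sum(1 for _ in node.preorder() if _.is_leaf)


def _tree_elements(
    tree: Tree,
    state: VizState,
    spec: RenderSpec,
    pos: Dict[TreeNode, Tuple[float, float]],
    mirrored: bool = False,
    cmp: Optional[ComparisonResult] = None,
    selected: Optional[TreeNode] = None,
    search_path: Optional[Sequence[TreeNode]] = None,
) -> List[str]:
    vis = visible_nodes(tree, state)
    in_path = set(search_path) if search_path else set()
    row_h = spec.viewport[1] / max(
        sum(1 for n in vis if n.is_leaf or n in state.collapsed), 1
    )
    elems: List[str] = []

    for node in vis:
        if node.parent is None or node.parent not in pos:
            continue
        px, py = pos[node.parent]
        cx, cy = pos[node]
        cls = "edge"
        if node in in_path and node.parent in in_path:
            cls += " search-path"
        if node in state.highlighted:
            cls += " highlight"
        d = f"M {_fmt(px)},{_fmt(py)} V {_fmt(cy)} H {_fmt(cx)}"
        elems.append(f'<path class="{cls}" d="{d}"/>')

    total_leaves = max(tree.n_leaves, 1)
    max_tri = 0.15 * spec.viewport[0] / (2 if cmp is not None else 1)
    for node in vis:
        x, y = pos[node]
        if node in state.collapsed:
            n_hidden = _count_leaves(node)
            tri_w = min(6.0 + 0.2 * spec.viewport[0] * n_hidden / total_leaves, max_tri)
            if mirrored:
                tri_w = -tri_w
            half = row_h / 2.0
            points = (
                f"{_fmt(x)},{_fmt(y)} {_fmt(x + tri_w)},{_fmt(y - half)} "
                f"{_fmt(x + tri_w)},{_fmt(y + half)}"
            )
            cls = "collapsed-stub"
            if cmp is not None:
                cls += f" bin-{color_bin(_score_of(cmp, node), spec)}"
            if node in state.highlighted:
                cls += " highlight"
            elems.append(f'<polygon class="{cls}" points="{points}"/>')

        cls = "node"
        if cmp is not None:
            cls += f" bin-{color_bin(_score_of(cmp, node), spec)}"
        if node in state.highlighted:
            cls += " highlight"
        if selected is not None and node is selected:
            cls += " selected"
        elems.append(
            f'<circle class="{cls}" cx="{_fmt(x)}" cy="{_fmt(y)}" r="2.50"/>'
        )

        if node.is_leaf:
            anchor = "end" if mirrored else "start"
            tx = x - 4.0 if mirrored else x + 4.0
            ty = y + spec.label_height_px * 0.35
            elems.append(
                f'<text class="leaf-label" x="{_fmt(tx)}" y="{_fmt(ty)}" '
                f'text-anchor="{anchor}">{escape(node.label or "")}</text>'
            )
    return elems


def _score_of(cmp: ComparisonResult, node: TreeNode) -> float:
    try:
        return cmp.scores[node]
    except KeyError:
        raise ValidationError(
            "comparison result does not cover a visible node; compute scores "
            "for at least the visible nodes before rendering"
        ) from None


def _svg(spec: RenderSpec, body: Iterable[str]) -> str:
    w, h = spec.viewport
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">',
        f"<style>{_stylesheet(spec)}</style>",
        *body,
        "</svg>",
    ]
    return "".join(parts)


def render_view(
    tree: Tree,
    state: VizState,
    spec: RenderSpec,
    search_path: Optional[Sequence[TreeNode]] = None,
) -> str:
    """Render a single tree; pure function of its inputs (byte-identical
    output for identical calls)."""
    pos = layout_rect(tree, state, spec)
    body = ['<g class="tree tree-0">']
    body.extend(_tree_elements(tree, state, spec, pos, search_path=search_path))
    body.append("</g>")
    return _svg(spec, body)


def render_compare(
    t1: Tree,
    t2: Tree,
    cmp: ComparisonResult,
    s1: VizState,
    s2: VizState,
    spec: RenderSpec,
    selected: Optional[TreeNode] = None,
) -> str:
    """Render two trees side by side (the right tree mirrored, labels facing
    inward), node glyphs colored by the color bin of their BCN scores."""
    gap = 24.0
    half = (spec.viewport[0] - gap) / 2.0
    pos1 = layout_rect(t1, s1, spec, width=half)
    pos2 = layout_rect(t2, s2, spec, mirrored=True, width=half, x_offset=half + gap)
    body = ['<g class="tree tree-0">']
    body.extend(_tree_elements(t1, s1, spec, pos1, cmp=cmp, selected=selected))
    body.append("</g>")
    body.append('<g class="tree tree-1">')
    body.extend(_tree_elements(t2, s2, spec, pos2, mirrored=True, cmp=cmp))
    body.append("</g>")
    return _svg(spec, body)
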