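"""Minimal SVG export of trees and side-by-side / face-to-face pairs.

Rectangular phylogram layout: branch lengths are drawn when present
(missing lengths count as one unit), leaf y-positions follow the child
order, one ``<text>`` element per leaf.  Colour annotations are honoured;
when an agreement classification is supplied, leaves outside the consensus
(conflicting or tree-specific) and the edges of fully non-consensus
subtrees are drawn in the shading colour.  Rendering is pure: identical
inputs give byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass

from .compare import AgreementResult, LeafClass
from .tree import Node, Tree, TreeError

_DEFAULT_COLOR = "#000000"


@dataclass(frozen=True)
class RenderSpec:
    orientation: str = "right"  # "right" or "face_to_face" (pairs only)
    leaf_spacing: float = 18.0
    font_size: float = 12.0
    shade_color: str = "#b8b8b8"
    width: float = 320.0
    margin: float = 10.0

    def __post_init__(self) -> None:
        if self.leaf_spacing <= 0 or self.font_size <= 0:
            raise TreeError("leaf spacing and font size must be positive")


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _layout(tree: Tree, spec: RenderSpec):
    """x by cumulative branch length, y by tip order; returns node maps."""
    xs: dict[int, float] = {}
    ys: dict[int, float] = {}
    for node in tree.root.preorder():
        step = node.length if node.length is not None else 1.0
        xs[id(node)] = (xs[id(node.parent)] if node.parent else 0.0) + (
            step if node.parent else 0.0
        )
    leaves = tree.leaves()
    for i, leaf in enumerate(leaves):
        ys[id(leaf)] = (i + 0.5) * spec.leaf_spacing
    for node in tree.root.postorder():
        if not node.is_leaf:
            ys[id(node)] = sum(ys[id(c)] for c in node.children) / len(node.children)
    max_x = max(xs.values()) or 1.0
    label_room = spec.width * 0.35
    scale = (spec.width - label_room) / max_x
    for k in xs:
        xs[k] *= scale
    return xs, ys


def _leaf_fill(leaf: Node, classes: dict[str, LeafClass] | None, spec: RenderSpec) -> str:
    own = leaf.annotations.get("color", _DEFAULT_COLOR)
    if classes is None:
        return own
    if classes.get(leaf.label or "") is LeafClass.IN_CONSENSUS:
        return own
    return spec.shade_color


def _shaded_nodes(tree: Tree, classes: dict[str, LeafClass] | None) -> set[int]:
    """Nodes whose leaves are all outside the consensus (edges greyed)."""
    if classes is None:
        return set()
    out: set[int] = set()
    status: dict[int, bool] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            shaded = classes.get(node.label or "") is not LeafClass.IN_CONSENSUS
        else:
            shaded = all(status[id(c)] for c in node.children)
        status[id(node)] = shaded
        if shaded:
            out.add(id(node))
    return out


def _draw(
    tree: Tree,
    spec: RenderSpec,
    classes: dict[str, LeafClass] | None,
    x_offset: float,
    y_offset: float,
    mirror: bool,
) -> list[str]:
    xs, ys = _layout(tree, spec)
    shaded = _shaded_nodes(tree, classes)
    span = spec.width

    def tx(x: float) -> float:
        return x_offset + (span - x if mirror else x)

    parts: list[str] = []
    for node in tree.root.preorder():
        stroke = spec.shade_color if id(node) in shaded else _DEFAULT_COLOR
        y = y_offset + ys[id(node)]
        if node.parent is not None:
            px = tx(xs[id(node.parent)])
            parts.append(
                f'<line x1="{_fmt(px)}" y1="{_fmt(y)}" '
                f'x2="{_fmt(tx(xs[id(node)]))}" y2="{_fmt(y)}" '
                f'stroke="{stroke}"/>'
            )
        if not node.is_leaf:
            cy = [y_offset + ys[id(c)] for c in node.children]
            parts.append(
                f'<line x1="{_fmt(tx(xs[id(node)]))}" y1="{_fmt(min(cy))}" '
                f'x2="{_fmt(tx(xs[id(node)]))}" y2="{_fmt(max(cy))}" '
                f'stroke="{stroke}"/>'
            )
    for leaf in tree.leaves():
        fill = _leaf_fill(leaf, classes, spec)
        x = tx(xs[id(leaf)]) + (-4.0 if mirror else 4.0)
        anchor = ' text-anchor="end"' if mirror else ""
        y = y_offset + ys[id(leaf)] + spec.font_size / 3.0
        parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" '
            f'font-size="{_fmt(spec.font_size)}" fill="{fill}"{anchor}>'
            f"{_escape(leaf.label or '')}</text>"
        )
    return parts


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def _document(parts: list[str], width: float, height: float) -> str:
    body = "\n".join(parts)
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}">\n{body}\n</svg>\n'
    )


def render_svg(
    tree: Tree,
    spec: RenderSpec | None = None,
    agreement: AgreementResult | None = None,
) -> str:
    """SVG drawing of one tree, tips to the right."""
    spec = spec or RenderSpec()
    classes = agreement.classes_for(tree) if agreement is not None else None
    height = len(tree.leaves()) * spec.leaf_spacing + 2 * spec.margin
    parts = _draw(tree, spec, classes, spec.margin, spec.margin, mirror=False)
    return _document(parts, spec.width + 2 * spec.margin, height)


def render_pair(
    t1: Tree,
    t2: Tree,
    spec: RenderSpec | None = None,
    agreement: AgreementResult | None = None,
) -> str:
    """Two trees in one drawing.

    ``face_to_face`` mirrors the second tree so the tip labels face
    inward; otherwise both trees share the same orientation side by side.
    """
    spec = spec or RenderSpec()
    gap = 40.0
    c1 = agreement.classes_for(t1) if agreement is not None else None
    c2 = agreement.classes_for(t2) if agreement is not None else None
    mirror = spec.orientation == "face_to_face"
    height = (
        max(len(t1.leaves()), len(t2.leaves())) * spec.leaf_spacing
        + 2 * spec.margin
    )
    parts = _draw(t1, spec, c1, spec.margin, spec.margin, mirror=False)
    parts += _draw(t2, spec, c2, spec.margin + spec.width + gap, spec.margin, mirror)
    return _document(parts, 2 * spec.width + gap + 2 * spec.margin, height)
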