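"""Tree-edition operations, applicable to one tree or jointly to a set.

These are the workbench edits: restriction to a taxon subset, rerooting on
a (multi-level) outgroup, manual subtree swap, coordinated renaming and
colouring.  Collection-level variants apply the per-tree operation
independently and aggregate warnings — a failure on one tree never aborts
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tree import Node, Tree, TreeCollection, TreeError


# ---------------------------------------------------------------------------
# restriction


def common_taxa(trees: list[Tree]) -> frozenset[str]:
    """Intersection of the leaf sets of the given trees."""
    if not trees:
        raise TreeError("common_taxa requires at least one tree")
    out = trees[0].taxa
    for t in trees[1:]:
        out &= t.taxa
    return out


def _suppress_unary(node: Node) -> None:
    """Collapse unary internal nodes below `node`, summing branch lengths."""
    for child in list(node.children):
        _suppress_unary(child)
    if len(node.children) == 1 and node.parent is not None:
        child = node.children[0]
        if node.length is None or child.length is None:
            child.length = None
        else:
            child.length = node.length + child.length
        idx = node.parent.children.index(node)
        node.parent.children[idx] = child
        child.parent = node.parent


def restrict_to_taxa(tree: Tree, keep: set[str] | frozenset[str]) -> Tree:
    """Induced subtree on ``keep`` ∩ leaves(tree).

    Pruned leaves are removed, unary nodes suppressed (branch lengths
    summed; absent + anything = absent); the relative nesting of the
    surviving taxa is unchanged.
    """
    kept = frozenset(keep) & tree.taxa
    if len(kept) < 2:
        raise TreeError("restriction would leave a degenerate tree")
    root = tree.root.copy()

    def rebuild(node: Node) -> Node | None:
        if node.is_leaf:
            return node if node.label in kept else None
        kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
        if not kids:
            return None
        node.children = kids
        for k in kids:
            k.parent = node
        return node

    new_root = rebuild(root)
    assert new_root is not None
    _suppress_unary(new_root)
    while len(new_root.children) == 1:
        new_root = new_root.children[0]
    new_root.parent = None
    new_root.length = None
    return Tree(new_root)


# ---------------------------------------------------------------------------
# rerooting


@dataclass(frozen=True)
class OutgroupSpec:
    """Ordered outgroup levels, outermost first.

    When the outermost level has no representative in a tree, the next
    level is tried, and so on.
    """

    levels: tuple[frozenset[str], ...]

    def __init__(self, levels) -> None:
        lv = tuple(frozenset(l) for l in levels)
        if not lv:
            raise TreeError("outgroup spec needs at least one level")
        if any(not l for l in lv):
            raise TreeError("outgroup levels must be non-empty")
        object.__setattr__(self, "levels", lv)


@dataclass
class RerootResult:
    tree: Tree
    warnings: list[str] = field(default_factory=list)


def _reroot_on_edge(tree: Tree, target: Node) -> Tree:
    """Reroot so the new root lies on the edge above ``target``.

    The edge's length is split equally between the two new root children
    (absent lengths stay absent); on every reversed edge the (length,
    support) pair travels with the edge to its new child node.
    """
    old_parent = target.parent
    assert old_parent is not None
    half = None if target.length is None else target.length / 2.0

    old_parent.children.remove(target)

    def rehang(node: Node, carry_length: float | None, carry_support: float | None) -> Node:
        """Turn `node`'s old parent side into a child; return node."""
        parent = node.parent
        my_length, my_support = node.length, node.support
        node.length, node.support = carry_length, carry_support
        if parent is not None:
            parent.children.remove(node)
            hung = rehang(parent, my_length, my_support)
            node.children.append(hung)
            hung.parent = node
        node.parent = None
        return node

    other = rehang(old_parent, half, target.support)
    # the old root may have been left unary by the reversal
    while len(other.children) == 1:
        child = other.children[0]
        if other.length is None or child.length is None:
            child.length = None
        else:
            child.length = other.length + child.length
        child.support = other.support if child.support is None else child.support
        child.parent = None
        other = child
    _suppress_unary_down(other)
    new_root = Node()
    target.length = half
    target.support = None if target.is_leaf else target.support
    new_root.add_child(target)
    new_root.add_child(other)
    return Tree(new_root)


def _suppress_unary_down(node: Node) -> None:
    for child in list(node.children):
        _suppress_unary_down(child)
    i = 0
    while i < len(node.children):
        c = node.children[i]
        if len(c.children) == 1:
            gc = c.children[0]
            if c.length is None or gc.length is None:
                gc.length = None
            else:
                gc.length = c.length + gc.length
            node.children[i] = gc
            gc.parent = node
        else:
            i += 1


def reroot_outgroup(tree: Tree, spec: OutgroupSpec) -> RerootResult:
    """Reroot on the first outgroup level with a representative.

    The tree is rerooted on the edge separating the MRCA of the present
    representatives from the rest; the unrooted bipartition set is
    unchanged.  If no level is represented, the tree is returned unchanged
    with a warning.
    """
    taxa = tree.taxa
    reps: frozenset[str] = frozenset()
    for level in spec.levels:
        reps = level & taxa
        if reps:
            break
    if not reps:
        return RerootResult(tree.copy(), ["no outgroup representative in any level"])
    if reps == taxa:
        return RerootResult(tree.copy(), ["outgroup covers all taxa; tree unchanged"])

    work = tree.copy()
    clades = work.clades()
    m = work.mrca(reps)
    warnings: list[str] = []
    if m is work.root:
        comp = taxa - reps
        if len(comp) == 1:
            target = work.find_leaf(next(iter(comp)))
        else:
            cm = work.mrca(comp)
            if clades[id(cm)] != comp or cm is work.root:
                raise TreeError("outgroup not monophyletic")
            target = cm
        warnings.append("non-monophyletic outgroup; rooted above its complement")
    else:
        target = m
        if clades[id(m)] != reps:
            warnings.append("non-monophyletic outgroup")
    return RerootResult(_reroot_on_edge(work, target), warnings)


@dataclass
class CollectionRerootResult:
    collection: TreeCollection
    warnings: dict[str, list[str]] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def reroot_collection(collection: TreeCollection, spec: OutgroupSpec) -> CollectionRerootResult:
    """Reroot every tree independently; errors leave that tree unchanged."""
    out = TreeCollection(collection.name)
    result = CollectionRerootResult(out)
    for name, tree in collection.items:
        try:
            r = reroot_outgroup(tree, spec)
            out.add(name, r.tree)
            if r.warnings:
                result.warnings[name] = r.warnings
        except TreeError as exc:
            out.add(name, tree.copy())
            result.errors[name] = str(exc)
    return result


# ---------------------------------------------------------------------------
# swap / rename / colour


def manual_swap(tree: Tree, taxon_a: str, taxon_b: str) -> Tree:
    """Exchange, in child order, the two subtrees of the MRCA of the taxa.

    The unordered topology is unchanged; only the displayed tip order
    moves.  Applying the same swap twice restores the original order.
    """
    if taxon_a == taxon_b:
        raise TreeError("cannot swap a taxon with itself")
    work = tree.copy()
    work.find_leaf(taxon_a)
    work.find_leaf(taxon_b)
    m = work.mrca({taxon_a, taxon_b})
    clades = work.clades()
    ia = ib = -1
    for i, child in enumerate(m.children):
        below = clades[id(child)]
        if taxon_a in below:
            ia = i
        if taxon_b in below:
            ib = i
    assert ia >= 0 and ib >= 0 and ia != ib
    m.children[ia], m.children[ib] = m.children[ib], m.children[ia]
    return work


def rename_taxa(trees: list[Tree], mapping: dict[str, str]) -> list[Tree]:
    """Rename tips across several trees at once.

    The mapping must be injective and must not collide with names that are
    not being renamed in any tree.
    """
    values = list(mapping.values())
    if len(set(values)) != len(values):
        raise TreeError("rename mapping is not injective")
    out: list[Tree] = []
    for idx, tree in enumerate(trees):
        present = tree.taxa
        applicable = {o: n for o, n in mapping.items() if o in present}
        untouched = present - set(applicable)
        for old, new in applicable.items():
            if new in untouched:
                raise TreeError(
                    f"rename collision in tree {idx}: {old!r} -> {new!r} "
                    f"clashes with existing taxon {new!r}"
                )
        work = tree.copy()
        for leaf in work.leaves():
            if leaf.label in applicable:
                leaf.label = applicable[leaf.label]
        out.append(work)
    return out


def set_color(trees: list[Tree], taxa: set[str] | frozenset[str], color: str) -> list[Tree]:
    """Set the ``color`` annotation on every matching leaf of every tree."""
    out: list[Tree] = []
    for tree in trees:
        work = tree.copy()
        for leaf in work.leaves():
            if leaf.label in taxa:
                leaf.annotations["color"] = color
        out.append(work)
    return out
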