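"""Core rooted-tree data model.

The tree is the universal object of every operation in this package: a
rooted, *ordered* tree whose child order defines the displayed tip order,
with optional branch lengths, optional support values on internal nodes
(read from numeric internal labels in Newick), and a per-leaf annotation
map used for colours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator


class TreeError(Exception):
    """Domain error raised by tree operations."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class Node:
    """A tree node.

    ``label`` is the taxon name for leaves and an optional name for
    internal nodes; ``length`` is the branch length to the parent (None if
    absent); ``support`` holds a numeric internal-node label; ``annotations``
    is a free key→text map (leaves carry colours here).
    """

    __slots__ = ("label", "length", "support", "children", "parent", "annotations")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        support: float | None = None,
    ) -> None:
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.annotations: dict[str, str] = {}

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list["Node"]:
        """Leaves below this node, in display (child) order."""
        return [n for n in self.preorder() if n.is_leaf]

    def copy(self) -> "Node":
        new = Node(self.label, self.length, self.support)
        new.annotations = dict(self.annotations)
        for child in self.children:
            new.add_child(child.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind}>"


class Tree:
    """A rooted ordered tree with unique, non-empty leaf labels."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.root.preorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate leaf label: {node.label!r}")
                seen.add(node.label)
            elif len(node.children) == 1 and node is not self.root:
                raise TreeError("internal unary node exposed to caller")
        if self.root.parent is not None:
            raise TreeError("root must not have a parent")

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        """Tip order, left to right."""
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def find_leaf(self, label: str) -> Node:
        for node in self.leaves():
            if node.label == label:
                return node
        raise TreeError(f"unknown taxon: {label!r}")

    def mrca(self, labels: set[str] | frozenset[str]) -> Node:
        """Most recent common ancestor of the given leaf labels."""
        want = set(labels)
        missing = want - self.taxa
        if missing:
            raise TreeError(f"unknown taxa: {sorted(missing)}")
        # smallest node whose leaf set covers `want`
        cover: dict[int, set[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                cover[id(node)] = {node.label}  # type: ignore[arg-type]
            else:
                s: set[str] = set()
                for c in node.children:
                    s |= cover[id(c)]
                cover[id(node)] = s
            if want <= cover[id(node)]:
                return node
        raise TreeError("mrca not found")  # pragma: no cover

    def clades(self) -> dict[int, frozenset[str]]:
        """Map node id → leaf set below it (every node)."""
        out: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                out[id(node)] = frozenset([node.label])  # type: ignore[list-item]
            else:
                s: frozenset[str] = frozenset()
                for c in node.children:
                    s |= out[id(c)]
                out[id(node)] = s
        return out

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree n={len(self.leaves())}>"


def canonical_shape(node: Node) -> str:
    """Order-insensitive canonical form of a rooted topology.

    Two rooted trees induce the same (unordered) topology iff their
    canonical shapes are equal.  Branch lengths and supports are ignored.
    """
    if node.is_leaf:
        return node.label or ""
    return "(" + ",".join(sorted(canonical_shape(c) for c in node.children)) + ")"


@dataclass
class TreeCollection:
    """A named, ordered list of (name, tree) pairs.

    Order is user-controlled and stable under edits; tree names are unique
    within the collection.
    """

    name: str
    items: list[tuple[str, Tree]] = field(default_factory=list)

    def add(self, tree_name: str, tree: Tree) -> None:
        if any(n == tree_name for n, _ in self.items):
            raise TreeError(f"duplicate tree name in collection: {tree_name!r}")
        self.items.append((tree_name, tree))

    def names(self) -> list[str]:
        return [n for n, _ in self.items]

    def trees(self) -> list[Tree]:
        return [t for _, t in self.items]

    def get(self, tree_name: str) -> Tree:
        for n, t in self.items:
            if n == tree_name:
                return t
        raise TreeError(f"no tree named {tree_name!r} in collection {self.name!r}")

    def replace(self, tree_name: str, tree: Tree) -> None:
        for i, (n, _) in enumerate(self.items):
            if n == tree_name:
                self.items[i] = (tree_name, tree)
                return
        raise TreeError(f"no tree named {tree_name!r} in collection {self.name!r}")

    def map(self, fn: Callable[[Tree], Tree]) -> "TreeCollection":
        return TreeCollection(self.name, [(n, fn(t)) for n, t in self.items])

    def copy(self) -> "TreeCollection":
        return TreeCollection(self.name, [(n, t.copy()) for n, t in self.items])

    def __len__(self) -> int:
        return len(self.items)
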