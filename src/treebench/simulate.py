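"""Random-tree fixtures and study-condition generators.

All test inputs in this package are generated here — no downloads, no
bundled data.  Rooted binary topologies are drawn uniformly by sequential
random leaf attachment (every edge, including the virtual edge above the
root, is equally likely, which yields the uniform distribution over the
(2n-3)!! labelled rooted shapes).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .edit import restrict_to_taxa
from .tree import Node, Tree, TreeError, canonical_shape


@dataclass(frozen=True)
class FixtureConfig:
    """Settings for the random-tree fixture generator.

    ``missing_fraction`` controls unequal leaf sets: each tree is
    restricted to a random subset dropping that fraction of the taxa.
    """

    n_taxa: int
    n_trees: int
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_trees < 1:
            raise TreeError("taxon and tree counts must be positive")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise TreeError("missing fraction must lie in [0, 1)")


def random_tree(labels: list[str], rng: random.Random) -> Tree:
    """Uniformly random rooted binary topology over the given labels."""
    if len(labels) < 1:
        raise TreeError("need at least one label")
    root = Node(label=labels[0])
    attachable = [root]
    for label in labels[1:]:
        target = rng.choice(attachable)
        fork = Node()
        leaf = Node(label=label)
        parent = target.parent
        if parent is None:
            root = fork
        else:
            parent.children[parent.children.index(target)] = fork
            fork.parent = parent
        fork.children = [target, leaf]
        target.parent = fork
        leaf.parent = fork
        attachable.extend([fork, leaf])
    root.parent = None
    return Tree(root)


def generate_fixtures(config: FixtureConfig) -> list[Tree]:
    """Random tree set, optionally with unequal leaf sets; deterministic."""
    rng = random.Random(config.seed)
    labels = [f"T{i + 1}" for i in range(config.n_taxa)]
    n_drop = round(config.missing_fraction * config.n_taxa)
    out: list[Tree] = []
    for _ in range(config.n_trees):
        tree = random_tree(labels, rng)
        if n_drop:
            keep = set(rng.sample(labels, max(2, config.n_taxa - n_drop)))
            tree = restrict_to_taxa(tree, keep)
        out.append(tree)
    return out


# ---------------------------------------------------------------------------
# supertree study conditions


def count_displaying_trees(
    labels: list[str], sources: list[Tree], cap: int = 3
) -> int:
    """Number of rooted binary trees on ``labels`` displaying every source.

    A tree displays a source when its restriction to the source's taxa is
    isomorphic to the source.  Counting stops at ``cap + 1``.  This is an
    enumeration over stepwise leaf additions with conflict pruning and is
    entirely independent of parsimony machinery, so it can serve as an
    oracle for supertree identifiability.
    """
    src_shapes = [canonical_shape(s.root) for s in sources]
    count = [0]

    def partial_ok(tree: Tree, present: set[str]) -> bool:
        for s, full_shape in zip(sources, src_shapes):
            inter = s.taxa & present
            if len(inter) < 2:
                continue
            if inter == s.taxa:
                want = full_shape
            else:
                want = canonical_shape(restrict_to_taxa(s, inter).root)
            if canonical_shape(restrict_to_taxa(tree, inter).root) != want:
                return False
        return True

    def attach_all(tree: Tree, label: str):
        n_nodes = len(list(tree.root.preorder()))
        for idx in range(n_nodes):
            t2 = tree.copy()
            target = list(t2.root.preorder())[idx]
            fork = Node()
            leaf = Node(label=label)
            parent = target.parent
            fork.children = [target, leaf]
            target.parent = fork
            leaf.parent = fork
            if parent is None:
                yield Tree(fork)
            else:
                parent.children[parent.children.index(target)] = fork
                fork.parent = parent
                node = parent
                while node.parent is not None:
                    node = node.parent
                yield Tree(node)

    def recurse(tree: Tree, rest: list[str], present: set[str]) -> None:
        if count[0] > cap:
            return
        if not rest:
            count[0] += 1
            return
        label = rest[0]
        for t2 in attach_all(tree, label):
            if partial_ok(t2, present | {label}):
                recurse(t2, rest[1:], present | {label})

    root = Node()
    for label in labels[:2]:
        root.add_child(Node(label=label))
    recurse(Tree(root), list(labels[2:]), set(labels[:2]))
    return count[0]


def definitive_subtree_sample(
    model: Tree,
    n_subsets: int,
    subset_size: int,
    rng: random.Random,
    max_attempts: int = 1000,
) -> list[Tree]:
    """Induced subtrees that jointly define the model tree.

    Draws ``n_subsets`` random taxon subsets of the given size and keeps
    the family only when the model is the unique rooted binary tree
    displaying all induced subtrees (checked by the independent
    enumeration oracle).  This is the coverage condition under which exact
    supertree recovery is possible at all.
    """
    labels = sorted(model.taxa)
    for _ in range(max_attempts):
        subsets = [frozenset(rng.sample(labels, subset_size)) for _ in range(n_subsets)]
        sources = [restrict_to_taxa(model, s) for s in subsets]
        if count_displaying_trees(labels, sources, cap=1) == 1:
            return sources
    raise TreeError("no definitive subtree family found")  # pragma: no cover
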