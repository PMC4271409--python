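"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they are used to
check: the Robinson-Foulds oracle enumerates splits by breadth-first
search over an undirected adjacency map built straight from the node
structure; the MAST oracle searches taxon subsets exhaustively; the
parsimony oracle enumerates internal state assignments.
"""

from __future__ import annotations

import itertools
import random

import pytest

from treebench import Tree, canonical_shape, parse_newick, restrict_to_taxa
from treebench.simulate import random_tree


@pytest.fixture
def t():
    """Shorthand Newick parser."""
    return parse_newick


def make_random_tree(n: int, seed: int, prefix: str = "T") -> Tree:
    rng = random.Random(seed)
    labels = [f"{prefix}{i + 1}" for i in range(n)]
    rng.shuffle(labels)
    return random_tree(labels, rng)


# ---------------------------------------------------------------------------
# naive Robinson-Foulds oracle (adjacency + BFS, no shared split code)


def naive_splits(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial unrooted splits via per-edge BFS on an adjacency map."""
    adjacency: dict[int, set[int]] = {}
    labels: dict[int, str] = {}
    nodes = list(tree.root.preorder())
    for node in nodes:
        adjacency.setdefault(id(node), set())
        if node.is_leaf:
            labels[id(node)] = node.label
        for child in node.children:
            adjacency.setdefault(id(child), set())
            adjacency[id(node)].add(id(child))
            adjacency[id(child)].add(id(node))
    # suppress the root if it has degree 2 (unrooted view)
    rid = id(tree.root)
    if len(adjacency[rid]) == 2:
        a, b = adjacency[rid]
        adjacency[a].discard(rid)
        adjacency[b].discard(rid)
        adjacency[a].add(b)
        adjacency[b].add(a)
        del adjacency[rid]
    taxa = frozenset(labels.values())
    edges = {frozenset((u, v)) for u in adjacency for v in adjacency[u]}
    splits: set[frozenset[str]] = set()
    for edge in edges:
        u, v = tuple(edge)
        seen = {u}
        queue = [u]
        while queue:
            cur = queue.pop()
            for nxt in adjacency[cur]:
                if nxt not in seen and frozenset((cur, nxt)) != edge:
                    seen.add(nxt)
                    queue.append(nxt)
        side = frozenset(labels[i] for i in seen if i in labels)
        if 2 <= len(side) <= len(taxa) - 2:
            if min(taxa) in side:
                side = taxa - side
            splits.add(side)
    return splits


def naive_rf(t1: Tree, t2: Tree) -> int:
    shared = t1.taxa & t2.taxa
    r1 = t1 if t1.taxa == shared else restrict_to_taxa(t1, shared)
    r2 = t2 if t2.taxa == shared else restrict_to_taxa(t2, shared)
    return len(naive_splits(r1) ^ naive_splits(r2))


# ---------------------------------------------------------------------------
# exhaustive MAST oracle


def is_agreement_set(t1: Tree, t2: Tree, subset: frozenset[str]) -> bool:
    if len(subset) < 2:
        return True
    a = restrict_to_taxa(t1, subset)
    b = restrict_to_taxa(t2, subset)
    return canonical_shape(a.root) == canonical_shape(b.root)


def exhaustive_mast_size(t1: Tree, t2: Tree) -> int:
    common = sorted(t1.taxa & t2.taxa)
    for size in range(len(common), 0, -1):
        for combo in itertools.combinations(common, size):
            if is_agreement_set(t1, t2, frozenset(combo)):
                return size
    return 0


# ---------------------------------------------------------------------------
# brute-force parsimony oracle


def brute_force_fitch(tree: Tree, character: dict) -> int:
    """Minimum changes over all assignments of {0,1} to free nodes."""
    nodes = list(tree.root.preorder())
    free: list[int] = []
    fixed: dict[int, int] = {}
    for node in nodes:
        if node.is_leaf:
            state = character[node.label]
            if state in ("?", None):
                free.append(id(node))
            else:
                fixed[id(node)] = int(state)
        else:
            free.append(id(node))
    best = None
    for assignment in itertools.product((0, 1), repeat=len(free)):
        states = dict(fixed)
        states.update(zip(free, assignment))
        changes = 0
        for node in nodes:
            for child in node.children:
                if states[id(node)] != states[id(child)]:
                    changes += 1
        if best is None or changes < best:
            best = changes
    return best or 0
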