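"""Pairwise tree comparison.

Implements the comparison toolbox: nontrivial bipartitions of the unrooted
tree, the Robinson-Foulds symmetric-difference distance (after restriction
to common taxa), the rooted maximum agreement subtree (MAST) with the
per-leaf agreement classification used for grey shading, and automated
tip-order harmonization of a tanglegram by an alternating barycenter
heuristic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import linear_sum_assignment

from .edit import common_taxa, restrict_to_taxa
from .tree import Node, Tree, TreeError


# ---------------------------------------------------------------------------
# bipartitions and Robinson-Foulds


@dataclass(frozen=True)
class Bipartition:
    """A nontrivial two-way split of a taxon set.

    ``side`` is the canonical half: the one NOT containing the
    lexicographically smallest taxon.  ``taxa`` is the full set, so the
    other half is always recoverable.
    """

    side: frozenset[str]
    taxa: frozenset[str]

    @staticmethod
    def of(side: frozenset[str], taxa: frozenset[str]) -> "Bipartition":
        if min(taxa) in side:
            side = taxa - side
        return Bipartition(side, taxa)

    @property
    def other(self) -> frozenset[str]:
        return self.taxa - self.side


def bipartitions(tree: Tree) -> frozenset[Bipartition]:
    """Nontrivial splits of the unrooted version of the tree.

    One bipartition per internal edge; splits with a single taxon on
    either side are excluded, and the root's artificial edge contributes
    no duplicate.
    """
    taxa = tree.taxa
    n = len(taxa)
    clades = tree.clades()
    out: set[Bipartition] = set()
    for node in tree.root.preorder():
        if node is tree.root or node.is_leaf:
            continue
        side = clades[id(node)]
        if 2 <= len(side) <= n - 2:
            out.add(Bipartition.of(side, taxa))
    return frozenset(out)


@dataclass(frozen=True)
class RFResult:
    common_taxon_count: int
    distance: int


def rf_distance(t1: Tree, t2: Tree) -> RFResult:
    """Robinson-Foulds distance after restriction to common taxa.

    Both trees are restricted to their shared taxa (suppressing unary
    nodes); the distance is the size of the symmetric difference of their
    nontrivial unrooted bipartition sets — the full symmetric-difference
    count, not half of it.
    """
    shared = common_taxa([t1, t2])
    if len(shared) < 4:
        raise TreeError(
            f"distance undefined: only {len(shared)} common taxa (need >= 4)"
        )
    r1 = t1 if t1.taxa == shared else restrict_to_taxa(t1, shared)
    r2 = t2 if t2.taxa == shared else restrict_to_taxa(t2, shared)
    b1, b2 = bipartitions(r1), bipartitions(r2)
    return RFResult(len(shared), len(b1 ^ b2))


# ---------------------------------------------------------------------------
# maximum agreement subtree (rooted)


class LeafClass(str, Enum):
    IN_CONSENSUS = "in_consensus"
    CONFLICTING = "conflicting"
    TREE_SPECIFIC = "tree_specific"


@dataclass
class AgreementResult:
    """MAST taxon set and the per-leaf shading classification.

    ``in_consensus`` leaves belong to the agreement set in both trees;
    ``tree_specific`` leaves are absent from the other tree; the remaining
    common leaves are ``conflicting``.  The three classes partition each
    tree's leaf set.
    """

    mast_taxa: frozenset[str]
    taxa1: frozenset[str]
    taxa2: frozenset[str]

    def classes(self, which: int) -> dict[str, LeafClass]:
        own = self.taxa1 if which == 1 else self.taxa2
        other = self.taxa2 if which == 1 else self.taxa1
        out: dict[str, LeafClass] = {}
        for taxon in own:
            if taxon in self.mast_taxa:
                out[taxon] = LeafClass.IN_CONSENSUS
            elif taxon not in other:
                out[taxon] = LeafClass.TREE_SPECIFIC
            else:
                out[taxon] = LeafClass.CONFLICTING
        return out

    def classes_for(self, tree: Tree) -> dict[str, LeafClass]:
        if tree.taxa == self.taxa1:
            return self.classes(1)
        if tree.taxa == self.taxa2:
            return self.classes(2)
        raise TreeError("tree does not match either side of this result")

    def to_rows(self) -> list[tuple[str, int, str]]:
        rows = [(t, 1, c.value) for t, c in sorted(self.classes(1).items())]
        rows += [(t, 2, c.value) for t, c in sorted(self.classes(2).items())]
        return rows


def _mast_dp(r1: Tree, r2: Tree, rng: random.Random | None) -> tuple[str, ...]:
    """Rooted MAST over two trees on the same taxon set.

    Dynamic program over node pairs; internal/internal cells solved by
    maximum-weight bipartite matching of the child subproblems.  Ties are
    broken toward the lexicographically smaller sorted taxon tuple, or
    uniformly at random when an rng is supplied.
    """
    nodes1 = list(r1.root.postorder())
    nodes2 = list(r2.root.postorder())
    leafset2 = {id(v): frozenset(l.label for l in v.leaves()) for v in nodes2}
    memo: dict[tuple[int, int], tuple[str, ...]] = {}

    def better(a: tuple[str, ...], b: tuple[str, ...]) -> tuple[str, ...]:
        if len(a) != len(b):
            return a if len(a) > len(b) else b
        if a == b:
            return a
        if rng is not None:
            return a if rng.random() < 0.5 else b
        return min(a, b)

    for u in nodes1:
        for v in nodes2:
            key = (id(u), id(v))
            if u.is_leaf:
                memo[key] = (u.label,) if u.label in leafset2[id(v)] else ()
                continue
            if v.is_leaf:
                found = any(l.label == v.label for l in u.leaves())
                memo[key] = (v.label,) if found else ()
                continue
            best: tuple[str, ...] = ()
            for c in u.children:
                best = better(best, memo[(id(c), id(v))])
            for d in v.children:
                best = better(best, memo[(id(u), id(d))])
            # maximum-weight matching of children(u) x children(v)
            cu, cv = u.children, v.children
            weights = np.array(
                [[len(memo[(id(c), id(d))]) for d in cv] for c in cu], dtype=float
            )
            rows, cols = linear_sum_assignment(weights, maximize=True)
            matched: list[str] = []
            for i, j in zip(rows, cols):
                matched.extend(memo[(id(cu[i]), id(cv[j]))])
            best = better(best, tuple(sorted(matched)))
            memo[key] = best
    return memo[(id(r1.root), id(r2.root))]


def mast(t1: Tree, t2: Tree, seed: int | None = None) -> AgreementResult:
    """Rooted maximum agreement subtree of two trees.

    Both trees are first restricted to their common taxa; the result is a
    maximum-cardinality subset S of those taxa such that the induced
    rooted subtrees on S are isomorphic (ignoring child order, after
    suppressing unary nodes), together with the shading classification.
    """
    shared = common_taxa([t1, t2])
    if not shared:
        raise TreeError("no common taxa: agreement subtree undefined")
    if len(shared) == 1:
        return AgreementResult(frozenset(shared), t1.taxa, t2.taxa)
    r1 = t1 if t1.taxa == shared else restrict_to_taxa(t1, shared)
    r2 = t2 if t2.taxa == shared else restrict_to_taxa(t2, shared)
    rng = random.Random(seed) if seed is not None else None
    chosen = _mast_dp(r1, r2, rng)
    return AgreementResult(frozenset(chosen), t1.taxa, t2.taxa)


# ---------------------------------------------------------------------------
# tanglegram untangling


@dataclass
class TanglegramLayout:
    order1: list[str]
    order2: list[str]
    crossings: int


def crossing_count(order1: list[str], order2: list[str]) -> int:
    """Pairs of common taxa appearing in opposite relative order.

    Equals the number of line crossings in a tanglegram drawn with
    straight connectors between matching tips.
    """
    shared = set(order1) & set(order2)
    pos1 = {t: i for i, t in enumerate(order1)}
    seq = [pos1[t] for t in order2 if t in shared]
    count = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if seq[i] > seq[j]:
                count += 1
    return count


def _barycenter_pass(tree: Tree, fixed_order: list[str]) -> None:
    """Sort every node's children by mean rank of their common leaves.

    Children with no common leaves go after those with, keeping their
    previous relative order; ties on the mean rank break by smallest
    leaf name.
    """
    rank = {t: i for i, t in enumerate(fixed_order)}
    info: dict[int, tuple[list[int], str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            ranks = [rank[node.label]] if node.label in rank else []
            info[id(node)] = (ranks, node.label or "")
        else:
            ranks = []
            name = min(info[id(c)][1] for c in node.children)
            for c in node.children:
                ranks.extend(info[id(c)][0])
            info[id(node)] = (ranks, name)
    for node in tree.root.preorder():
        if node.is_leaf or len(node.children) < 2:
            continue
        keyed = []
        for i, c in enumerate(node.children):
            ranks, name = info[id(c)]
            if ranks:
                keyed.append(((0, sum(ranks) / len(ranks), name), c))
            else:
                keyed.append(((1, float(i), name), c))
        keyed.sort(key=lambda kv: kv[0])
        node.children = [c for _, c in keyed]


def auto_swap(
    t1: Tree, t2: Tree, max_rounds: int = 10, seed: int = 0
) -> tuple[Tree, Tree, TanglegramLayout]:
    """Harmonize tip orders so taxa appear in the same order in both trees.

    Alternating barycenter heuristic: holding one tree fixed, the other
    tree's children are sorted by the mean rank of their common leaves in
    the fixed tip order; sides alternate until a fixpoint or max_rounds.
    Only child orders change, never topology, and the crossing count never
    increases (an increasing half-step is reverted and iteration stops).
    """
    del seed  # the heuristic is deterministic; kept for interface stability
    a, b = t1.copy(), t2.copy()
    best = crossing_count(a.leaf_labels(), b.leaf_labels())
    for _ in range(max_rounds):
        changed = False
        for mover, fixed in ((a, b), (b, a)):
            before_order = mover.leaf_labels()
            _barycenter_pass(mover, fixed.leaf_labels())
            after = crossing_count(a.leaf_labels(), b.leaf_labels())
            if after > best:
                _restore_order(mover, before_order)
                layout = TanglegramLayout(a.leaf_labels(), b.leaf_labels(), best)
                return a, b, layout
            if mover.leaf_labels() != before_order:
                changed = True
            best = after
        if not changed:
            break
    return a, b, TanglegramLayout(a.leaf_labels(), b.leaf_labels(), best)


def _restore_order(tree: Tree, order: list[str]) -> None:
    _barycenter_pass(tree, order)
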