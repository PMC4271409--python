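"""MRP supertree inference.

Matrix representation with parsimony: each nontrivial clade of each rooted
source tree becomes a binary character (clade members 1, other taxa of that
source tree 0, absent taxa ?), a synthetic all-zero outgroup row roots the
analysis, and the matrix is analysed with equal-weight Fitch parsimony.
Small problems are solved exactly (all most-parsimonious topologies via
exhaustive stepwise-addition enumeration with branch-and-bound pruning);
larger ones by seeded random-addition + nearest-neighbour-interchange hill
climbing.  The supertree returned is the strict consensus of the MP trees,
rooted on the synthetic outgroup, with that leaf removed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .compare import bipartitions
from .tree import Node, Tree, TreeError

MRP_ROOT = "__MRP_ROOT__"

# leaf state sets as 2-bit masks: 1 = {0}, 2 = {1}, 3 = {0,1} (missing)
_STATE_MASK = {"0": 1, "1": 2, "?": 3, 0: 1, 1: 2, None: 3}


@dataclass(frozen=True)
class Character:
    """One binary MRP character with its provenance."""

    source: str
    clade: frozenset[str]


@dataclass
class MRPMatrix:
    """Taxa-by-characters matrix over {0, 1, ?} (Baum-Ragan coding)."""

    taxa: list[str]
    characters: list[Character]
    data: np.ndarray  # uint8 masks, shape (n_taxa, n_characters)
    warnings: list[str] = field(default_factory=list)

    def column(self, j: int) -> dict[str, str]:
        inv = {1: "0", 2: "1", 3: "?"}
        return {t: inv[int(self.data[i, j])] for i, t in enumerate(self.taxa)}

    def state(self, taxon: str, j: int) -> str:
        return self.column(j)[taxon]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)


def mrp_matrix(source_trees: list[Tree], names: list[str] | None = None) -> MRPMatrix:
    """Baum-Ragan matrix of a set of rooted source trees.

    One character per nontrivial clade (a proper internal node below the
    root whose clade has >= 2 taxa), ordered by (source tree, clade
    preorder).  The synthetic outgroup row ``__MRP_ROOT__`` is 0 in every
    character.  A source tree with < 3 leaves contributes no characters.
    """
    if not source_trees:
        raise TreeError("mrp_matrix requires at least one source tree")
    if names is None:
        names = [f"tree{i + 1}" for i in range(len(source_trees))]
    union: set[str] = set()
    for t in source_trees:
        union |= t.taxa
    taxa = sorted(union) + [MRP_ROOT]
    index = {t: i for i, t in enumerate(taxa)}

    chars: list[Character] = []
    columns: list[np.ndarray] = []
    warnings: list[str] = []
    for name, tree in zip(names, source_trees):
        tree_taxa = tree.taxa
        clades = tree.clades()
        count = 0
        for node in tree.root.preorder():
            if node is tree.root or node.is_leaf:
                continue
            clade = clades[id(node)]
            if len(clade) < 2 or clade == tree_taxa:
                continue
            col = np.full(len(taxa), _STATE_MASK["?"], dtype=np.uint8)
            for t in tree_taxa:
                col[index[t]] = _STATE_MASK["1" if t in clade else "0"]
            col[index[MRP_ROOT]] = _STATE_MASK["0"]
            chars.append(Character(name, clade))
            columns.append(col)
            count += 1
        if count == 0:
            warnings.append(f"source tree {name!r} contributes no characters")
    data = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(taxa), 0), dtype=np.uint8)
    )
    return MRPMatrix(taxa, chars, data, warnings)


# ---------------------------------------------------------------------------
# parsimony scoring


def _hartigan_cost(tree: Tree, masks: dict[str, np.ndarray]) -> np.ndarray:
    """Per-character minimum change counts on an arbitrary (possibly
    multifurcating) tree; exact for unordered binary characters."""
    nchar = next(iter(masks.values())).shape[0] if masks else 0
    total = np.zeros(nchar, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            sets[id(node)] = masks[node.label]  # type: ignore[index]
            continue
        c0 = np.zeros(nchar, dtype=np.int64)
        c1 = np.zeros(nchar, dtype=np.int64)
        for child in node.children:
            m = sets[id(child)]
            c0 += m & 1
            c1 += (m >> 1) & 1
        k = np.maximum(c0, c1)
        total += len(node.children) - k
        sets[id(node)] = ((c0 == k).astype(np.uint8)) | (
            ((c1 == k).astype(np.uint8)) << 1
        )
    return total


def fitch_length(tree: Tree, character: dict) -> int:
    """Minimum number of state changes for one binary character.

    ``character`` maps each leaf label to 0, 1 or "?" (missing = either
    state).  Small-parsimony (Fitch/Hartigan) bottom-up pass.
    """
    missing = tree.taxa - set(character)
    if missing:
        raise TreeError(f"character missing states for: {sorted(missing)}")
    masks = {
        t: np.array([_STATE_MASK[character[t]]], dtype=np.uint8) for t in tree.taxa
    }
    return int(_hartigan_cost(tree, masks)[0])


def matrix_parsimony_score(tree: Tree, matrix: MRPMatrix) -> int:
    """Sum of Fitch lengths over all characters of the matrix."""
    if tree.taxa != frozenset(matrix.taxa):
        raise TreeError("tree leaf set does not match matrix taxa")
    if matrix.n_characters == 0:
        return 0
    masks = {t: matrix.data[i, :] for i, t in enumerate(matrix.taxa)}
    return int(_hartigan_cost(tree, masks).sum())


# ---------------------------------------------------------------------------
# tree search

# Internal search representation: an unrooted binary tree over taxon
# indices, stored rooted at taxon 0 as a nested structure in which a leaf
# is an int and an internal node is a 2-tuple; the structure spans taxa
# 1..n-1 and taxon 0 hangs above its root.


def _fitch_tuple(struct, leaf_masks: np.ndarray):
    if isinstance(struct, int):
        return leaf_masks[struct], 0
    (a, ca), (b, cb) = _fitch_tuple(struct[0], leaf_masks), _fitch_tuple(
        struct[1], leaf_masks
    )
    inter = a & b
    zero = inter == 0
    states = np.where(zero, a | b, inter)
    return states, ca + cb + int(np.count_nonzero(zero))


def _score_struct(struct, leaf_masks: np.ndarray) -> int:
    states, cost = _fitch_tuple(struct, leaf_masks)
    return cost + int(np.count_nonzero((states & leaf_masks[0]) == 0))


def _attachments(struct, x: int):
    """All structures obtained by attaching leaf x on one edge of struct."""
    yield (struct, x)
    if not isinstance(struct, int):
        for variant in _attachments(struct[0], x):
            yield (variant, struct[1])
        for variant in _attachments(struct[1], x):
            yield (struct[0], variant)


def _struct_leaves(struct) -> list[int]:
    if isinstance(struct, int):
        return [struct]
    return _struct_leaves(struct[0]) + _struct_leaves(struct[1])


def _struct_to_tree(struct, taxa: list[str]) -> Tree:
    def conv(s) -> Node:
        if isinstance(s, int):
            return Node(label=taxa[s])
        node = Node()
        node.add_child(conv(s[0]))
        node.add_child(conv(s[1]))
        return node

    root = Node()
    root.add_child(Node(label=taxa[0]))
    root.add_child(conv(struct))
    return Tree(root)


@dataclass
class SearchConfig:
    """Parsimony search settings.

    Problems with at most ``exhaustive_threshold`` taxa are solved by
    exhaustive branch-and-bound enumeration (returning ALL MP topologies);
    larger ones by ``starts`` random-addition sequences each followed by
    NNI hill climbing for at most ``max_rounds`` improvement rounds.
    """

    exhaustive_threshold: int = 9
    starts: int = 8
    max_rounds: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exhaustive_threshold < 4:
            raise TreeError("exhaustive threshold must be >= 4")
        if self.starts < 1:
            raise TreeError("need at least one search start")


def _greedy_addition(order: list[int], leaf_masks: np.ndarray):
    """Stepwise addition placing each taxon at its cheapest edge."""
    base, first, *rest = order
    assert base == 0
    struct = first
    for x in rest:
        best = None
        best_score = None
        for cand in _attachments(struct, x):
            s = _score_struct(cand, leaf_masks)
            if best_score is None or s < best_score:
                best, best_score = cand, s
        struct = best
    return struct


def _nni_neighbors(struct):
    """All structures one nearest-neighbour interchange away."""
    if isinstance(struct, int):
        return
    a, b = struct
    if not isinstance(a, int):
        x, y = a
        yield ((x, b), y)
        yield ((y, b), x)
    if not isinstance(b, int):
        x, y = b
        yield (x, (y, a))
        yield (y, (x, a))
    for v in _nni_neighbors(a):
        yield (v, b)
    for v in _nni_neighbors(b):
        yield (a, v)


def _canonical(struct) -> str:
    if isinstance(struct, int):
        return str(struct)
    a, b = _canonical(struct[0]), _canonical(struct[1])
    return f"({a},{b})" if a < b else f"({b},{a})"


def _exhaustive_search(leaf_masks: np.ndarray, n: int, upper: int):
    """All minimum-score unrooted topologies, by B&B over addition order.

    The parsimony score of a partial tree never decreases when a taxon is
    added, so any partial tree scoring above the best complete score found
    so far can be discarded with its whole subtree of completions.
    """
    best = [upper]
    results: list = []

    def recurse(struct, next_taxon: int) -> None:
        s = _score_struct(struct, leaf_masks)
        if s > best[0]:
            return
        if next_taxon == n:
            if s < best[0]:
                best[0] = s
                results.clear()
            results.append(struct)
            return
        for cand in _attachments(struct, next_taxon):
            recurse(cand, next_taxon + 1)

    recurse(1, 2)
    # results may contain leftovers scoring exactly the old bound; re-filter
    final = [r for r in results if _score_struct(r, leaf_masks) == best[0]]
    return final, best[0]


def _heuristic_search(leaf_masks: np.ndarray, n: int, config: SearchConfig):
    rng = random.Random(config.seed)
    best_score: int | None = None
    best_structs: dict[tuple, object] = {}
    for _ in range(config.starts):
        order = list(range(1, n))
        rng.shuffle(order)
        struct = _greedy_addition([0] + order, leaf_masks)
        score = _score_struct(struct, leaf_masks)
        for _ in range(config.max_rounds):
            improved = False
            for cand in _nni_neighbors(struct):
                s = _score_struct(cand, leaf_masks)
                if s < score:
                    struct, score = cand, s
                    improved = True
                    break
            if not improved:
                break
        if best_score is None or score < best_score:
            best_score = score
            best_structs = {_canonical(struct): struct}
        elif score == best_score:
            best_structs.setdefault(_canonical(struct), struct)
    return list(best_structs.values()), best_score


def mp_search(matrix: MRPMatrix, config: SearchConfig | None = None) -> list[Tree]:
    """Most-parsimonious trees for an MRP matrix.

    Returns rooted representations (rooted at the synthetic outgroup when
    present, else at the first taxon); their unrooted topologies are the
    MP set, deduplicated by bipartition set.
    """
    if config is None:
        config = SearchConfig()
    n = matrix.n_taxa
    if n < 4:
        raise TreeError("parsimony search needs at least 4 taxa")
    # put the rooting taxon at index 0 of the search ordering
    taxa = list(matrix.taxa)
    anchor = taxa.index(MRP_ROOT) if MRP_ROOT in taxa else 0
    order = [taxa[anchor]] + [t for i, t in enumerate(taxa) if i != anchor]
    tindex = {t: i for i, t in enumerate(matrix.taxa)}
    leaf_masks = np.stack([matrix.data[tindex[t], :] for t in order], axis=0)

    if n <= config.exhaustive_threshold:
        # seed the bound with a greedy tree
        if matrix.n_characters:
            greedy = _greedy_addition(list(range(n)), leaf_masks)
            upper = _score_struct(greedy, leaf_masks)
        else:
            upper = 0
        structs, _ = _exhaustive_search(leaf_masks, n, upper)
    else:
        structs, _ = _heuristic_search(leaf_masks, n, config)
    return [_struct_to_tree(s, order) for s in structs]


# ---------------------------------------------------------------------------
# consensus and the full pipeline


def strict_consensus(trees: list[Tree]) -> Tree:
    """Strict consensus of rooted trees on one taxon set.

    Keeps exactly the clades present in every input, multifurcating where
    the inputs disagree.
    """
    if not trees:
        raise TreeError("strict_consensus requires at least one tree")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise TreeError("strict consensus requires identical taxon sets")

    def proper_clades(t: Tree) -> set[frozenset[str]]:
        clades = t.clades()
        out = set()
        for node in t.root.preorder():
            if node is t.root or node.is_leaf:
                continue
            c = clades[id(node)]
            if 2 <= len(c) < len(taxa):
                out.add(c)
        return out

    shared = proper_clades(trees[0])
    for t in trees[1:]:
        shared &= proper_clades(t)
    return tree_from_clades(taxa, shared)


def tree_from_clades(taxa: frozenset[str], clades: set[frozenset[str]]) -> Tree:
    """Build the rooted tree realizing a nested family of clades.

    The clades must be pairwise compatible (nested or disjoint); children
    are ordered deterministically by smallest member.
    """
    root = Node()
    holder: dict[int, frozenset[str]] = {id(root): taxa}
    nodes = [root]
    for clade in sorted(clades, key=lambda c: (-len(c), sorted(c))):
        host = root
        for cand in nodes:
            s = holder[id(cand)]
            if clade < s and len(s) < len(holder[id(host)]):
                host = cand
        node = Node()
        holder[id(node)] = clade
        host.add_child(node)
        nodes.append(node)
    # deepest-containing assignment for leaves
    for taxon in taxa:
        host = root
        for cand in nodes:
            s = holder[id(cand)]
            if taxon in s and len(s) < len(holder[id(host)]):
                host = cand
        host.add_child(Node(label=taxon))

    def sort_rec(node: Node) -> str:
        if node.is_leaf:
            return node.label or ""
        keys = [(sort_rec(c), c) for c in node.children]
        keys.sort(key=lambda kv: kv[0])
        node.children = [c for _, c in keys]
        return keys[0][0]

    sort_rec(root)
    return Tree(root)


def _drop_leaf(tree: Tree, label: str) -> Tree:
    keep = tree.taxa - {label}
    if len(keep) < 2:
        raise TreeError("cannot drop leaf from a 2-taxon tree")
    from .edit import restrict_to_taxa

    return restrict_to_taxa(tree, keep)


def mrp_supertree(
    source_trees: list[Tree], config: SearchConfig | None = None
) -> Tree:
    """MRP supertree of a set of rooted source trees.

    Pipeline: Baum-Ragan matrix → parsimony search → strict consensus of
    the MP trees → root on the synthetic outgroup → remove it.  The result
    is a rooted tree on the union of the source taxa.
    """
    union: set[str] = set()
    for t in source_trees:
        union |= t.taxa
    if len(union) < 4:
        raise TreeError("supertree needs at least 4 distinct taxa")
    matrix = mrp_matrix(source_trees)
    mp_trees = mp_search(matrix, config)
    consensus = strict_consensus(mp_trees)
    # consensus trees built here are rooted with MRP_ROOT attached at the
    # root, so removing that leaf yields the rooted supertree directly
    return _drop_leaf(consensus, MRP_ROOT)


def dedupe_by_splits(trees: list[Tree]) -> list[Tree]:
    """Drop trees whose unrooted bipartition set duplicates an earlier one."""
    seen: set[frozenset] = set()
    out: list[Tree] = []
    for t in trees:
        key = bipartitions(t)
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# matrix export


def to_nexus(matrix: MRPMatrix) -> str:
    """NEXUS DATA block (symbols "01", missing "?")."""
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
        "    MATRIX",
    ]
    width = max((len(t) for t in matrix.taxa), default=0)
    inv = {1: "0", 2: "1", 3: "?"}
    for i, taxon in enumerate(matrix.taxa):
        row = "".join(inv[int(v)] for v in matrix.data[i, :])
        lines.append(f"    {taxon.ljust(width)}  {row}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def to_phylip(matrix: MRPMatrix) -> str:
    """PHYLIP relaxed-format matrix."""
    inv = {1: "0", 2: "1", 3: "?"}
    lines = [f"{matrix.n_taxa} {matrix.n_characters}"]
    for i, taxon in enumerate(matrix.taxa):
        row = "".join(inv[int(v)] for v in matrix.data[i, :])
        lines.append(f"{taxon} {row}")
    return "\n".join(lines) + "\n"
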