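"""MRP matrix coding, parsimony scoring, tree search and consensus."""

import itertools
import random

import pytest

from treebench import (
    MRP_ROOT,
    SearchConfig,
    Tree,
    TreeError,
    bipartitions,
    canonical_shape,
    fitch_length,
    matrix_parsimony_score,
    mp_search,
    mrp_matrix,
    mrp_supertree,
    rename_taxa,
    rf_distance,
    strict_consensus,
    to_nexus,
    to_phylip,
    write_newick,
)
from treebench.simulate import definitive_subtree_sample, random_tree
from treebench.tree import Node

from conftest import brute_force_fitch, make_random_tree


def rooted_with_outgroup(tree: Tree) -> Tree:
    """Attach the synthetic outgroup leaf above the root."""
    work = tree.copy()
    root = Node()
    root.add_child(Node(label=MRP_ROOT))
    root.add_child(work.root)
    return Tree(root)


class TestMatrix:
    def test_single_source_single_character(self, t):
        m = mrp_matrix([t("((A,B),C);")])
        assert m.n_characters == 1
        assert m.column(0) == {"A": "1", "B": "1", "C": "0", MRP_ROOT: "0"}

    def test_missing_taxa_coded_as_question(self, t):
        m = mrp_matrix([t("((A,B),C);"), t("((B,C),D);")])
        assert m.n_characters == 2
        assert m.column(1) == {"A": "?", "B": "1", "C": "1", "D": "0", MRP_ROOT: "0"}

    def test_two_leaf_source_contributes_nothing(self, t):
        m = mrp_matrix([t("(A,B);")])
        assert m.n_characters == 0
        assert m.warnings

    def test_character_order_is_source_then_preorder(self, t):
        m = mrp_matrix([t("(((A,B),C),D);"), t("((E,F),G);")])
        assert [c.source for c in m.characters] == ["tree1", "tree1", "tree2"]
        assert m.characters[0].clade == {"A", "B", "C"}  # preorder: larger first
        assert m.characters[1].clade == {"A", "B"}

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_equivariance(self, seed):
        tree = make_random_tree(6, seed)
        mapping = {x: f"Z_{x}" for x in tree.taxa}
        renamed = rename_taxa([tree], mapping)[0]
        m1, m2 = mrp_matrix([tree]), mrp_matrix([renamed])
        assert m1.n_characters == m2.n_characters
        for j in range(m1.n_characters):
            col1 = m1.column(j)
            col2 = m2.column(j)
            assert {mapping.get(k, k): v for k, v in col1.items()} == col2


class TestFitch:
    def test_one_change_on_balanced_quartet(self, t):
        tree = t("((A,B),(C,D));")
        assert fitch_length(tree, {"A": 0, "B": 0, "C": 1, "D": 1}) == 1

    def test_constant_character_costs_nothing(self, t):
        tree = t("(((A,B),C),(D,E));")
        assert fitch_length(tree, dict.fromkeys("ABCDE", 1)) == 0

    def test_missing_state_is_free(self, t):
        tree = t("((A,B),(C,D));")
        assert fitch_length(tree, {"A": 0, "B": "?", "C": 1, "D": 1}) == 1

    def test_multifurcating_tree(self, t):
        tree = t("((A,B,C),(D,E,F));")
        character = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1, "F": 0}
        assert fitch_length(tree, character) == brute_force_fitch(tree, character)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_enumeration(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 6)
        tree = make_random_tree(n, seed * 19 + 5)
        character = {
            taxon: rng.choice([0, 1, "?"]) for taxon in tree.taxa
        }
        assert fitch_length(tree, character) == brute_force_fitch(tree, character)


class TestMatrixScore:
    def test_single_character_equals_fitch(self, t):
        m = mrp_matrix([t("((A,B),C);")])
        tree = rooted_with_outgroup(t("((A,B),C);"))
        assert matrix_parsimony_score(tree, m) == fitch_length(tree, m.column(0))

    def test_empty_matrix_scores_zero(self, t):
        m = mrp_matrix([t("(A,B);")])
        tree = rooted_with_outgroup(t("(A,B);"))
        assert matrix_parsimony_score(tree, m) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_model_tree_scores_one_change_per_clade(self, seed):
        model = make_random_tree(7, seed * 23)
        m = mrp_matrix([model])
        scored = matrix_parsimony_score(rooted_with_outgroup(model), m)
        assert scored == m.n_characters

    def test_leaf_set_mismatch_raises(self, t):
        m = mrp_matrix([t("((A,B),C);")])
        with pytest.raises(TreeError):
            matrix_parsimony_score(t("((A,B),C);"), m)


class TestSearch:
    def test_single_source_recovered(self, t):
        m = mrp_matrix([t("((A,B),C);")])
        mp = mp_search(m)
        assert len(mp) == 1
        assert matrix_parsimony_score(mp[0], m) == 1
        # the unrooted topology groups A,B against C and the synthetic root
        assert {frozenset(b.side) for b in bipartitions(mp[0])} == {
            frozenset({"C", MRP_ROOT})
        }

    def test_zero_characters_returns_all_topologies(self, t):
        m = mrp_matrix([t("(A,B);"), t("(C,D);")])
        assert m.n_characters == 0
        mp = mp_search(m)  # 5 taxa with the synthetic root: 15 topologies
        assert len(mp) == 15
        shapes = {frozenset(bipartitions(x)) for x in mp}
        assert len(shapes) == 15

    @pytest.mark.parametrize("seed", range(5))
    def test_heuristic_reaches_exhaustive_score(self, seed):
        rng = random.Random(seed)
        sources = [
            random_tree(rng.sample([f"T{i}" for i in range(7)], 5), rng)
            for _ in range(4)
        ]
        m = mrp_matrix(sources)
        exact = mp_search(m, SearchConfig(exhaustive_threshold=10, seed=seed))
        heur = mp_search(
            m, SearchConfig(exhaustive_threshold=4, starts=8, seed=seed)
        )
        best_exact = matrix_parsimony_score(exact[0], m)
        best_heur = min(matrix_parsimony_score(x, m) for x in heur)
        assert best_heur == best_exact
        # heuristic may return a subset of the MP set, never a wrong tree
        exact_keys = {frozenset(bipartitions(x)) for x in exact}
        if best_heur == best_exact:
            assert all(frozenset(bipartitions(x)) in exact_keys for x in heur)


class TestStrictConsensus:
    def test_identity(self, t):
        tree = t("(((A,B),C),(D,E));")
        out = strict_consensus([tree, tree.copy()])
        assert canonical_shape(out.root) == canonical_shape(tree.root)

    def test_total_conflict_gives_star(self, t):
        out = strict_consensus([t("((A,B),(C,D));"), t("((A,C),(B,D));")])
        assert write_newick(out) == "(A,B,C,D);"

    def test_partial_agreement(self, t):
        out = strict_consensus([t("((A,B),(C,D));"), t("(((A,B),C),D);")])
        assert write_newick(out) == "((A,B),C,D);"

    def test_unequal_taxa_raise(self, t):
        with pytest.raises(TreeError):
            strict_consensus([t("(A,B);"), t("(A,C);")])

    @pytest.mark.parametrize("seed", range(6))
    def test_output_clades_are_exactly_the_intersection(self, seed):
        trees = [make_random_tree(7, seed * 31 + k) for k in range(3)]
        out = strict_consensus(trees)

        def clade_set(tree):
            clades = tree.clades()
            return {
                clades[id(n)]
                for n in tree.root.preorder()
                if not n.is_leaf and n is not tree.root
                and 2 <= len(clades[id(n)]) < len(tree.taxa)
            }

        expected = clade_set(trees[0])
        for x in trees[1:]:
            expected &= clade_set(x)
        assert clade_set(out) == expected


class TestSupertree:
    def test_compatible_sources_combine(self, t):
        result = mrp_supertree([t("((A,B),C);"), t("((B,C),D);")])
        assert canonical_shape(result.root) == canonical_shape(t("(((A,B),C),D);").root)

    def test_single_source_round_trips(self, t):
        source = t("(((A,B),C),D);")
        result = mrp_supertree([source])
        assert canonical_shape(result.root) == canonical_shape(source.root)

    def test_duplicate_sources_idempotent(self, t):
        source = t("(((A,B),C),D);")
        result = mrp_supertree([source, source.copy()])
        assert canonical_shape(result.root) == canonical_shape(source.root)

    @pytest.mark.parametrize("seed", range(3))
    def test_model_recovery_from_definitive_subtrees(self, seed):
        rng = random.Random(seed)
        model = random_tree([f"T{i + 1}" for i in range(8)], rng)
        sources = definitive_subtree_sample(model, 6, 5, rng)
        result = mrp_supertree(sources, SearchConfig(exhaustive_threshold=9))
        assert rf_distance(result, model).distance == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_splits_compatible_with_model_without_full_coverage(self, seed):
        rng = random.Random(seed + 100)
        from treebench import restrict_to_taxa

        model = random_tree([f"T{i + 1}" for i in range(8)], rng)
        labels = sorted(model.taxa)
        sources = [
            restrict_to_taxa(model, frozenset(rng.sample(labels, 5)))
            for _ in range(3)
        ]
        result = mrp_supertree(sources, SearchConfig(exhaustive_threshold=9))
        model_splits = {b.side for b in bipartitions(model)}
        for split in bipartitions(result):
            # compatibility: the split never conflicts with a model split
            s1 = split.side
            for s2 in model_splits:
                taxa = model.taxa
                assert (
                    not (s1 & s2)
                    or not (s1 - s2)
                    or not (s2 - s1)
                    or not (taxa - (s1 | s2))
                )


class TestExports:
    def test_nexus_block(self, t):
        text = to_nexus(mrp_matrix([t("((A,B),C);"), t("((B,C),D);")]))
        assert text.startswith("#NEXUS")
        assert "NTAX=5 NCHAR=2" in text
        assert 'SYMBOLS="01" MISSING=?' in text
        assert MRP_ROOT in text

    def test_phylip_matrix(self, t):
        text = to_phylip(mrp_matrix([t("((A,B),C);")]))
        lines = text.strip().split("\n")
        assert lines[0] == "4 1"
        assert len(lines) == 5
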