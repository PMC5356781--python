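"""Wagner parsimony: oracle equivalence, invariants, search, consensus."""
import itertools

import numpy as np
import pytest

from nodulephylo import (CharacterMatrix, ValidationError, assign_edge_changes,
                         search_mpt, strict_consensus, wagner_length)
from nodulephylo.tree import PhyloTree, enumerate_topologies

from oracles import all_topologies, brute_force_wagner, fitch_length, random_topology


def _tree_from_edges(edges, taxa):
    return PhyloTree(edges, dict(enumerate(taxa)))


def _leaf_states(matrix):
    return {i: matrix.states[i].tolist() for i in range(matrix.n_taxa)}


class TestWagnerLength:
    def test_constant_character_is_free(self):
        m = CharacterMatrix(list("ABCD"), ["c"], np.ones((4, 1), int))
        for t in enumerate_topologies(list("ABCD")):
            assert wagner_length(t, m) == 0

    def test_binary_split_example(self):
        # A=0,B=0,C=1,D=1 on AB|CD needs exactly one change
        m = CharacterMatrix(list("ABCD"), ["c"], np.array([[0], [0], [1], [1]]))
        ab_cd = next(t for t in enumerate_topologies(list("ABCD"))
                     if frozenset("CD") in t.bipartitions())
        assert wagner_length(ab_cd, m) == 1

    def test_ordered_states_example(self):
        # A=0,B=2,C=1,D=1 on AB|CD costs 2 (brute force over 3^2 labelings)
        m = CharacterMatrix(list("ABCD"), ["c"], np.array([[0], [2], [1], [1]]),
                            "ordered-ternary")
        ab_cd = next(t for t in enumerate_topologies(list("ABCD"))
                     if frozenset("CD") in t.bipartitions())
        assert wagner_length(ab_cd, m) == 2
        assert brute_force_wagner([tuple(e) for e in ab_cd.edges()],
                                  _leaf_states(m)) == 2

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 7))
            c = int(rng.integers(1, 9))
            taxa = [f"t{i}" for i in range(n)]
            m = CharacterMatrix(taxa, [f"c{j}" for j in range(c)],
                                rng.integers(0, 3, size=(n, c)), "ordered-ternary")
            edges = random_topology(rng, n)
            tree = _tree_from_edges(edges, taxa)
            assert wagner_length(tree, m) == brute_force_wagner(edges, _leaf_states(m))

    def test_equals_fitch_on_binary_matrices(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 8))
            c = int(rng.integers(1, 10))
            taxa = [f"t{i}" for i in range(n)]
            m = CharacterMatrix(taxa, [f"c{j}" for j in range(c)],
                                rng.integers(0, 2, size=(n, c)))
            edges = random_topology(rng, n)
            tree = _tree_from_edges(edges, taxa)
            assert wagner_length(tree, m) == fitch_length(edges, _leaf_states(m))

    def test_invariant_under_taxon_reordering(self, rng, quartet_matrix):
        tree = next(enumerate_topologies(quartet_matrix.taxa))
        base = wagner_length(tree, quartet_matrix)
        for perm in itertools.permutations(quartet_matrix.taxa):
            assert wagner_length(tree, quartet_matrix.reorder(list(perm))) == base

    def test_invariant_under_rerooting(self, rng):
        # the internal rooting choice must not affect the length
        from nodulephylo.parsimony import _farris_intervals
        taxa = [f"t{i}" for i in range(6)]
        m = CharacterMatrix(taxa, [f"c{j}" for j in range(5)],
                            rng.integers(0, 3, size=(6, 5)), "ordered-ternary")
        tree = _tree_from_edges(random_topology(rng, 6), taxa)
        lengths = {_farris_intervals(tree, m, root_label=t)[-1] for t in taxa}
        assert len(lengths) == 1

    def test_length_bounded_below_by_state_range(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        m = CharacterMatrix(taxa, [f"c{j}" for j in range(6)],
                            rng.integers(0, 3, size=(5, 6)), "ordered-ternary")
        tree = _tree_from_edges(random_topology(rng, 5), taxa)
        total = wagner_length(tree, m)
        bound = int((m.states.max(axis=0) - m.states.min(axis=0)).sum())
        assert total >= bound

    def test_taxa_mismatch_rejected(self, quartet_matrix):
        tree = next(enumerate_topologies(["A", "B", "C", "X"]))
        with pytest.raises(ValidationError, match="match"):
            wagner_length(tree, quartet_matrix)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 1), (5, 15), (7, 945)])
    def test_double_factorial_counts(self, n, count):
        labels = [f"t{i}" for i in range(n)]
        trees = list(enumerate_topologies(labels))
        assert len(trees) == count
        assert len({t.bipartitions() for t in trees}) == count

    def test_cap_enforced(self):
        with pytest.raises(ValidationError, match="cap"):
            next(enumerate_topologies([f"t{i}" for i in range(11)]))


class TestSearch:
    def test_clean_split_recovers_unique_mpt(self, quartet_matrix):
        mpts = search_mpt(quartet_matrix)
        assert len(mpts.trees) == 1
        assert frozenset("CD") in mpts.trees[0].bipartitions()
        assert mpts.length == 10  # 5 derived states on each side of one edge

    def test_all_constant_matrix_ties_every_topology(self):
        m = CharacterMatrix(list("ABCD"), ["c"], np.ones((4, 1), int))
        mpts = search_mpt(m)
        assert mpts.length == 0
        assert len(mpts.trees) == mpts.n_examined == 3

    def test_min_length_matches_full_brute_force(self, rng):
        for _ in range(8):
            taxa = [f"t{i}" for i in range(5)]
            m = CharacterMatrix(taxa, [f"c{j}" for j in range(8)],
                                rng.integers(0, 2, size=(5, 8)))
            mpts = search_mpt(m)
            oracle = min(
                brute_force_wagner(edges, _leaf_states(m))
                for edges in all_topologies(5)
            )
            assert mpts.length == oracle
            assert mpts.n_examined == 15

    def test_two_taxa_manhattan_distance(self):
        m = CharacterMatrix(["A", "B"], ["c1", "c2"],
                            np.array([[0, 2], [2, 2]]), "ordered-ternary")
        mpts = search_mpt(m)
        assert mpts.length == 2
        assert len(mpts.trees) == 1

    def test_duplicating_a_taxon_keeps_min_length(self, rng, quartet_matrix):
        base = search_mpt(quartet_matrix).length
        dup = quartet_matrix.with_taxon("A2", quartet_matrix.row("A"))
        assert search_mpt(dup).length == base

    def test_min_length_monotone_in_characters(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        states = rng.integers(0, 2, size=(5, 10))
        prev = 0
        for c in range(1, 11):
            m = CharacterMatrix(taxa, [f"c{j}" for j in range(c)], states[:, :c])
            cur = search_mpt(m).length
            assert cur >= prev
            prev = cur


class TestEdgeChanges:
    def test_constant_matrix_all_edges_zero(self):
        m = CharacterMatrix(list("ABCD"), ["c"], np.ones((4, 1), int))
        tree = assign_edge_changes(next(enumerate_topologies(list("ABCD"))), m)
        assert all(v == 0 for v in tree.edge_changes.values())

    def test_two_taxon_ordered_distance(self):
        m = CharacterMatrix(["A", "B"], ["c"], np.array([[0], [2]]),
                            "ordered-ternary")
        tree = assign_edge_changes(next(enumerate_topologies(["A", "B"])), m)
        assert tree.length == 2

    def test_edge_changes_sum_to_wagner_length(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 8))
            c = int(rng.integers(1, 10))
            taxa = [f"t{i}" for i in range(n)]
            m = CharacterMatrix(taxa, [f"c{j}" for j in range(c)],
                                rng.integers(0, 3, size=(n, c)), "ordered-ternary")
            tree = _tree_from_edges(random_topology(rng, n), taxa)
            scored = assign_edge_changes(tree, m)
            assert scored.length == wagner_length(tree, m)


class TestConsensus:
    def test_single_tree_identity(self, quartet_matrix):
        tree = search_mpt(quartet_matrix).trees[0]
        assert strict_consensus([tree]).bipartitions() == tree.bipartitions()

    def test_all_quartets_give_star(self):
        trees = list(enumerate_topologies(list("ABCD")))
        assert strict_consensus(trees).bipartitions() == frozenset()

    def test_two_of_three_quartets_give_star(self):
        trees = list(enumerate_topologies(list("ABCD")))[:2]
        assert strict_consensus(trees).bipartitions() == frozenset()

    def test_shared_clade_is_retained(self):
        labels = list("ABCDE")
        trees = [t for t in enumerate_topologies(labels)
                 if frozenset("DE") in t.bipartitions()]
        cons = strict_consensus(trees)
        assert cons.bipartitions() == frozenset({frozenset("DE")})

    def test_mismatched_leaf_sets_rejected(self):
        t1 = next(enumerate_topologies(list("ABCD")))
        t2 = next(enumerate_topologies(list("ABCX")))
        with pytest.raises(ValidationError, match="leaf"):
            strict_consensus([t1, t2])
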