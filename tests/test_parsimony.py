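"""Parsimony engine: scoring oracles, searches, indices, bootstrap."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paintphylo.characters import Character, CharacterMatrix
from paintphylo.parsimony import (
    bootstrap,
    fitch_length,
    indices,
    n_unrooted_topologies,
    per_character_steps,
    search_bnb,
    search_exhaustive,
    search_tbr,
)
from paintphylo.trees import Node, PhyloTree

from conftest import random_binary_matrix


# ---------------------------------------------------------------------------
# Independent topology enumeration (test oracle): nested-tuple trees grown by
# leaf insertion, converted to PhyloTree and scored via the public API only.
# ---------------------------------------------------------------------------

def tuple_trees(labels):
    if len(labels) == 3:
        return [tuple(labels)]
    out = []
    for t in tuple_trees(labels[:-1]):
        out.extend(_insert_everywhere(t, labels[-1]))
    return out


def _insert_everywhere(tree, leaf):
    results = []
    for i, sub in enumerate(tree):
        for replacement in _insert_into(sub, leaf):
            results.append(tree[:i] + (replacement,) + tree[i + 1 :])
    return results


def _insert_into(sub, leaf):
    yield (sub, leaf)  # insert on the edge above `sub`
    if isinstance(sub, tuple):
        for i, child in enumerate(sub):
            for replacement in _insert_into(child, leaf):
                yield sub[:i] + (replacement,) + sub[i + 1 :]


def tuple_to_phylo(t) -> PhyloTree:
    def build(x) -> Node:
        if isinstance(x, tuple):
            node = Node()
            for c in x:
                node.add(build(c))
            return node
        return Node(label=x)

    return PhyloTree(build(t), rooted=False)


def brute_force_optima(matrix):
    best, keep = None, []
    for t in tuple_trees(tuple(matrix.taxa)):
        tree = tuple_to_phylo(t)
        s = fitch_length(tree, matrix)
        if best is None or s < best:
            best, keep = s, [tree]
        elif s == best:
            keep.append(tree)
    return best, {t.bipartitions() for t in keep}


def test_tuple_enumeration_counts_are_correct():
    for n in (4, 5, 6, 7):
        trees = tuple_trees(tuple(f"t{i}" for i in range(n)))
        keys = {tuple_to_phylo(t).bipartitions() for t in trees}
        assert len(trees) == len(keys) == n_unrooted_topologies(n)


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------

class TestFitch:
    def test_matches_dendropy_on_random_inputs(self, rng, tmp_path):
        from dendropy.model.parsimony import fitch_down_pass
        from paintphylo.characters import write_nexus

        for trial in range(15):
            n, C = int(rng.integers(4, 9)), int(rng.integers(5, 30))
            m = random_binary_matrix(rng, n, C, missing=0.15)
            p = tmp_path / f"m{trial}.nex"
            write_nexus(m, p, missing_symbol="?")
            dm = dendropy.StandardCharacterMatrix.get(path=p, schema="nexus")
            tree = dendropy.simulate.treesim.uniform_pure_birth_tree(
                taxon_namespace=dm.taxon_namespace
            )
            expected = fitch_down_pass(
                tree.postorder_node_iter(),
                taxon_state_sets_map=dm.taxon_state_sets_map(gaps_as_missing=True),
            )
            mine = fitch_length(
                PhyloTree.from_newick(tree.as_string(schema="newick")), m
            )
            assert mine == expected

    def test_constant_character_contributes_zero(self):
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [Character("c1", "association"), Character("c2", "association")],
            np.array([[1, 1], [1, 0], [1, 1], [1, 0]], dtype=np.int8),
        )
        t = PhyloTree.from_newick("((A,B),(C,D));")
        assert list(per_character_steps(t, m)) == [0, 2]

    def test_invariant_under_leaf_permutation_and_rerooting(self, rng):
        from paintphylo.trees import root_on

        m = random_binary_matrix(rng, 6, 15, missing=0.1)
        t = PhyloTree.from_newick("((t0,(t1,t2)),(t3,(t4,t5)));")
        base = fitch_length(t, m)
        perm = list(rng.permutation(6))
        m2 = m.subset_taxa([f"t{i}" for i in perm])
        assert fitch_length(t, m2) == base
        for og in m.taxa:
            assert fitch_length(root_on(t, og), m) == base

    def test_missing_data_leaf_is_free(self):
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [Character("c", "association")],
            np.array([[1], [-1], [0], [0]], dtype=np.int8),
        )
        t = PhyloTree.from_newick("((A,B),(C,D));")
        assert fitch_length(t, m) == 1


# ---------------------------------------------------------------------------
# Searches
# ---------------------------------------------------------------------------

class TestSearches:
    def test_bnb_equals_brute_force_lengths_and_tree_sets(self, rng):
        for _ in range(8):
            n = int(rng.integers(5, 8))
            m = random_binary_matrix(rng, n, int(rng.integers(6, 16)), missing=0.1)
            best, keys = brute_force_optima(m)
            res = search_bnb(m)
            assert res.best_length == best
            assert {t.bipartitions() for t in res.optimal_trees} == keys

    def test_four_taxa_single_informative_character(self):
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [Character("c", "association")],
            np.array([[1], [1], [0], [0]], dtype=np.int8),
        )
        res = search_bnb(m)
        assert res.best_length == 1
        assert res.n_trees == 1
        expected = PhyloTree.from_newick("((A,B),(C,D));")
        assert res.optimal_trees[0] == expected

    def test_bnb_refuses_oversized_problems(self, rng):
        m = random_binary_matrix(rng, 18, 5)
        with pytest.raises(ValueError, match="search_tbr"):
            search_bnb(m)

    def test_tbr_finds_exact_optimum(self, rng):
        hits = 0
        trials = 25
        for seed in range(trials):
            m = random_binary_matrix(rng, int(rng.integers(6, 9)), 15)
            exact = search_bnb(m, keep_trees=False).best_length
            heur = search_tbr(m, n_starts=3, seed=seed, max_plateau=1).best_length
            hits += heur == exact
        assert hits >= trials - 1  # >=96% of seeded runs reach the optimum

    def test_tbr_recovers_homoplasy_free_signal(self):
        # characters exactly mirroring one topology: CI = 1, tree recovered
        taxa = [f"t{i}" for i in range(8)]
        truth = PhyloTree.from_newick("((t0,(t1,t2)),((t3,t4),(t5,(t6,t7))));")
        cols = []
        for clade in truth.bipartitions():
            cols.append([1 if t in clade else 0 for t in taxa])
        m = CharacterMatrix(
            taxa,
            [Character(f"c{j}", "association") for j in range(len(cols))],
            np.array(cols, dtype=np.int8).T,
        )
        res = search_tbr(m, n_starts=5, seed=0)
        assert res.ci == 1.0 and res.hi == 0.0
        assert truth.bipartitions() in {t.bipartitions() for t in res.optimal_trees}

    def test_search_deterministic_given_seed(self, rng):
        m = random_binary_matrix(rng, 9, 20)
        a = search_tbr(m, n_starts=4, seed=7)
        b = search_tbr(m, n_starts=4, seed=7)
        assert a.best_length == b.best_length
        assert [t.to_newick() for t in a.optimal_trees] == [
            t.to_newick() for t in b.optimal_trees
        ]


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------

class TestIndices:
    def test_hand_computed_five_taxon_case(self):
        # tree ((A,B),(C,D),E); char1 groups AB (s=1,m=1,g=2), char2 groups
        # AC (s=2,m=1,g=2), char3 constant (0,0,0):
        # CI = 2/3, RI = (4-3)/(4-2) = 1/2, HI = 1/3
        m = CharacterMatrix(
            ["A", "B", "C", "D", "E"],
            [Character(f"c{j}", "association") for j in range(3)],
            np.array(
                [[1, 1, 0], [1, 0, 0], [0, 1, 0], [0, 0, 0], [0, 0, 0]],
                dtype=np.int8,
            ),
        )
        t = PhyloTree.from_newick("((A,B),(C,D),E);")
        ci, ri, hi, steps = indices(t, m)
        assert list(steps) == [1, 2, 0]
        assert ci == pytest.approx(2 / 3)
        assert ri == pytest.approx(0.5)
        assert hi == pytest.approx(1 / 3)

    def test_ri_undefined_without_potential_synapomorphy(self):
        # every variable character autapomorphic: sum(g) == sum(m)
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [Character(f"c{j}", "association") for j in range(2)],
            np.array([[1, 0], [0, 1], [0, 0], [0, 0]], dtype=np.int8),
        )
        res = search_bnb(m)
        assert res.ri is None
        assert res.ci == 1.0

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_index_identities_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = random_binary_matrix(rng, int(rng.integers(4, 8)), int(rng.integers(4, 12)))
        res = search_exhaustive(m)
        if res.ci is not None:
            assert 0 < res.ci <= 1
            assert abs(res.hi + res.ci - 1) < 1e-12
        if res.ri is not None:
            assert 0 <= res.ri <= 1
        assert res.best_length == int(res.per_character_steps.sum())


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_congruent_characters_give_full_support(self, rng):
        # ten identical characters supporting one clade, nothing conflicting
        taxa = ["A", "B", "C", "D", "E"]
        states = np.array(
            [[1] * 10, [1] * 10, [0] * 10, [0] * 10, [0] * 10], dtype=np.int8
        )
        m = CharacterMatrix(
            taxa, [Character(f"c{j}", "association") for j in range(10)], states
        )
        cons, support = bootstrap(m, replicates=100, seed=0)
        assert support[frozenset({"D", "E", "C"})] == pytest.approx(100.0)

    def test_deterministic_under_seed(self, rng):
        m = random_binary_matrix(rng, 6, 12)
        c1, s1 = bootstrap(m, replicates=50, seed=123)
        c2, s2 = bootstrap(m, replicates=50, seed=123)
        assert s1 == s2
        assert c1.to_newick(include_support=True) == c2.to_newick(include_support=True)

    def test_supports_bounded_and_consensus_majority(self, rng):
        m = random_binary_matrix(rng, 6, 10)
        cons, support = bootstrap(m, replicates=60, seed=5)
        assert all(0.0 <= v <= 100.0 for v in support.values())
        kept = {b for b in cons.bipartitions()}
        for b in kept:
            assert support[b] > 50.0
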