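"""Ancestral states and branch signatures against exhaustive labelings."""

import itertools

import numpy as np
import pytest

from paintphylo.ancestral import ancestral_states, branch_signatures
from paintphylo.characters import Character, CharacterMatrix
from paintphylo.parsimony import fitch_length
from paintphylo.trees import PhyloTree, root_on

from conftest import random_binary_matrix


def exhaustive_mpr_sets(tree: PhyloTree, matrix: CharacterMatrix):
    """Oracle: per node and character, states used by some minimum labeling,
    found by trying every 0/1 assignment of the internal nodes."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    leaves = {n.label: n for n in nodes if n.is_leaf}
    sets = {id(n): {c: set() for c in range(matrix.n_characters)} for n in nodes}
    minima = []
    for c in range(matrix.n_characters):
        best, best_assignments = None, []
        leaf_state = {
            lab: matrix.states[matrix.taxa.index(lab), c] for lab in leaves
        }
        for assign in itertools.product((0, 1), repeat=len(internal)):
            node_state = {id(n): s for n, s in zip(internal, assign)}
            cost = 0
            ok_all = True
            for n in nodes:
                if n.is_leaf:
                    s = leaf_state[n.label]
                    node_state[id(n)] = s
            for n in nodes:
                for child in n.children:
                    a, b = node_state[id(n)], node_state[id(child)]
                    if a == -1 or b == -1:
                        continue
                    if a != b:
                        cost += 1
            # missing leaves: choose the cheaper of the two states
            # (handled by counting only non-missing comparisons above, which
            # equals assigning the parent's state to the missing leaf)
            if best is None or cost < best:
                best, best_assignments = cost, [dict(node_state)]
            elif cost == best:
                best_assignments.append(dict(node_state))
        minima.append(best)
        for a in best_assignments:
            for n in internal:
                sets[id(n)][c].add(a[id(n)])
    return minima, sets, internal


class TestAncestralStates:
    def test_uniform_character_has_no_changes(self):
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [Character("c", "association")],
            np.ones((4, 1), dtype=np.int8),
        )
        t = root_on(PhyloTree.from_newick("((A,B),(C,D));"), "A")
        rec = ancestral_states(t, m)
        assert all(s == 2 for s in rec.state_sets[:, 0])  # state {1} everywhere
        assert rec.char_length[0] == 0

    def test_matches_exhaustive_labeling_oracle(self, rng):
        t = root_on(PhyloTree.from_newick("((A,B),(C,(D,E)));"), "A")
        for _ in range(6):
            m = random_binary_matrix(rng, 5, 8)
            m.taxa = ["A", "B", "C", "D", "E"]
            minima, oracle_sets, internal = exhaustive_mpr_sets(t, m)
            rec = ancestral_states(t, m)
            assert list(rec.char_length) == minima
            nodes = list(t.postorder())
            for n in internal:
                i = next(j for j, x in enumerate(nodes) if x is n)
                for c in range(m.n_characters):
                    mine = {s for s in (0, 1) if rec.state_sets[i, c] >> s & 1}
                    assert mine == oracle_sets[id(n)][c]

    def test_requires_rooted_tree(self, rng):
        m = random_binary_matrix(rng, 4, 3)
        t = PhyloTree.from_newick("((t0,t1),(t2,t3));")
        with pytest.raises(ValueError, match="rooted"):
            ancestral_states(t, m)


class TestBranchSignatures:
    def test_autapomorphy_lands_on_terminal_branch(self):
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [Character("c", "association")],
            np.array([[0], [0], [1], [0]], dtype=np.int8),
        )
        t = root_on(PhyloTree.from_newick("((A,B),(C,D));"), "A")
        (sig,) = branch_signatures(t, m)
        assert sig.clade == frozenset({"C"})
        assert sig.changes[0].direction == "gain"
        assert not sig.changes[0].ambiguous

    @pytest.mark.parametrize("mode", ["acctran", "deltran", "ambiguous"])
    def test_total_changes_equal_tree_length(self, mode, rng):
        for _ in range(5):
            m = random_binary_matrix(rng, 6, 12, missing=0.1)
            t = root_on(
                PhyloTree.from_newick("((t0,(t1,t2)),(t3,(t4,t5)));"), "t0"
            )
            sigs = branch_signatures(t, m, resolution=mode)
            assert sum(len(s.changes) for s in sigs) == fitch_length(t, m)

    def test_acctran_deltran_move_but_preserve_count(self):
        # one character with an ambiguous placement: gain on the stem of
        # (C,D) vs parallel gains; both modes place the same number
        m = CharacterMatrix(
            ["A", "B", "C", "D", "E"],
            [Character("c", "association")],
            np.array([[0], [0], [1], [1], [1]], dtype=np.int8),
        )
        t = root_on(PhyloTree.from_newick("((A,B),((C,D),E));"), "A")
        acc = branch_signatures(t, m, "acctran")
        dele = branch_signatures(t, m, "deltran")
        assert sum(len(s.changes) for s in acc) == sum(len(s.changes) for s in dele)

    def test_ambiguous_mode_reports_alternatives(self):
        # gain of a character present in two non-sister tips: the single
        # change has two equally parsimonious placements
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [Character("c", "association")],
            np.array([[0], [1], [1], [0]], dtype=np.int8),
        )
        t = root_on(PhyloTree.from_newick("((A,B),(C,D));"), "A")
        sigs = branch_signatures(t, m, "ambiguous")
        changes = [ch for s in sigs for ch in s.changes]
        assert len(changes) == 2  # B and C change independently (length 2)

    def test_shared_derived_character_marks_the_stem_branch(self):
        # a character shared by a clade maps to that clade's stem branch
        m = CharacterMatrix(
            ["OUT", "A", "B", "C"],
            [Character("7q/10", "association")],
            np.array([[0], [1], [1], [1]], dtype=np.int8),
        )
        t = root_on(PhyloTree.from_newick("((OUT,A),(B,C));"), "OUT")
        sigs = branch_signatures(t, m)
        placed = {s.clade for s in sigs}
        assert frozenset({"A", "B", "C"}) in placed
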