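"""Ancestral character states and per-branch rearrangement signatures.

Given a tree rooted on the outgroup and a binary matrix, reconstruct
most-parsimonious ancestral states (Fitch down-pass plus outside/"up" costs,
i.e. Sankoff with unit costs) and place each character's state changes on
branches.  A change placed on a branch is that clade's *chromosome
signature*: the rearrangement(s) shared by exactly its members.

Optimisation-rule handling: ACCTRAN and DELTRAN pick a concrete
most-parsimonious labeling (changes accelerated toward the root, or delayed
toward the tips); the default ``ambiguous`` mode reports the DELTRAN
placement but flags every change whose position differs between
most-parsimonious reconstructions and lists the alternative branches.  In
every mode the number of change records equals the tree's Fitch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

from .characters import MISSING, Character, CharacterMatrix
from .trees import Node, PhyloTree

__all__ = [
    "AncestralReconstruction",
    "Change",
    "BranchSignature",
    "ancestral_states",
    "branch_signatures",
    "signatures_to_tsv",
    "annotated_newick",
]

INF = 10**9


def _indexed(tree: PhyloTree):
    """Postorder node list, children indices, parent indices, leaf rows."""
    nodes = list(tree.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    children = [[idx[id(c)] for c in n.children] for n in nodes]
    parent = [None] * len(nodes)
    for i, n in enumerate(nodes):
        for c in children[i]:
            parent[c] = i
    return nodes, idx, children, parent


@dataclass
class AncestralReconstruction:
    """Per-node most-parsimonious state sets for every character."""

    tree: PhyloTree
    matrix: CharacterMatrix
    # state_sets[i][c] is a bitmask over {0->1, 1->2} of states node i takes
    # in at least one most-parsimonious reconstruction of character c
    state_sets: np.ndarray
    clades: list[frozenset[str]]
    char_length: np.ndarray  # per-character minimum steps

    def ambiguous_nodes(self) -> np.ndarray:
        """Boolean (node x character): node state not unique across MPRs."""
        return self.state_sets == 3

    def node_state(self, clade: frozenset[str], label: str) -> set[int]:
        i = self.clades.index(clade)
        c = self.matrix.labels().index(label)
        m = int(self.state_sets[i, c])
        return {s for s in (0, 1) if m >> s & 1}


def _leaf_costs(matrix: CharacterMatrix, label: str, c: int) -> list[int]:
    v = matrix.states[matrix.taxa.index(label), c]
    if v == MISSING:
        return [0, 0]
    return [0 if v == 0 else INF, 0 if v == 1 else INF]


def _dp(tree: PhyloTree, matrix: CharacterMatrix):
    """Down-pass costs, outside costs, and per-character totals."""
    nodes, idx, children, parent = _indexed(tree)
    N, C = len(nodes), matrix.n_characters
    cost = np.zeros((N, C, 2), dtype=np.int64)  # min steps of subtree, node=state
    for i, n in enumerate(nodes):
        if n.is_leaf:
            if C:
                cost[i, :, :] = [_leaf_costs(matrix, n.label, c) for c in range(C)]
        else:
            for s in (0, 1):
                tot = np.zeros(C, dtype=np.int64)
                for ch in children[i]:
                    tot += np.minimum(cost[ch, :, s], cost[ch, :, 1 - s] + 1)
                cost[i, :, s] = tot
    root = N - 1  # postorder: root last
    total = cost[root].min(axis=1)
    # outside[i, c, t]: min cost of the whole tree minus subtree(i), with the
    # parent of i fixed to state t (includes the parent's own subtrees other
    # than i, and everything above)
    outside = np.zeros((N, C, 2), dtype=np.int64)
    order = [root]
    stack = [root]
    while stack:
        i = stack.pop()
        for ch in children[i]:
            order.append(ch)
            stack.append(ch)
    for i in order:
        if i == root:
            continue
        p = parent[i]
        for t in (0, 1):
            sib = np.zeros(C, dtype=np.int64)
            for ch in children[p]:
                if ch != i:
                    sib += np.minimum(cost[ch, :, t], cost[ch, :, 1 - t] + 1)
            if p == root:
                above = np.zeros(C, dtype=np.int64)
            else:
                above = np.minimum(
                    outside[p, :, t], outside[p, :, 1 - t] + 1
                )
            outside[i, :, t] = sib + above
    return nodes, idx, children, parent, cost, outside, total


def ancestral_states(
    tree: PhyloTree, matrix: CharacterMatrix
) -> AncestralReconstruction:
    """Most-parsimonious state sets at every node of a rooted tree.

    A node's set contains a state when some most-parsimonious reconstruction
    assigns it; two-state sets mark ambiguous nodes.  Requires a rooted tree
    (root on the outgroup first).
    """
    if not tree.rooted:
        raise ValueError("ancestral_states requires a rooted tree (use root_on)")
    _check(tree, matrix)
    nodes, idx, children, parent, cost, outside, total = _dp(tree, matrix)
    N, C = len(nodes), matrix.n_characters
    root = N - 1
    sets = np.zeros((N, C), dtype=np.int8)
    for i in range(N):
        for s in (0, 1):
            if i == root:
                ok = cost[root, :, s] == total
            else:
                # best completion with node i = s
                t_costs = np.minimum(
                    outside[i, :, 0] + (1 if s != 0 else 0),
                    outside[i, :, 1] + (1 if s != 1 else 0),
                )
                ok = cost[i, :, s] + t_costs == total
            sets[i, :] |= (ok.astype(np.int8)) << s
    leafsets = _clades(nodes, children)
    return AncestralReconstruction(tree, matrix, sets, leafsets, total)


def _clades(nodes, children) -> list[frozenset[str]]:
    out: list[frozenset[str]] = [frozenset()] * len(nodes)
    for i, n in enumerate(nodes):
        if n.is_leaf:
            out[i] = frozenset([n.label])
        else:
            out[i] = frozenset().union(*(out[c] for c in children[i]))
    return out


def _check(tree: PhyloTree, matrix: CharacterMatrix) -> None:
    tl, ml = tree.leaf_labels(), frozenset(matrix.taxa)
    if tl != ml:
        raise ValueError(
            f"tree/matrix mismatch: matrix-only={sorted(ml - tl)}, tree-only={sorted(tl - ml)}"
        )


@dataclass(frozen=True)
class Change:
    character: Character
    direction: Literal["gain", "loss"]
    ambiguous: bool = False
    alt_clades: tuple[frozenset[str], ...] = ()


@dataclass
class BranchSignature:
    """All character changes assigned to the branch above one node."""

    clade: frozenset[str]
    changes: list[Change] = field(default_factory=list)


def _concrete_labeling(
    nodes, children, parent, cost, outside, total, matrix, mode: str, outgroup_row: np.ndarray
) -> np.ndarray:
    """One most-parsimonious 0/1 labeling per (node, character)."""
    N, C = cost.shape[0], cost.shape[1]
    root = N - 1
    label = np.zeros((N, C), dtype=np.int8)
    order = [root]
    stack = [root]
    while stack:
        i = stack.pop()
        for ch in children[i]:
            order.append(ch)
            stack.append(ch)
    for c in range(C):
        # root: prefer the outgroup's observed state among optima (polarity)
        opts = [s for s in (0, 1) if cost[root, c, s] == total[c]]
        if len(opts) == 1:
            label[root, c] = opts[0]
        else:
            og = outgroup_row[c]
            label[root, c] = og if og in (0, 1) else 0
        for i in order[1:]:
            t = label[parent[i], c]
            cands = [
                s
                for s in (0, 1)
                if cost[i, c, s] + (1 if s != t else 0)
                == min(cost[i, c, 0] + (1 if t != 0 else 0), cost[i, c, 1] + (1 if t != 1 else 0))
            ]
            if len(cands) == 1:
                label[i, c] = cands[0]
            elif mode == "acctran":
                label[i, c] = 1 - t  # accelerate: change as close to the root as possible
            else:
                label[i, c] = t  # delay: keep the parent's state
    return label


def branch_signatures(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    resolution: Literal["acctran", "deltran", "ambiguous"] = "ambiguous",
) -> list[BranchSignature]:
    """Character changes per branch of a rooted tree.

    ``acctran``/``deltran`` report the corresponding concrete labeling.
    ``ambiguous`` (default) reports the DELTRAN placement and flags changes
    whose branch differs between most-parsimonious reconstructions, listing
    the alternative branches by clade.  In every mode the total number of
    change records equals the tree's Fitch length.
    """
    if not tree.rooted:
        raise ValueError("branch_signatures requires a rooted tree")
    _check(tree, matrix)
    nodes, idx, children, parent, cost, outside, total = _dp(tree, matrix)
    N, C = cost.shape[0], cost.shape[1]
    root = N - 1
    clades = _clades(nodes, children)
    # outgroup = leaf child of the root (rooting convention)
    og_leaf = next(
        (i for i in children[root] if nodes[i].is_leaf), children[root][0]
    )
    outgroup_row = matrix.states[matrix.taxa.index(nodes[og_leaf].label)] if nodes[og_leaf].is_leaf else np.full(C, MISSING)
    mode = "acctran" if resolution == "acctran" else "deltran"
    lab = _concrete_labeling(
        nodes, children, parent, cost, outside, total, matrix, mode, outgroup_row
    )
    # edges where a change occurs in some / in all MPRs, per character
    some = np.zeros((N, C), dtype=bool)
    all_ = np.zeros((N, C), dtype=bool)
    for i in range(N):
        if i == root:
            continue
        for c in range(C):
            with_change = INF
            without = INF
            for t in (0, 1):
                above = outside[i, c, t]
                for s in (0, 1):
                    v = above + cost[i, c, s] + (1 if s != t else 0)
                    if s != t:
                        with_change = min(with_change, v)
                    else:
                        without = min(without, v)
            some[i, c] = with_change == total[c]
            all_[i, c] = without > total[c]
    sigs: dict[int, BranchSignature] = {}
    for i in range(N):
        if i == root:
            continue
        p = parent[i]
        for c in range(C):
            if lab[i, c] != lab[p, c]:
                direction = "gain" if lab[i, c] == 1 else "loss"
                ambiguous = bool(some[i, c] and not all_[i, c])
                alts: tuple[frozenset[str], ...] = ()
                if resolution == "ambiguous" and ambiguous:
                    alts = tuple(
                        clades[j]
                        for j in range(N)
                        if j != i and j != root and some[j, c]
                    )
                sigs.setdefault(i, BranchSignature(clade=clades[i])).changes.append(
                    Change(matrix.characters[c], direction, ambiguous, alts)
                )
    return [sigs[i] for i in sorted(sigs, key=lambda j: (-len(clades[j]), sorted(clades[j])))]


def signatures_to_tsv(signatures: Sequence[BranchSignature], path: str | Path) -> None:
    """Per-branch report: clade, change count, and each change."""
    lines = ["clade\tn_changes\tcharacter\tkind\tdirection\tambiguous\talternatives"]
    for sig in signatures:
        clade = "+".join(sorted(sig.clade))
        for ch in sig.changes:
            alts = ";".join("+".join(sorted(a)) for a in ch.alt_clades)
            lines.append(
                f"{clade}\t{len(sig.changes)}\t{ch.character.label}\t{ch.character.kind}"
                f"\t{ch.direction}\t{int(ch.ambiguous)}\t{alts}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def annotated_newick(tree: PhyloTree, signatures: Sequence[BranchSignature]) -> str:
    """Newick with NHX-style comments listing each branch's changes."""
    by_clade = {sig.clade: sig for sig in signatures}
    sets: dict[int, frozenset[str]] = {}
    for n in tree.postorder():
        if n.is_leaf:
            sets[id(n)] = frozenset([n.label])
        else:
            sets[id(n)] = frozenset().union(*(sets[id(c)] for c in n.children))

    def fmt(n: Node) -> str:
        s = (
            n.label
            if n.is_leaf
            else "(" + ",".join(fmt(c) for c in n.children) + ")"
        )
        sig = by_clade.get(sets[id(n)])
        if sig and sig.changes:
            body = ":".join(
                f"{'+' if ch.direction == 'gain' else '-'}{ch.character.label}"
                for ch in sig.changes
            )
            s += f"[&&NHX:changes={body}]"
        return s

    return fmt(tree.root) + ";"
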