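"""Labelled phylogenetic trees: Newick I/O, bipartitions, consensus, rooting.

The tree class is deliberately small: leaves carry species codes, internal
nodes may carry bootstrap support, and comparisons go through canonical
bipartition sets so that two trees are equal exactly when they encode the
same unrooted topology.  Newick parsing is delegated to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import dendropy

__all__ = ["Node", "PhyloTree", "consensus", "rf_distance", "root_on"]


@dataclass(eq=False)  # identity semantics: parent/child links are cyclic
class Node:
    label: str | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    length: float | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class PhyloTree:
    """A rooted or unrooted labelled tree.

    Unrooted trees are stored with an arbitrary basal multifurcation; all
    topology comparisons use unrooted bipartitions unless the tree is rooted.
    """

    def __init__(self, root: Node, rooted: bool = False) -> None:
        self.root = root
        self.rooted = rooted

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = False) -> "PhyloTree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )

        def convert(dnode) -> Node:
            node = Node(
                label=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length,
            )
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        return cls(convert(dt.seed_node), rooted=rooted)

    def copy(self) -> "PhyloTree":
        def dup(n: Node) -> Node:
            m = Node(label=n.label, length=n.length, support=n.support)
            for c in n.children:
                m.add(dup(c))
            return m

        return PhyloTree(dup(self.root), rooted=self.rooted)

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    # -- topology -----------------------------------------------------------

    def _leafsets(self) -> dict[int, frozenset[str]]:
        sets: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                sets[id(n)] = frozenset([n.label])
            else:
                sets[id(n)] = frozenset().union(*(sets[id(c)] for c in n.children))
        return sets

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Canonical nontrivial unrooted bipartitions.

        Each split is represented by the side *not* containing the
        lexicographically smallest leaf label, so representations agree
        across trees on the same leaf set.
        """
        all_leaves = self.leaf_labels()
        ref = min(all_leaves)
        sets = self._leafsets()
        out = set()
        for n in self.postorder():
            if n is self.root:
                continue
            side = sets[id(n)]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return frozenset(out)

    def clades(self) -> frozenset[frozenset[str]]:
        """Leaf sets of internal nodes (rooted view, excludes root and leaves)."""
        sets = self._leafsets()
        return frozenset(
            sets[id(n)]
            for n in self.postorder()
            if not n.is_leaf and n is not self.root
        )

    def topology_key(self) -> frozenset[frozenset[str]]:
        return self.bipartitions()

    def is_binary_unrooted(self) -> bool:
        for n in self.postorder():
            if n.is_leaf:
                continue
            k = len(n.children)
            if n is self.root:
                if k != 3 and not (self.rooted and k == 2):
                    return False
            elif k != 2:
                return False
        return True

    # -- output -------------------------------------------------------------

    def to_newick(
        self, include_support: bool = False, include_lengths: bool = False
    ) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = n.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if include_support and n.support is not None:
                    s += f"{n.support:g}"
            if include_lengths and n.length is not None:
                s += f":{n.length:g}"
            return s

        return fmt(self.root) + ";"

    def to_dendropy(
        self, taxon_namespace: dendropy.TaxonNamespace | None = None
    ) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(include_lengths=True),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PhyloTree)
            and self.leaf_labels() == other.leaf_labels()
            and self.bipartitions() == other.bipartitions()
        )

    def __hash__(self) -> int:
        return hash((self.leaf_labels(), self.bipartitions()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.to_newick()!r}, rooted={self.rooted})"


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    """Unrooted Robinson–Foulds distance (symmetric bipartition difference)."""
    if a.leaf_labels() != b.leaf_labels():
        raise ValueError("trees are on different leaf sets")
    return len(a.bipartitions() ^ b.bipartitions())


def root_on(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root on the pendant edge of ``outgroup`` (outgroup sister to the rest)."""
    if outgroup not in tree.leaf_labels():
        raise ValueError(f"outgroup {outgroup!r} not among leaves")
    # build adjacency, then re-hang from a new root on the outgroup edge
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    nodes: dict[int, Node] = {}

    def walk(n: Node) -> None:
        nodes[id(n)] = n
        if n.is_leaf:
            labels[id(n)] = n.label
        for c in n.children:
            adj.setdefault(id(n), []).append(id(c))
            adj.setdefault(id(c), []).append(id(n))
            walk(c)

    walk(tree.root)
    og = next(i for i, lab in labels.items() if lab == outgroup)
    attach = adj[og][0]

    def build(i: int, avoid: int) -> Node:
        node = Node(label=labels.get(i))
        kids = [j for j in adj.get(i, []) if j != avoid]
        for j in kids:
            node.add(build(j, i))
        if len(node.children) == 1 and node.label is None:
            # suppress the degree-2 node left by removing the old root
            return node.children[0]
        return node

    root = Node()
    root.add(Node(label=outgroup))
    root.add(build(attach, og))
    return PhyloTree(root, rooted=True)


def tree_from_clades(
    leafset: Iterable[str], clades: dict[frozenset[str], float | None]
) -> PhyloTree:
    """Build a (possibly multifurcating) rooted tree from a laminar clade family.

    ``clades`` maps each clade's leaf set to an optional support value.
    """
    leafset = frozenset(leafset)
    for c in clades:
        if not c <= leafset or len(c) < 2:
            raise ValueError(f"bad clade {sorted(c)}")
    ordered = sorted(clades, key=len, reverse=True)
    root = Node()
    node_of: dict[frozenset[str], Node] = {leafset: root}
    covers: dict[frozenset[str], frozenset[str]] = {leafset: leafset}

    def parent_of(c: frozenset[str]) -> frozenset[str]:
        best = leafset
        for other in ordered:
            if other is not c and c < other and len(other) < len(best):
                best = other
        return best

    for c in ordered:
        if len(c) == len(leafset):
            root.support = clades[c]
            continue
        p = parent_of(c)
        pnode = node_of.get(p, root if p == leafset else None)
        if pnode is None:
            raise ValueError("incompatible clade family")
        n = Node(support=clades[c])
        pnode.add(n)
        node_of[c] = n
    # attach leaves to the smallest containing clade
    for leaf in sorted(leafset):
        best, best_node = leafset, root
        for c, n in node_of.items():
            if leaf in c and len(c) < len(best):
                best, best_node = c, n
        best_node.add(Node(label=leaf))
    return PhyloTree(root, rooted=False)


def consensus(
    trees: Sequence[PhyloTree], rule: str = "strict", min_freq: float = 0.5
) -> PhyloTree:
    """Strict or majority-rule consensus of unrooted trees on one leaf set.

    Majority rule keeps bipartitions with frequency > ``min_freq``; supports
    (as percentages) are attached to the corresponding nodes.
    """
    if not trees:
        raise ValueError("no trees to summarise")
    leafset = trees[0].leaf_labels()
    for t in trees[1:]:
        if t.leaf_labels() != leafset:
            raise ValueError("trees are on different leaf sets")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for b in t.bipartitions():
            counts[b] = counts.get(b, 0) + 1
    n = len(trees)
    if rule == "strict":
        kept = {b: 100.0 for b, c in counts.items() if c == n}
    elif rule == "majority":
        kept = {
            b: 100.0 * c / n for b, c in counts.items() if c / n > min_freq
        }
    else:
        raise ValueError(f"unknown consensus rule {rule!r}")
    return tree_from_clades(leafset, kept)
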