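"""Maximum parsimony on binary character matrices.

Fitch (unordered) parsimony with missing data treated as the full state set
at the leaf.  Characters are packed into two big-integer bitmasks per node —
bit *i* of ``A`` set when character *i*'s state set contains 0, bit *i* of
``B`` when it contains 1 — so one Fitch combine for all characters costs a
handful of bigint operations and the number of union events is a popcount.

Search strategies:

* exhaustive enumeration over all unrooted binary topologies (small n);
* branch and bound by stepwise taxon addition with a max–mini addition
  order, provably returning every minimum-length topology;
* heuristic hill-climbing with tree-bisection-reconnection (TBR) swapping
  from random-addition starting trees, with an optional equal-length plateau
  walk so ties at the optimum are collected.

Homoplasy statistics follow the classical definitions: CI = Σm/Σs,
RI = (Σg − Σs)/(Σg − Σm), HI = 1 − CI, where m is a character's minimum
conceivable steps (1 if variable, else 0), s its steps on the tree, and g its
maximum steps on the star tree (for a binary character, the smaller of its
two state counts over non-missing leaves).

Internal tree representation: adjacency dicts whose leaves are matrix taxon
indices 0..n-1 and whose internal nodes are ids >= n; partial trees simply
use a subset of the leaves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .characters import MISSING, CharacterMatrix
from .trees import Node, PhyloTree, tree_from_clades

__all__ = [
    "ParsimonyResult",
    "fitch_length",
    "per_character_steps",
    "enumerate_topologies",
    "n_unrooted_topologies",
    "search_exhaustive",
    "search_bnb",
    "search_tbr",
    "indices",
    "bootstrap",
]

Adj = dict[int, list[int]]


# ---------------------------------------------------------------------------
# Encoding and scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Encoded:
    taxa: tuple[str, ...]
    A: tuple[int, ...]  # per leaf: bitmask of characters whose set contains 0
    B: tuple[int, ...]
    full: int
    n: int  # leaf ids are 0..n-1; internal ids >= n


def _encode(matrix: CharacterMatrix) -> _Encoded:
    C = matrix.n_characters
    A, B = [], []
    for row in matrix.states:
        a = b = 0
        for j, v in enumerate(row):
            if v != 1:
                a |= 1 << j
            if v != 0:
                b |= 1 << j
        A.append(a)
        B.append(b)
    return _Encoded(tuple(matrix.taxa), tuple(A), tuple(B), (1 << C) - 1, matrix.n_taxa)


def _score(adj: Adj, enc: _Encoded, collect_unions: list[int] | None = None) -> int:
    """Fitch length of an unrooted (possibly partial) tree."""
    n, full, A, B = enc.n, enc.full, enc.A, enc.B
    root_leaf = min(k for k in adj if k < n)
    start = adj[root_leaf][0]
    if start < n:  # two-leaf tree
        empty = full & ~((A[root_leaf] & A[start]) | (B[root_leaf] & B[start]))
        if empty and collect_unions is not None:
            collect_unions.append(empty)
        return empty.bit_count()
    order: list[tuple[int, int]] = []
    stack = [(start, root_leaf)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        if node >= n:
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
    steps = 0
    setsA: dict[int, int] = {}
    setsB: dict[int, int] = {}
    for node, parent in reversed(order):
        if node < n:
            setsA[node], setsB[node] = A[node], B[node]
            continue
        kids = [nb for nb in adj[node] if nb != parent]
        a, b = setsA[kids[0]], setsB[kids[0]]
        for k in kids[1:]:
            ka, kb = setsA[k], setsB[k]
            ia, ib = a & ka, b & kb
            empty = full & ~(ia | ib)
            if empty:
                steps += empty.bit_count()
                if collect_unions is not None:
                    collect_unions.append(empty)
                a = ia | (empty & (a | ka))
                b = ib | (empty & (b | kb))
            else:
                a, b = ia, ib
        setsA[node], setsB[node] = a, b
    ia = setsA[start] & A[root_leaf]
    ib = setsB[start] & B[root_leaf]
    empty = full & ~(ia | ib)
    if empty:
        steps += empty.bit_count()
        if collect_unions is not None:
            collect_unions.append(empty)
    return steps


# ---------------------------------------------------------------------------
# Tree plumbing
# ---------------------------------------------------------------------------

def _check_leaves(tree: PhyloTree, matrix: CharacterMatrix) -> None:
    tl, ml = tree.leaf_labels(), frozenset(matrix.taxa)
    if tl != ml:
        raise ValueError(
            "tree/matrix leaf mismatch: "
            f"matrix-only={sorted(ml - tl)}, tree-only={sorted(tl - ml)}"
        )


def _adj_from_tree(tree: PhyloTree, taxa: Sequence[str]) -> Adj:
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    adj: Adj = {}
    next_internal = [n]
    ids: dict[int, int] = {}

    def get_id(node: Node) -> int:
        key = id(node)
        if key not in ids:
            if node.is_leaf:
                ids[key] = index[node.label]
            else:
                ids[key] = next_internal[0]
                next_internal[0] += 1
        return ids[key]

    def walk(node: Node) -> None:
        for c in node.children:
            a, b = get_id(node), get_id(c)
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
            walk(c)

    walk(tree.root)
    for v in [v for v, nbs in adj.items() if len(nbs) == 2 and v >= n]:
        a, b = adj[v]
        adj[a] = [x if x != v else b for x in adj[a]]
        adj[b] = [x if x != v else a for x in adj[b]]
        del adj[v]
    return adj


def _tree_from_adj(adj: Adj, taxa: Sequence[str]) -> PhyloTree:
    n = len(taxa)
    anchor = min(k for k in adj if k < n)
    start = adj[anchor][0]

    def build(i: int, parent: int) -> Node:
        if i < n:
            return Node(label=taxa[i])
        node = Node()
        for nb in adj[i]:
            if nb != parent:
                node.add(build(nb, i))
        return node

    root = build(start, anchor)
    root.add(Node(label=taxa[anchor]))
    return PhyloTree(root, rooted=False)


def _topology_key(adj: Adj, n: int) -> frozenset[int]:
    """Canonical key: leaf-index masks of the split sides not containing the
    smallest present leaf."""
    anchor = min(k for k in adj if k < n)
    start = adj[anchor][0]
    if start < n:
        return frozenset()
    order: list[tuple[int, int]] = []
    stack = [(start, anchor)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        if node >= n:
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
    n_leaves = sum(1 for k in adj if k < n)
    masks: dict[int, int] = {}
    out = set()
    for node, parent in reversed(order):
        if node < n:
            masks[node] = 1 << node
        else:
            m = 0
            for nb in adj[node]:
                if nb != parent:
                    m |= masks[nb]
            masks[node] = m
            if 2 <= m.bit_count() <= n_leaves - 2:
                out.add(m)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Public scoring
# ---------------------------------------------------------------------------

def fitch_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Minimum total unordered state changes of ``matrix`` on ``tree``."""
    _check_leaves(tree, matrix)
    if matrix.n_characters == 0:
        return 0
    return _score(_adj_from_tree(tree, matrix.taxa), _encode(matrix))


def per_character_steps(tree: PhyloTree, matrix: CharacterMatrix) -> np.ndarray:
    """Fitch steps of each character on ``tree``."""
    _check_leaves(tree, matrix)
    unions: list[int] = []
    _score(_adj_from_tree(tree, matrix.taxa), _encode(matrix), collect_unions=unions)
    steps = np.zeros(matrix.n_characters, dtype=int)
    for mask in unions:
        while mask:
            low = mask & -mask
            steps[low.bit_length() - 1] += 1
            mask ^= low
    return steps


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def _insert_leaf(edges: list[tuple[int, int]], i: int, leaf: int, new_node: int):
    u, v = edges[i]
    return edges[:i] + edges[i + 1 :] + [(u, new_node), (new_node, v), (new_node, leaf)]


def _edges_to_adj(edges: Iterable[tuple[int, int]]) -> Adj:
    adj: Adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def enumerate_topologies(
    n: int, leaf_order: Sequence[int] | None = None
) -> Iterator[Adj]:
    """All unrooted binary topologies on n leaves (ids 0..n-1)."""
    if n < 3:
        raise ValueError("need >= 3 leaves")
    order = list(leaf_order) if leaf_order is not None else list(range(n))

    def rec(edges: list[tuple[int, int]], k: int):
        if k == n:
            yield _edges_to_adj(edges)
            return
        for i in range(len(edges)):
            yield from rec(_insert_leaf(edges, i, order[k], n + k - 2), k + 1)

    yield from rec([(order[0], n), (order[1], n), (order[2], n)], 3)


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! distinct unrooted binary topologies on n labelled leaves."""
    out = 1
    for k in range(3, 2 * n - 5 + 1, 2):
        out *= k
    return out


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class ParsimonyResult:
    """Outcome of a parsimony search."""

    best_length: int
    optimal_trees: list[PhyloTree]
    ci: float | None = None
    ri: float | None = None
    hi: float | None = None
    per_character_steps: np.ndarray | None = None
    method: str = ""
    complete: bool = True  # whether the tree set is provably exhaustive

    @property
    def n_trees(self) -> int:
        return len(self.optimal_trees)


def _finish(
    matrix: CharacterMatrix,
    best: int,
    adjs: dict[frozenset[int], Adj],
    method: str,
    complete: bool,
) -> ParsimonyResult:
    trees = [_tree_from_adj(adj, matrix.taxa) for adj in adjs.values()]
    res = ParsimonyResult(
        best_length=best, optimal_trees=trees, method=method, complete=complete
    )
    if trees:
        res.ci, res.ri, res.hi, res.per_character_steps = indices(trees[0], matrix)
    return res


# ---------------------------------------------------------------------------
# Exact searches
# ---------------------------------------------------------------------------

def search_exhaustive(matrix: CharacterMatrix, max_taxa: int = 9) -> ParsimonyResult:
    """Score every topology; exact.  Refuses beyond ``max_taxa``."""
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if n > max_taxa:
        raise ValueError(f"{n} taxa: use search_bnb or search_tbr")
    enc = _encode(matrix)
    best: int | None = None
    keep: dict[frozenset[int], Adj] = {}
    for adj in enumerate_topologies(n):
        s = _score(adj, enc)
        if best is None or s < best:
            best, keep = s, {_topology_key(adj, n): adj}
        elif s == best:
            keep.setdefault(_topology_key(adj, n), adj)
    return _finish(matrix, best, keep, "exhaustive", True)


def _addition_order(matrix: CharacterMatrix, enc: _Encoded) -> list[int]:
    """Max–mini stepwise addition order for tight early bounds.

    Start from the most divergent pair, then greedily add the taxon whose
    *best* placement increases the partial tree length the most.
    """
    n = matrix.n_taxa
    if n <= 4:
        return list(range(n))
    states = matrix.states
    diff = np.zeros((n, n), dtype=int)
    for i in range(n):
        ok_i = states[i] != MISSING
        for j in range(i + 1, n):
            ok = ok_i & (states[j] != MISSING)
            diff[i, j] = diff[j, i] = int(np.sum((states[i] != states[j]) & ok))
    i0, j0 = map(int, np.unravel_index(np.argmax(diff), diff.shape))
    k0 = max(
        (k for k in range(n) if k not in (i0, j0)),
        key=lambda k: int(diff[i0, k] + diff[j0, k]),
    )
    chosen = [i0, j0, int(k0)]
    edges = [(i0, n), (j0, n), (k0, n)]
    remaining = [k for k in range(n) if k not in chosen]
    next_internal = n + 1
    while remaining:
        best_t, best_cost, best_edges = None, -1, None
        for t in remaining:
            placement, placed = None, None
            for i in range(len(edges)):
                trial = _insert_leaf(edges, i, t, next_internal)
                s = _score(_edges_to_adj(trial), enc)
                if placement is None or s < placement:
                    placement, placed = s, trial
            if placement > best_cost:
                best_t, best_cost, best_edges = t, placement, placed
        chosen.append(best_t)
        remaining.remove(best_t)
        edges = best_edges
        next_internal += 1
    return chosen


def search_bnb(
    matrix: CharacterMatrix,
    keep_trees: bool = True,
    max_taxa: int = 16,
    upper_bound: int | None = None,
    max_trees: int = 200_000,
) -> ParsimonyResult:
    """Branch and bound over stepwise addition; provably all optimal trees.

    Partial-tree length never decreases when a taxon is added, so a partial
    tree longer than the incumbent cannot lead to an optimum.  With
    ``keep_trees=False`` only the optimal length is guaranteed (equal-length
    partials are pruned too); the tree list is then empty.
    """
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceeds branch-and-bound limit {max_taxa}; use search_tbr"
        )
    if n <= 5:
        return search_exhaustive(matrix)
    enc = _encode(matrix)
    order = _addition_order(matrix, enc)
    best = upper_bound
    keep: list[list[tuple[int, int]]] = []
    overflow = False

    def rec(edges: list[tuple[int, int]], s_here: int, k: int) -> None:
        nonlocal best, keep, overflow
        if k == n:
            if best is None or s_here < best:
                best = s_here
                keep = [edges] if keep_trees else []
            elif s_here == best and keep_trees:
                if len(keep) >= max_trees:
                    overflow = True
                else:
                    keep.append(edges)
            return
        for i in range(len(edges)):
            trial = _insert_leaf(edges, i, order[k], n + k - 2)
            s = _score(_edges_to_adj(trial), enc)
            if best is not None and (s > best or (s == best and not keep_trees)):
                continue
            rec(trial, s, k + 1)

    e0 = [(order[0], n), (order[1], n), (order[2], n)]
    rec(e0, _score(_edges_to_adj(e0), enc), 3)
    if keep_trees and not keep and upper_bound is not None:
        # the supplied bound was below the optimum: rerun without it
        return search_bnb(matrix, keep_trees=True, max_taxa=max_taxa, max_trees=max_trees)
    adjs = {
        _topology_key(adj, n): adj
        for adj in (_edges_to_adj(e) for e in keep)
    }
    res = _finish(matrix, best, adjs, "branch-and-bound", keep_trees and not overflow)
    if not keep_trees:
        res.complete = False
    return res


# ---------------------------------------------------------------------------
# TBR heuristic
# ---------------------------------------------------------------------------

def _random_addition_tree(enc: _Encoded, rng: np.random.Generator) -> Adj:
    n = len(enc.taxa)
    order = [int(x) for x in rng.permutation(n)]
    edges = [(order[0], n), (order[1], n), (order[2], n)]
    for k in range(3, n):
        best_s, best_edges = None, None
        for i in range(len(edges)):
            trial = _insert_leaf(edges, i, order[k], n + k - 2)
            s = _score(_edges_to_adj(trial), enc)
            if best_s is None or s < best_s:
                best_s, best_edges = s, trial
        edges = best_edges
    return _edges_to_adj(edges)


def _split_components(adj: Adj, u: int, v: int) -> tuple[set[int], set[int]]:
    seen = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if x == u and y == v:
                continue
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return seen, set(adj) - seen


def _tbr_neighbors(adj: Adj, n: int) -> Iterator[Adj]:
    """All TBR rearrangements, visited in canonical sorted-edge order.

    Bisect every edge; on each side splice out the freed endpoint if it was
    internal; reconnect every edge of one side to every edge of the other
    (single-leaf sides attach directly).  Freed internal ids are reused as
    the reattachment nodes, so node ids stay within 0..2n-3.
    """
    all_edges = sorted((u, v) if u < v else (v, u) for u in adj for v in adj[u])
    all_edges = sorted(set(all_edges))
    for u, v in all_edges:
        comp_u, comp_v = _split_components(adj, u, v)

        def side(comp: set[int], endpoint: int) -> tuple[Adj, int | None]:
            """Component adjacency with the endpoint spliced; freed id or None."""
            sub = {x: [y for y in adj[x] if y in comp] for x in comp}
            sub[endpoint] = [y for y in sub[endpoint] if y != (v if endpoint == u else u)]
            if endpoint >= n and len(sub[endpoint]) == 2:
                a, b = sub[endpoint]
                sub[a] = [x if x != endpoint else b for x in sub[a]]
                sub[b] = [x if x != endpoint else a for x in sub[b]]
                del sub[endpoint]
                return sub, endpoint
            return sub, None

        sub1, free1 = side(comp_u, u)
        sub2, free2 = side(comp_v, v)
        frees = [f for f in (free1, free2) if f is not None]

        def attachments(sub: Adj) -> list[tuple[int, int] | int]:
            if len(sub) == 1:  # single leaf
                return [next(iter(sub))]
            return sorted(
                set((a, b) if a < b else (b, a) for a in sub for b in sub[a])
            )

        at1, at2 = attachments(sub1), attachments(sub2)
        for e1 in at1:
            for e2 in at2:
                new_adj: Adj = {x: list(ys) for x, ys in sub1.items()}
                for x, ys in sub2.items():
                    new_adj[x] = list(ys)
                pool = list(frees)

                def endpoint(e) -> int:
                    if isinstance(e, int):
                        return e
                    a, b = e
                    w = pool.pop()
                    new_adj[a] = [x if x != b else w for x in new_adj[a]]
                    new_adj[b] = [x if x != a else w for x in new_adj[b]]
                    new_adj[w] = [a, b]
                    return w

                p1, p2 = endpoint(e1), endpoint(e2)
                # connect the two attachment points
                new_adj.setdefault(p1, [])
                new_adj.setdefault(p2, [])
                if p2 not in new_adj[p1]:
                    new_adj[p1].append(p2)
                    new_adj[p2].append(p1)
                yield new_adj


def search_tbr(
    matrix: CharacterMatrix,
    n_starts: int = 10,
    seed: int = 0,
    max_plateau: int = 2000,
) -> ParsimonyResult:
    """Hill-climb with TBR swapping from random-addition starting trees.

    Deterministic given ``seed``: starting orders come from one generator and
    TBR sweeps visit candidates in canonical edge order, accepting the first
    strict improvement.  Around each optimum an equal-length plateau walk
    (bounded by ``max_plateau`` topologies) collects ties; the returned set
    is not guaranteed exhaustive.
    """
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if n <= 5:
        res = search_exhaustive(matrix)
        res.method = "tbr(exhaustive fallback)"
        return res
    enc = _encode(matrix)
    rng = np.random.default_rng(seed)
    best: int | None = None
    keep: dict[frozenset[int], Adj] = {}
    for _ in range(n_starts):
        adj = _random_addition_tree(enc, rng)
        s = _score(adj, enc)
        improved = True
        while improved:
            improved = False
            for nb in _tbr_neighbors(adj, n):
                s2 = _score(nb, enc)
                if s2 < s:
                    adj, s = nb, s2
                    improved = True
                    break
        if best is None or s < best:
            best, keep = s, {}
        if s == best:
            key = _topology_key(adj, n)
            if key not in keep:
                keep[key] = adj
                if max_plateau > 1:
                    frontier = [adj]
                    while frontier and len(keep) < max_plateau:
                        cur = frontier.pop()
                        for nb in _tbr_neighbors(cur, n):
                            if _score(nb, enc) == best:
                                k2 = _topology_key(nb, n)
                                if k2 not in keep:
                                    keep[k2] = nb
                                    frontier.append(nb)
                                    if len(keep) >= max_plateau:
                                        break
    return _finish(matrix, best, keep, "tbr", False)


# ---------------------------------------------------------------------------
# Homoplasy indices
# ---------------------------------------------------------------------------

def _min_and_max_steps(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    states = matrix.states
    n0 = (states == 0).sum(axis=0)
    n1 = (states == 1).sum(axis=0)
    m = ((n0 > 0) & (n1 > 0)).astype(int)
    g = np.minimum(n0, n1)
    return m, g


def indices(
    tree_or_result: "PhyloTree | ParsimonyResult", matrix: CharacterMatrix
) -> tuple[float | None, float | None, float | None, np.ndarray]:
    """(CI, RI, HI, per-character steps) of a tree on ``matrix``.

    RI is None (undefined) when Σg == Σm, i.e. no character could show
    synapomorphy on any tree.  Constant characters contribute nothing to any
    of the sums.
    """
    tree = (
        tree_or_result.optimal_trees[0]
        if isinstance(tree_or_result, ParsimonyResult)
        else tree_or_result
    )
    steps = per_character_steps(tree, matrix)
    m, g = _min_and_max_steps(matrix)
    S, M, G = int(steps.sum()), int(m.sum()), int(g.sum())
    ci = M / S if S else None
    ri = (G - S) / (G - M) if G > M else None
    hi = 1.0 - ci if ci is not None else None
    return ci, ri, hi, steps


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap(
    matrix: CharacterMatrix,
    replicates: int = 1000,
    seed: int = 0,
    n_starts: int = 10,
    exhaustive_max_taxa: int = 7,
) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """Character (column) bootstrap with majority-rule consensus.

    Each replicate resamples characters with replacement at the original
    width, re-runs the search (exhaustive for small taxon sets, TBR without a
    plateau walk otherwise), and contributes the bipartitions present in the
    strict consensus of its optimal trees.  Returns the >50% majority-rule
    consensus with percent supports on its nodes, plus the full support
    table keyed by canonical bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n, C = matrix.n_taxa, matrix.n_characters
    counts: dict[frozenset[str], int] = {}
    from .characters import Character

    boot_chars = [Character(f"b{j}", "association") for j in range(C)]
    for _ in range(replicates):
        cols = rng.integers(0, C, size=C)
        sub = CharacterMatrix(matrix.taxa, boot_chars, matrix.states[:, cols])
        if n <= exhaustive_max_taxa:
            res = search_exhaustive(sub)
        else:
            res = search_tbr(
                sub, n_starts=n_starts, seed=int(rng.integers(2**31)), max_plateau=1
            )
        bips: frozenset[frozenset[str]] | None = None
        for t in res.optimal_trees:
            b = t.bipartitions()
            bips = b if bips is None else (bips & b)
        for b in bips or ():
            counts[b] = counts.get(b, 0) + 1
    support = {b: 100.0 * c / replicates for b, c in counts.items()}
    kept = {b: s for b, s in support.items() if s > 50.0}
    tree = tree_from_clades(frozenset(matrix.taxa), kept)
    return tree, support
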