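"""Karyotype evolution simulator with painting-style output.

Evolves a karyotype along a known rooted tree under four rearrangement
classes and emits, per tip, the homology map that painting the tip with
whole-chromosome probes of the *ancestor* would produce, together with a
ground-truth event log.  This makes every downstream step of the pipeline
(character coding, parsimony, branch signatures) testable against a known
truth without any external data.

Model
-----
* A chromosome is an ordered list of blocks from p-terminus to q-terminus;
  a block is an oriented fragment of one ancestral chromosome arm with a
  relative length.  The centromere is a position along the chromosome.
* **Robertsonian fusion** joins two whole chromosomes at a centromere: one
  becomes the p side (reversed), the other the q side.  Visible as a new
  syntenic association.
* **Tandem fusion** concatenates one chromosome onto the q-terminus of
  another (its centromere is lost).  Also visible as an association.
* **Fission** breaks a chromosome at its centromere (or at a block boundary
  or a random interior point when the centromere is terminal).  Visible as a
  lost association or a broken whole-chromosome synteny.
* **Pericentric inversion** reverses a segment spanning the centromere,
  with breakpoints drawn uniformly on each side.  Inversions are not
  deducible from a signal list alone, so each one deposits a heritable
  cytological mark (its character label) on the blocks it touched; tips
  expose their marks as a curated inversion-character supplement, mimicking
  how inversions are scored from banding rather than from paints.

Event counts per branch are Poisson with mean rate x branch length; all
operand choices come from one seeded generator, so equal seeds give equal
output.  ``replay`` re-applies a recorded event log deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .homology import HomologyMap, SignalBlock, canonical_pair
from .trees import Node, PhyloTree

__all__ = [
    "Block",
    "Chromosome",
    "SimulationConfig",
    "Event",
    "EventLog",
    "SimulationResult",
    "make_ancestor",
    "simulate",
    "replay",
    "homology_map_from_karyotype",
    "inversion_supplement",
]

EventType = Literal["robertsonian_fusion", "fission", "pericentric_inversion", "tandem_fusion"]

DEFAULT_RATES: dict[str, float] = {
    "robertsonian_fusion": 0.4,
    "fission": 0.2,
    "pericentric_inversion": 0.25,
    "tandem_fusion": 0.15,
}


@dataclass(frozen=True)
class Block:
    """Oriented fragment of one ancestral chromosome arm."""

    anc: str  # ancestral chromosome id
    arm: str  # "p" or "q"
    lo: float  # fragment interval within the arm, 0 <= lo < hi <= 1
    hi: float
    orient: int = 1
    marks: frozenset[str] = frozenset()

    @property
    def length(self) -> float:
        return self.hi - self.lo

    def flipped(self) -> "Block":
        return replace(self, orient=-self.orient)


@dataclass(frozen=True)
class Chromosome:
    id: str
    blocks: tuple[Block, ...]
    cent_pos: float  # distance from p-terminus, in block-length units

    @property
    def length(self) -> float:
        return sum(b.length for b in self.blocks)


KaryotypeState = dict[str, Chromosome]


def make_ancestor(n_chromosomes: int, include_x: bool = True) -> KaryotypeState:
    """Bi-armed ancestral karyotype: chromosome k = one p and one q arm."""
    ids = [str(i + 1) for i in range(n_chromosomes - (1 if include_x else 0))]
    if include_x:
        ids.append("X")
    state: KaryotypeState = {}
    for cid in ids:
        blocks = (Block(cid, "p", 0.0, 1.0), Block(cid, "q", 0.0, 1.0))
        state[cid] = Chromosome(id=cid, blocks=blocks, cent_pos=1.0)
    return state


@dataclass(frozen=True)
class Event:
    """One recorded rearrangement; carries everything needed to replay it."""

    branch: str  # name of the child node of the branch the event lies on
    event_type: EventType
    operands: tuple[str, ...]  # chromosome ids consumed
    products: tuple[str, ...]  # chromosome ids produced
    breakpoints: tuple[float, ...] = ()
    # expected character effects: (character label, 'gain'/'loss')
    effects: tuple[tuple[str, str], ...] = ()
    skipped: bool = False


EventLog = list[Event]


@dataclass
class SimulationConfig:
    tree: PhyloTree  # rooted, with branch lengths on every non-root node
    ancestor: KaryotypeState
    rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be >= 0")
        if len(self.ancestor) < 2:
            raise ValueError("ancestral karyotype needs >= 2 chromosomes")
        unknown = set(self.rates) - set(DEFAULT_RATES)
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")


@dataclass
class SimulationResult:
    config: SimulationConfig
    tip_karyotypes: dict[str, KaryotypeState]
    tip_maps: dict[str, HomologyMap]
    event_log: EventLog


# ---------------------------------------------------------------------------
# Applying events
# ---------------------------------------------------------------------------

def _reverse_blocks(blocks: Sequence[Block]) -> tuple[Block, ...]:
    return tuple(b.flipped() for b in reversed(blocks))


def _boundary_labels(left: Block, right: Block) -> tuple[str, str]:
    return left.anc, right.anc


def _split_blocks(
    blocks: Sequence[Block], pos: float
) -> tuple[tuple[Block, ...], tuple[Block, ...]]:
    """Split a block list at distance ``pos`` from its start."""
    left: list[Block] = []
    right: list[Block] = []
    x = 0.0
    for b in blocks:
        if x + b.length <= pos + 1e-12 and not right:
            left.append(b)
        elif x >= pos - 1e-12 or right:
            right.append(b)
        else:
            f = (pos - x) / b.length
            if b.orient == 1:
                cut = b.lo + f * b.length
                left.append(replace(b, hi=cut))
                right.append(replace(b, lo=cut))
            else:
                cut = b.hi - f * b.length
                left.append(replace(b, lo=cut))
                right.append(replace(b, hi=cut))
        x += b.length
    return tuple(left), tuple(right)


def apply_event(state: KaryotypeState, ev: Event) -> None:
    """Apply a recorded event in place.  Raises if operands are inapplicable."""
    if ev.skipped:
        return
    for cid in ev.operands:
        if cid not in state:
            raise ValueError(f"event on missing chromosome {cid!r}")
    if ev.event_type == "robertsonian_fusion":
        a, b = (state.pop(c) for c in ev.operands)
        new = Chromosome(
            id=ev.products[0],
            blocks=_reverse_blocks(a.blocks) + b.blocks,
            cent_pos=a.length,
        )
        state[new.id] = new
    elif ev.event_type == "tandem_fusion":
        a, b = (state.pop(c) for c in ev.operands)
        state[ev.products[0]] = Chromosome(
            id=ev.products[0], blocks=a.blocks + b.blocks, cent_pos=a.cent_pos
        )
    elif ev.event_type == "fission":
        (c,) = (state.pop(cid) for cid in ev.operands)
        (pos,) = ev.breakpoints
        left, right = _split_blocks(c.blocks, pos)
        if not left or not right:
            raise ValueError(f"degenerate fission of {c.id} at {pos}")
        state[ev.products[0]] = Chromosome(
            id=ev.products[0], blocks=left, cent_pos=min(c.cent_pos, sum(b.length for b in left))
        )
        state[ev.products[1]] = Chromosome(
            id=ev.products[1], blocks=right, cent_pos=max(0.0, c.cent_pos - pos)
        )
    elif ev.event_type == "pericentric_inversion":
        (c,) = (state.pop(cid) for cid in ev.operands)
        lo, hi = ev.breakpoints
        mark = ev.effects[0][0] if ev.effects else None
        head, rest = _split_blocks(c.blocks, lo)
        mid, tail = _split_blocks(rest, hi - lo)
        if mark:
            mid = tuple(replace(b, marks=b.marks | {mark}) for b in mid)
        new_blocks = head + _reverse_blocks(mid) + tail
        new_cent = lo + (hi - c.cent_pos)
        state[ev.products[0]] = Chromosome(
            id=ev.products[0], blocks=new_blocks, cent_pos=new_cent
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown event type {ev.event_type!r}")


# ---------------------------------------------------------------------------
# Sampling events
# ---------------------------------------------------------------------------

def _signal_runs(blocks: Sequence[Block]) -> list[str]:
    """Ancestor labels of the chromosome's merged signal runs, in order."""
    out: list[str] = []
    for b in blocks:
        if not out or out[-1] != b.anc:
            out.append(b.anc)
    return out


def _sample_event(
    state: KaryotypeState,
    etype: EventType,
    branch: str,
    rng: np.random.Generator,
    fresh: Iterable[str],
) -> Event:
    ids = sorted(state)
    if etype in ("robertsonian_fusion", "tandem_fusion"):
        if len(ids) < 2:
            return Event(branch, etype, (), (), skipped=True)
        i, j = rng.choice(len(ids), size=2, replace=False)
        a, b = state[ids[int(i)]], state[ids[int(j)]]
        new_id = next(fresh)
        if etype == "robertsonian_fusion":
            la, lb = a.blocks[0].anc, b.blocks[0].anc
        else:
            la, lb = a.blocks[-1].anc, b.blocks[0].anc
        effects = (
            ((canonical_pair(la, lb), "gain"),) if la != lb else ((la, "gain"),)
        )
        return Event(branch, etype, (a.id, b.id), (new_id,), effects=effects)
    if etype == "fission":
        cid = ids[int(rng.integers(len(ids)))]
        c = state[cid]
        L = c.length
        if 1e-9 < c.cent_pos < L - 1e-9:
            pos = c.cent_pos
        else:
            pos = float(rng.uniform(0.05, 0.95)) * L
        left, right = _split_blocks(c.blocks, pos)
        if not left or not right:
            return Event(branch, etype, (cid,), (), skipped=True)
        la, lb = left[-1].anc, right[0].anc
        effects = (
            ((canonical_pair(la, lb), "loss"),) if la != lb else ((la, "loss"),)
        )
        p1, p2 = next(fresh), next(fresh)
        return Event(branch, etype, (cid,), (p1, p2), breakpoints=(pos,), effects=effects)
    if etype == "pericentric_inversion":
        cid = ids[int(rng.integers(len(ids)))]
        c = state[cid]
        L = c.length
        cent = min(max(c.cent_pos, 0.0), L)
        lo = float(rng.uniform(0.0, cent)) if cent > 1e-9 else 0.0
        hi = float(rng.uniform(cent, L)) if cent < L - 1e-9 else L
        if hi - lo < 1e-9:
            return Event(branch, etype, (cid,), (), skipped=True)
        # the mark names the ancestral chromosome at the centromere plus the
        # breakpoints: independent inversions of one chromosome differ by
        # their breakpoints and are cytologically distinguishable, so they
        # must not collapse into a single character
        runs = _signal_runs(_split_blocks(c.blocks, cent)[0][::-1] or c.blocks)
        anc_at_cent = runs[0] if runs else c.blocks[0].anc
        mark = f"i{anc_at_cent}:{lo:.4f}-{hi:.4f}"
        return Event(
            branch,
            etype,
            (cid,),
            (cid,),
            breakpoints=(lo, hi),
            effects=((mark, "gain"),),
        )
    raise ValueError(f"unknown event type {etype!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def _node_names(tree: PhyloTree) -> dict[int, str]:
    """Stable names: leaves keep labels, internal nodes n1, n2, ... preorder."""
    names: dict[int, str] = {}
    k = 0
    for n in tree.preorder():
        if n.is_leaf:
            names[id(n)] = n.label
        else:
            k += 1
            names[id(n)] = f"n{k}"
    return names


def _copy_state(state: KaryotypeState) -> KaryotypeState:
    return dict(state)  # Chromosome/Block are immutable


def simulate(config: SimulationConfig) -> SimulationResult:
    """Evolve the ancestor along the tree; return tips, maps, and event log."""
    rng = np.random.default_rng(config.seed)
    names = _node_names(config.tree)
    counter = iter(f"c{i}" for i in range(1, 10**6))
    log: EventLog = []
    tips: dict[str, KaryotypeState] = {}

    def walk(node: Node, state: KaryotypeState) -> None:
        for child in node.children:
            child_state = _copy_state(state)
            length = child.length if child.length is not None else 1.0
            events: list[Event] = []
            for etype, rate in sorted(config.rates.items()):
                k = int(rng.poisson(rate * length))
                events.extend([etype] * k)
            if events:
                order = rng.permutation(len(events))
                events = [events[int(i)] for i in order]
            for etype in events:
                ev = _sample_event(child_state, etype, names[id(child)], rng, counter)
                log.append(ev)
                apply_event(child_state, ev)
            if child.is_leaf:
                tips[child.label] = child_state
            else:
                walk(child, child_state)

    walk(config.tree.root, _copy_state(config.ancestor))
    maps = {
        tip: homology_map_from_karyotype(state, "ANC", tip)
        for tip, state in tips.items()
    }
    return SimulationResult(config, tips, maps, log)


def replay(
    ancestor: KaryotypeState, log: EventLog, tree: PhyloTree
) -> dict[str, KaryotypeState]:
    """Re-apply a recorded log along the tree; deterministic.

    Raises naming the event index if an operand is inapplicable.
    """
    names = _node_names(tree)
    by_branch: dict[str, list[tuple[int, Event]]] = {}
    for i, ev in enumerate(log):
        by_branch.setdefault(ev.branch, []).append((i, ev))
    tips: dict[str, KaryotypeState] = {}

    def walk(node: Node, state: KaryotypeState) -> None:
        for child in node.children:
            child_state = _copy_state(state)
            for i, ev in by_branch.get(names[id(child)], []):
                try:
                    apply_event(child_state, ev)
                except ValueError as exc:
                    raise ValueError(f"event {i}: {exc}") from exc
            if child.is_leaf:
                tips[child.label] = child_state
            else:
                walk(child, child_state)

    walk(tree.root, _copy_state(ancestor))
    return tips


# ---------------------------------------------------------------------------
# Painting-style output
# ---------------------------------------------------------------------------

def homology_map_from_karyotype(
    state: KaryotypeState, probe_species: str, target_species: str
) -> HomologyMap:
    """The map that painting ``state`` with ancestor whole-chromosome probes
    would produce: consecutive blocks of one ancestral chromosome merge into
    a single signal."""
    hmap = HomologyMap(probe_species=probe_species, target_species=target_species)
    for cid in sorted(state):
        blocks = state[cid].blocks
        signals: list[SignalBlock] = []
        for b in blocks:
            if signals and signals[-1].probe_chromosome == b.anc:
                signals[-1] = replace(
                    signals[-1], length=signals[-1].length + b.length
                )
            else:
                signals.append(
                    SignalBlock(
                        probe_chromosome=b.anc,
                        position_index=len(signals),
                        painted=True,
                        length=b.length,
                    )
                )
        hmap.signals[cid] = signals
    hmap.validate()
    return hmap


def inversion_supplement(
    tips: Mapping[str, KaryotypeState], extra_taxa: Sequence[str] = ()
) -> dict[str, dict[str, int]]:
    """Curated inversion characters from tip cytology: mark -> taxon -> 0/1.

    ``extra_taxa`` (e.g. the ancestor used as outgroup) score 0 throughout.
    """
    all_marks: set[str] = set()
    tip_marks: dict[str, set[str]] = {}
    for taxon, state in tips.items():
        marks = set()
        for c in state.values():
            for b in c.blocks:
                marks |= b.marks
        tip_marks[taxon] = marks
        all_marks |= marks
    out: dict[str, dict[str, int]] = {}
    for mark in sorted(all_marks):
        col = {t: int(mark in tip_marks[t]) for t in tips}
        for t in extra_taxa:
            col[t] = 0
        out[mark] = col
    return out
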