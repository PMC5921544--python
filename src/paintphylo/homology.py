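"""Karyotypes and cross-species chromosome-painting homology maps.

A Zoo-FISH experiment hybridises whole-chromosome paint probes from one
species onto metaphase chromosomes of another.  The readable result is, for
each target chromosome, the ordered list of probe-chromosome signals from the
p-terminus to the q-terminus.  This module represents those maps, counts
homologous segments, detects syntenic associations (two or more probe
chromosomes physically adjacent on one target chromosome — the raw material
for fusion-derived phylogenetic characters), and composes two maps that share
a reference genome into probe-to-probe correspondences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Karyotype",
    "SignalBlock",
    "HomologyMap",
    "SyntenicAssociation",
    "HomologyMapError",
    "parse_homology_map",
    "write_homology_map",
    "count_segments",
    "detect_associations",
    "adjacent_pairs",
    "compose_maps",
    "canonical_pair",
]


class HomologyMapError(ValueError):
    """Raised for malformed or inconsistent homology-map input."""


@dataclass(frozen=True)
class Karyotype:
    """A species karyotype at chromosome resolution.

    ``diploid_number`` is 2n; odd values are permitted because several
    phyllostomid species carry X0 or XY1Y2 sex systems (e.g. CBR 2n=20/21).
    ``fundamental_number`` (FN) counts chromosome arms in the complement.
    """

    species_code: str
    diploid_number: int
    fundamental_number: int
    chromosomes: tuple[tuple[str, bool, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.diploid_number < 2:
            raise ValueError("diploid_number must be >= 2")
        ids = [c[0] for c in self.chromosomes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chromosome ids in {self.species_code}")

    @property
    def chromosome_ids(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.chromosomes)


@dataclass(frozen=True)
class SignalBlock:
    """One hybridisation signal (or unpainted gap) on a target chromosome.

    ``probe_chromosome`` may be arm-qualified ("7q").  ``painted=False``
    encodes blocks no probe labels, typically constitutive heterochromatin
    (e.g. the fully heterochromatic RFI 16q); such blocks are retained but
    never counted as homologous segments.  ``length`` is a relative size used
    only by map composition; the default 1.0 means "blocks of equal weight".
    """

    probe_chromosome: str
    position_index: int
    painted: bool = True
    length: float = 1.0
    target_arm: str | None = None  # "p" / "q" when the source row was arm-qualified


@dataclass
class HomologyMap:
    """Signals of one probe set on one target species, per target chromosome."""

    probe_species: str
    target_species: str
    signals: dict[str, list[SignalBlock]] = field(default_factory=dict)
    target_karyotype: Karyotype | None = None

    def validate(self) -> None:
        for chrom, blocks in self.signals.items():
            if not blocks:
                raise HomologyMapError(f"empty signal list for target {chrom}")
            positions = [b.position_index for b in blocks]
            if positions != list(range(len(blocks))):
                raise HomologyMapError(
                    f"positions on target {chrom} not consecutive from 0: {positions}"
                )
            for b in blocks:
                if b.painted and not b.probe_chromosome:
                    raise HomologyMapError(
                        f"painted block without probe label on target {chrom}"
                    )
        if self.target_karyotype is not None:
            known = set(self.target_karyotype.chromosome_ids)
            unknown = set(self.signals) - known
            if unknown:
                raise HomologyMapError(
                    f"targets absent from {self.target_species} karyotype: {sorted(unknown)}"
                )

    def probe_chromosomes(self) -> set[str]:
        """Bare probe chromosome labels (arm qualifiers stripped) seen painted."""
        out: set[str] = set()
        for blocks in self.signals.values():
            for b in blocks:
                if b.painted:
                    out.add(strip_arm(b.probe_chromosome))
        return out

    def is_complete(self, probe_karyotype: Karyotype) -> bool:
        """Whether every probe chromosome produced at least one signal.

        Y chromosomes are exempt: paints were made from flow-sorted female or
        mixed material and Y-linked probes are frequently absent.
        """
        seen = self.probe_chromosomes()
        for cid in probe_karyotype.chromosome_ids:
            if cid.upper().startswith("Y"):
                continue
            if cid not in seen:
                return False
        return True


@dataclass(frozen=True)
class SyntenicAssociation:
    """A maximal run of >=2 adjacent painted signals on one target chromosome."""

    probe_species: str
    members: tuple[str, ...]
    target_species: str
    target_chromosome: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("association needs >= 2 members")

    def pairs(self) -> list[str]:
        """Canonical labels of the adjacent pairs within the run (deduplicated)."""
        seen: list[str] = []
        for a, b in zip(self.members, self.members[1:]):
            lab = canonical_pair(a, b)
            if lab not in seen:
                seen.append(lab)
        return seen


_ARM_RE = re.compile(r"^(.*?)([pq])$")


def strip_arm(label: str) -> str:
    m = _ARM_RE.match(label)
    return m.group(1) if m else label


def canonical_pair(a: str, b: str) -> str:
    """Canonical unordered association label: lexicographically sorted "A/B".

    Lexicographic order reproduces the field's labels ("13/4", "2/Y2").
    """
    x, y = sorted((a, b))
    return f"{x}/{y}"


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def parse_homology_map(path: str | Path) -> HomologyMap:
    """Read a homology map in the TSV dialect.

    Header lines ``#probe=<CODE>`` and ``#target=<CODE>``; other ``#`` lines
    are comments.  Data rows are
    ``target_chromosome<TAB>position_index<TAB>probe_label<TAB>painted(0/1)``
    with an optional fifth relative-length column.  The probe label is "."
    on unpainted rows.  Target chromosome ids may be arm-qualified ("4q");
    arm rows are folded into the bare chromosome id, p-arm rows first.
    """
    path = Path(path)
    probe = target = None
    rows: list[tuple[int, str, str | None, int, str, bool, float]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#probe="):
                    probe = line.split("=", 1)[1].strip()
                elif line.startswith("#target="):
                    target = line.split("=", 1)[1].strip()
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise HomologyMapError(
                    f"{path.name}:{lineno}: expected 4 or 5 tab-separated fields, got {len(parts)}"
                )
            tchrom_raw, pos_s, plabel, painted_s = parts[:4]
            length = 1.0
            if len(parts) == 5:
                try:
                    length = float(parts[4])
                except ValueError as exc:
                    raise HomologyMapError(f"{path.name}:{lineno}: bad length {parts[4]!r}") from exc
                if length <= 0:
                    raise HomologyMapError(f"{path.name}:{lineno}: length must be > 0")
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise HomologyMapError(f"{path.name}:{lineno}: bad position {pos_s!r}") from exc
            if painted_s not in ("0", "1"):
                raise HomologyMapError(f"{path.name}:{lineno}: painted must be 0 or 1")
            painted = painted_s == "1"
            if painted and plabel == ".":
                raise HomologyMapError(f"{path.name}:{lineno}: painted row with '.' label")
            arm = None
            m = _ARM_RE.match(tchrom_raw)
            if m and m.group(1):
                tchrom, arm = m.group(1), m.group(2)
            else:
                tchrom = tchrom_raw
            rows.append((lineno, tchrom, arm, pos, plabel, painted, length))
    if probe is None or target is None:
        raise HomologyMapError(f"{path.name}: missing #probe=/#target= header")
    if not rows:
        raise HomologyMapError(f"{path.name}: no signal rows")

    hmap = HomologyMap(probe_species=probe, target_species=target)
    # group rows per (chromosome, arm); p-arm rows precede q-arm rows, plain
    # rows keep file order.  Position indices are then renumbered consecutively.
    grouped: dict[str, dict[str | None, list[tuple[int, int, str, bool, float]]]] = {}
    for lineno, tchrom, arm, pos, plabel, painted, length in rows:
        grouped.setdefault(tchrom, {}).setdefault(arm, []).append(
            (pos, lineno, plabel, painted, length)
        )
    for tchrom, by_arm in grouped.items():
        ordered: list[tuple[int, str, bool, float, str | None]] = []
        arm_order = [a for a in ("p", None, "q") if a in by_arm]
        for arm in arm_order:
            entries = sorted(by_arm[arm])
            seen_pos = set()
            for pos, lineno, plabel, painted, length in entries:
                if pos in seen_pos:
                    raise HomologyMapError(
                        f"{path.name}:{lineno}: duplicate (target {tchrom}{arm or ''}, position {pos})"
                    )
                seen_pos.add(pos)
                ordered.append((lineno, plabel, painted, length, arm))
        hmap.signals[tchrom] = [
            SignalBlock(
                probe_chromosome="" if plabel == "." else plabel,
                position_index=i,
                painted=painted,
                length=length,
                target_arm=arm,
            )
            for i, (lineno, plabel, painted, length, arm) in enumerate(ordered)
        ]
    hmap.validate()
    return hmap


def write_homology_map(hmap: HomologyMap, path: str | Path) -> None:
    """Write a map in the TSV dialect (LF endings, UTF-8)."""
    path = Path(path)
    lines = [f"#probe={hmap.probe_species}", f"#target={hmap.target_species}"]
    for tchrom in hmap.signals:
        for b in hmap.signals[tchrom]:
            tid = f"{tchrom}{b.target_arm}" if b.target_arm else tchrom
            label = b.probe_chromosome if b.painted else "."
            row = [tid, str(b.position_index), label, "1" if b.painted else "0"]
            if b.length != 1.0:
                row.append(repr(b.length))
            lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# Segment counting and association detection
# ---------------------------------------------------------------------------

def _is_y_target(chrom: str) -> bool:
    return chrom.upper().startswith("Y")


def count_segments(hmap: HomologyMap, include_y: bool = True) -> int:
    """Total painted signal blocks across target chromosomes.

    Each signal counts once, so a chromosome painted CBR 2/Y2/2/Y2 contributes
    four segments.  ``include_y=False`` drops Y/Y1/Y2 *target* chromosomes
    before counting (the convention some printed totals follow).
    """
    total = 0
    for tchrom, blocks in hmap.signals.items():
        if not include_y and _is_y_target(tchrom):
            continue
        total += sum(1 for b in blocks if b.painted)
    return total


def detect_associations(hmap: HomologyMap) -> list[SyntenicAssociation]:
    """Maximal runs of >=2 adjacent painted signals, per target chromosome.

    Unpainted (heterochromatic) blocks break adjacency: two probe signals
    separated by heterochromatin are not physically linked at the resolution
    painting resolves.
    """
    out: list[SyntenicAssociation] = []
    for tchrom, blocks in hmap.signals.items():
        run: list[str] = []
        for b in blocks:
            if b.painted:
                run.append(b.probe_chromosome)
            else:
                if len(run) >= 2:
                    out.append(
                        SyntenicAssociation(
                            hmap.probe_species, tuple(run), hmap.target_species, tchrom
                        )
                    )
                run = []
        if len(run) >= 2:
            out.append(
                SyntenicAssociation(
                    hmap.probe_species, tuple(run), hmap.target_species, tchrom
                )
            )
    return out


def adjacent_pairs(hmap: HomologyMap) -> set[str]:
    """All canonical pairwise adjacency labels in the map (arm qualifiers kept)."""
    pairs: set[str] = set()
    for assoc in detect_associations(hmap):
        pairs.update(assoc.pairs())
    return pairs


# ---------------------------------------------------------------------------
# Transitive composition through a shared reference genome
# ---------------------------------------------------------------------------

def _intervals(blocks: Sequence[SignalBlock]) -> list[tuple[float, float, SignalBlock]]:
    """Lay blocks out on [0, 1] of the reference chromosome.

    Arm-qualified blocks share the chromosome half for their arm (p first),
    proportionally to relative length within the arm; unqualified blocks split
    the whole chromosome proportionally.  Arm boundaries are hard breakpoints.
    """
    arms = {b.target_arm for b in blocks}
    spans: list[tuple[float, float, Sequence[SignalBlock]]] = []
    if arms == {None} or len(arms) == 1:
        spans.append((0.0, 1.0, blocks))
    else:
        p_blocks = [b for b in blocks if b.target_arm == "p"]
        q_blocks = [b for b in blocks if b.target_arm != "p"]
        if p_blocks:
            spans.append((0.0, 0.5, p_blocks))
        if q_blocks:
            spans.append((0.5, 1.0, q_blocks))
    out: list[tuple[float, float, SignalBlock]] = []
    for lo, hi, group in spans:
        total = sum(b.length for b in group)
        x = lo
        for b in group:
            w = (hi - lo) * b.length / total
            out.append((x, x + w, b))
            x += w
    return out


def compose_maps(
    ab: HomologyMap, cb: HomologyMap, eps: float = 1e-9
) -> dict[str, set[str]]:
    """Correspondences A-label -> {C-labels} from two maps on one reference.

    ``ab`` maps species-A probes onto reference R; ``cb`` maps species-C
    probes onto the same R.  For each reference chromosome both maps cover,
    the two block partitions are interleaved by position order and every pair
    of painted blocks with overlapping reference intervals is emitted.  Block
    lengths are relative (equal by default); arm boundaries are hard
    breakpoints when either map is arm-resolved.
    """
    if ab.target_species != cb.target_species:
        raise HomologyMapError(
            f"reference mismatch: {ab.target_species} vs {cb.target_species}"
        )
    corr: dict[str, set[str]] = {}
    for tchrom in ab.signals:
        if tchrom not in cb.signals:
            continue
        a_iv = _intervals(ab.signals[tchrom])
        c_iv = _intervals(cb.signals[tchrom])
        for alo, ahi, ablk in a_iv:
            if not ablk.painted:
                continue
            for clo, chi, cblk in c_iv:
                if not cblk.painted:
                    continue
                if min(ahi, chi) - max(alo, clo) > eps:
                    corr.setdefault(ablk.probe_chromosome, set()).add(
                        cblk.probe_chromosome
                    )
    return corr


def identity_map(species: str, chromosomes: Iterable[str]) -> HomologyMap:
    """The identity self-map of a reference genome (one block per chromosome)."""
    hmap = HomologyMap(probe_species=species, target_species=species)
    for cid in chromosomes:
        hmap.signals[cid] = [SignalBlock(probe_chromosome=cid, position_index=0)]
    return hmap
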