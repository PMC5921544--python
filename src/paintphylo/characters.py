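"""Binary rearrangement characters and the taxa x characters matrix.

Characters follow the symbol grammar of comparative cytogenetics, with
labels expressed in outgroup (probe-species) chromosome numbering:

* association ``"A/B"`` — probe chromosomes A and B physically adjacent on
  one target chromosome (a fusion-derived synteny); unordered, canonicalised
  by lexicographic sort ("13/4", "2/Y2").
* inversion ``"iN"`` — an inversion rearranging probe chromosome N.
* arm state ``"Np"`` / ``"Nq"`` / ``"Np+q"`` — a separated short arm, long
  arm, or a short-arm piece linked to a long-arm piece.
* whole chromosome ``"N"`` — probe chromosome N conserved as a single
  syntenic block.

Cell states are 1 (present), 0 (absent) and missing.  Missing means the taxon
was not scored for that character (no map for the probe set, or a region that
could not be evaluated) — under parsimony it contributes the full state set,
never a silent 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .homology import HomologyMap, adjacent_pairs, strip_arm

__all__ = [
    "Character",
    "CharacterMatrix",
    "MISSING",
    "derive_characters",
    "concat_matrices",
    "read_matrix",
    "write_nexus",
    "write_phylip",
    "write_tsv",
]

MISSING = -1

_KIND_RES = (
    ("association", re.compile(r"^[^/]+/[^/]+$")),
    ("inversion", re.compile(r"^i.+$")),
    ("arm_state", re.compile(r"^.+?(p|q|p\+q)$")),
)


def classify_label(label: str) -> str:
    for kind, rx in _KIND_RES:
        if rx.match(label):
            return kind
    return "whole_chromosome"


@dataclass(frozen=True)
class Character:
    label: str
    kind: str

    @classmethod
    def from_label(cls, label: str) -> "Character":
        return cls(label=label, kind=classify_label(label))


class CharacterMatrix:
    """Rectangular taxa x binary-characters matrix with missing data.

    ``states`` is an int8 array with entries in {0, 1, MISSING}.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[Character],
        states: np.ndarray,
    ) -> None:
        if len(taxa) == 0:
            raise ValueError("matrix needs at least one taxon")
        states = np.asarray(states, dtype=np.int8)
        if states.shape != (len(taxa), len(characters)):
            raise ValueError(
                f"states shape {states.shape} != ({len(taxa)}, {len(characters)})"
            )
        bad = ~np.isin(states, (0, 1, MISSING))
        if bad.any():
            raise ValueError("states must be 0, 1 or missing")
        labels = [c.label for c in characters]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate character labels")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxa")
        self.taxa = list(taxa)
        self.characters = list(characters)
        self.states = states

    # -- basic queries ------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def labels(self) -> list[str]:
        return [c.label for c in self.characters]

    def column(self, label: str) -> np.ndarray:
        return self.states[:, self.labels().index(label)]

    def is_variable(self) -> np.ndarray:
        """Per character: has both a 0 and a 1 among non-missing cells."""
        has0 = (self.states == 0).any(axis=0)
        has1 = (self.states == 1).any(axis=0)
        return has0 & has1

    def is_parsimony_informative(self) -> np.ndarray:
        """Per character: at least two taxa in each of two states."""
        n0 = (self.states == 0).sum(axis=0)
        n1 = (self.states == 1).sum(axis=0)
        return (n0 >= 2) & (n1 >= 2)

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return CharacterMatrix(list(taxa), self.characters, self.states[idx])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.characters == other.characters
            and np.array_equal(self.states, other.states)
        )


# ---------------------------------------------------------------------------
# Character derivation from homology maps
# ---------------------------------------------------------------------------

def derive_characters(
    maps: Mapping[str, HomologyMap],
    taxa: Sequence[str],
    include_intact: bool = True,
    supplement: Mapping[str, Mapping[str, int]] | None = None,
    label_prefix: str = "",
) -> CharacterMatrix:
    """Presence/absence characters from one probe set's maps across taxa.

    ``maps`` is taxon -> HomologyMap (all sharing one probe species).  One
    association character is emitted per distinct pairwise adjacency seen in
    at least one taxon; with ``include_intact`` a whole-chromosome character
    is emitted per probe chromosome, scored 1 when the probe paints exactly
    one contiguous signal in that taxon.  ``supplement`` adds curated
    characters (inversions, arm states — not derivable from signal lists
    alone) as label -> {taxon: 0/1}; taxa absent from a supplement entry are
    scored missing.

    ``label_prefix`` namespaces the labels (e.g. ``"PHA "``) so matrices from
    different probe sets can be concatenated without collisions.

    Deterministic and invariant to map iteration order: characters are sorted
    by (kind, label).
    """
    for t in taxa:
        if t not in maps:
            raise ValueError(f"taxon without a homology map: {t}")
    probe_species = {m.probe_species for m in maps.values()}
    if len(probe_species) != 1:
        raise ValueError(f"maps mix probe sets: {sorted(probe_species)}")

    pair_sets = {t: adjacent_pairs(maps[t]) for t in taxa}
    all_pairs = sorted(set().union(*pair_sets.values())) if pair_sets else []

    columns: list[tuple[Character, dict[str, int]]] = []
    for lab in all_pairs:
        columns.append(
            (
                Character(label_prefix + lab, "association"),
                {t: int(lab in pair_sets[t]) for t in taxa},
            )
        )
    if include_intact:
        probes = sorted(set().union(*(maps[t].probe_chromosomes() for t in taxa)))
        for p in probes:
            col = {}
            for t in taxa:
                nsig = sum(
                    1
                    for blocks in maps[t].signals.values()
                    for b in blocks
                    if b.painted and strip_arm(b.probe_chromosome) == p
                )
                col[t] = int(nsig == 1)
            columns.append((Character(label_prefix + p, "whole_chromosome"), col))
    if supplement:
        for lab in sorted(supplement):
            cells = supplement[lab]
            col = {t: int(cells[t]) if t in cells and cells[t] is not None else MISSING for t in taxa}
            columns.append((Character(label_prefix + lab, classify_label(lab)), col))

    columns.sort(key=lambda c: (c[0].kind, c[0].label))
    states = np.array(
        [[col[t] for _, col in columns] for t in taxa], dtype=np.int8
    ).reshape(len(taxa), len(columns))
    return CharacterMatrix(list(taxa), [c for c, _ in columns], states)


def concat_matrices(matrices: Sequence[CharacterMatrix]) -> CharacterMatrix:
    """Concatenate matrices over the union of taxa; absent cells are missing."""
    taxa: list[str] = []
    for m in matrices:
        for t in m.taxa:
            if t not in taxa:
                taxa.append(t)
    chars: list[Character] = []
    blocks: list[np.ndarray] = []
    for m in matrices:
        chars.extend(m.characters)
        block = np.full((len(taxa), m.n_characters), MISSING, dtype=np.int8)
        for i, t in enumerate(m.taxa):
            block[taxa.index(t)] = m.states[i]
        blocks.append(block)
    return CharacterMatrix(taxa, chars, np.hstack(blocks))


# ---------------------------------------------------------------------------
# Matrix I/O: NEXUS, relaxed PHYLIP, labelled TSV
# ---------------------------------------------------------------------------

def _state_char(v: int) -> str:
    return "-" if v == MISSING else str(int(v))


def write_nexus(
    matrix: CharacterMatrix, path: str | Path, missing_symbol: str = "-"
) -> None:
    """NEXUS DATA block, DATATYPE=STANDARD SYMBOLS="01" MISSING=-.

    Some readers reserve "-" for alignment gaps; pass ``missing_symbol="?"``
    for those.
    """
    lines = ["#NEXUS", "", "BEGIN DATA;"]
    lines.append(
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};"
    )
    lines.append(
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING={missing_symbol};'
    )
    lines.append("    CHARLABELS")
    lines.append(
        "        " + " ".join(f"'{c.label}'" for c in matrix.characters)
    )
    lines.append("    ;")
    lines.append("    MATRIX")
    width = max(len(t) for t in matrix.taxa) + 2
    for i, t in enumerate(matrix.taxa):
        row = "".join(
            missing_symbol if v == MISSING else str(int(v)) for v in matrix.states[i]
        )
        lines.append(f"        {t:<{width}}{row}")
    lines.append("    ;")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_phylip(matrix: CharacterMatrix, path: str | Path) -> None:
    """Relaxed PHYLIP (name, whitespace, 0/1/- row).  Labels are not stored."""
    lines = [f"{matrix.n_taxa} {matrix.n_characters}"]
    width = max(len(t) for t in matrix.taxa) + 2
    for i, t in enumerate(matrix.taxa):
        row = "".join(_state_char(v) for v in matrix.states[i])
        lines.append(f"{t:<{width}}{row}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_tsv(matrix: CharacterMatrix, path: str | Path) -> None:
    """Labelled TSV: header row of character labels, then taxon rows."""
    lines = ["taxon\t" + "\t".join(c.label for c in matrix.characters)]
    for i, t in enumerate(matrix.taxa):
        lines.append(t + "\t" + "\t".join(_state_char(v) for v in matrix.states[i]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_row_states(row: str, where: str) -> list[int]:
    out = []
    for ch in row:
        if ch in "01":
            out.append(int(ch))
        elif ch in "-?":
            out.append(MISSING)
        else:
            raise ValueError(f"{where}: illegal state symbol {ch!r}")
    return out


def _read_nexus(text: str, where: str) -> CharacterMatrix:
    # tolerant NEXUS DATA/CHARACTERS reader for the dialect written above
    ntax = nchar = None
    m = re.search(r"DIMENSIONS[^;]*NTAX\s*=\s*(\d+)[^;]*NCHAR\s*=\s*(\d+)", text, re.I)
    if m:
        ntax, nchar = int(m.group(1)), int(m.group(2))
    labels: list[str] | None = None
    m = re.search(r"CHARLABELS(.*?);", text, re.S | re.I)
    if m:
        labels = re.findall(r"'([^']*)'|(\S+)", m.group(1))
        labels = [a or b for a, b in labels]
    m = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not m:
        raise ValueError(f"{where}: no MATRIX block")
    taxa, rows = [], []
    for line in m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        name, row = line.split(None, 1)
        taxa.append(name.strip("'"))
        rows.append(_parse_row_states(row.replace(" ", ""), where))
    return _assemble(taxa, rows, labels, ntax, nchar, where)


def _read_phylip(text: str, where: str) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    ntax, nchar = int(header[0]), int(header[1])
    taxa, rows = [], []
    for line in lines[1 : 1 + ntax]:
        name, row = line.split(None, 1)
        taxa.append(name)
        rows.append(_parse_row_states(row.replace(" ", ""), where))
    return _assemble(taxa, rows, None, ntax, nchar, where)


def _read_tsv(text: str, where: str) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    labels = header[1:]
    taxa, rows = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        taxa.append(parts[0])
        rows.append(_parse_row_states("".join(parts[1:]), where))
    return _assemble(taxa, rows, labels, None, len(labels), where)


def _assemble(taxa, rows, labels, ntax, nchar, where) -> CharacterMatrix:
    if not rows:
        raise ValueError(f"{where}: empty matrix")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{where}: non-rectangular matrix (row widths {sorted(widths)})")
    width = widths.pop()
    if nchar is not None and nchar != width:
        raise ValueError(f"{where}: NCHAR={nchar} but rows have {width} states")
    if ntax is not None and ntax != len(taxa):
        raise ValueError(f"{where}: NTAX={ntax} but {len(taxa)} rows")
    if labels is None:
        labels = [f"c{i+1}" for i in range(width)]
    if len(labels) != width:
        raise ValueError(f"{where}: {len(labels)} labels for {width} characters")
    chars = [Character.from_label(lab) for lab in labels]
    return CharacterMatrix(taxa, chars, np.array(rows, dtype=np.int8))


def read_matrix(path: str | Path) -> CharacterMatrix:
    """Read NEXUS, relaxed PHYLIP, or labelled TSV (auto-detected)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.upper().startswith("#NEXUS"):
        return _read_nexus(text, path.name)
    first = stripped.splitlines()[0] if stripped else ""
    if re.match(r"^\s*\d+\s+\d+\s*$", first):
        return _read_phylip(text, path.name)
    return _read_tsv(text, path.name)
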