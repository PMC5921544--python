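# Methods

## The problem

Zoo-FISH (cross-species chromosome painting) hybridises whole-chromosome
paint probes of one species onto metaphase spreads of another.  Each target
chromosome then reads as an ordered list of probe-chromosome signals from
p-terminus to q-terminus.  Two kinds of phylogenetic evidence fall out of
such maps: *syntenic associations* — two or more probe chromosomes physically
adjacent on one target chromosome, the footprint of a fusion — and broken or
conserved whole-chromosome syntenies, the footprint of fissions.  Scored as
binary presence/absence characters across taxa, these support a cladistic
analysis under maximum parsimony.  This package implements that pipeline for
the phyllostomid-bat system it reproduces: probes from *Phyllostomus
hastatus* (PHA, the karyotypically conservative outgroup) and *Carollia
brevicauda* (CBR) painted onto *Rhinophylla pumilio* (RPU), *Rhinophylla*
aff. *fischerae* (RFI), *Trinycteris nicefori* (TNI) and *Glossophaga
soricina* (GSO), combined with previously published maps of eight
stenodermatine species.

## Homology maps

A map is stored per (probe set, target species) as ordered `SignalBlock`
lists keyed by target chromosome.  Unpainted heterochromatic blocks (e.g.
the fully heterochromatic RFI 16q) are retained in the data structure but
excluded from segment totals and association detection; an unpainted block
also *breaks* adjacency, since heterochromatin physically separates its
neighbours at painting resolution.  Interleaved signals count separately:
a chromosome painted CBR 2/Y2/2/Y2 contributes four segments.

The published totals are reproduced by `count_segments` with
`include_y=True` for seven of the eight maps; the CBR→RPU total (26) matches
only after dropping the Y-linked target chromosome (the enumerated signals
sum to 27), so the flag makes both conventions reachable and the fixture
table records which one reproduces each printed number.

Association characters are *pairwise adjacencies*, canonicalised by
lexicographic sort of the two labels (which reproduces the field's notation:
"13/4", "2/Y2").  A maximal run like TNI 11 = PHA 12/15/14 therefore yields
the pairs 12/15 and 14/15.

## Transitive composition

Two maps sharing a reference genome (here GSO) are composed by laying each
map's blocks onto the unit interval of every reference chromosome —
proportionally to relative block length, with the arm boundary as a hard
breakpoint when a map is arm-resolved — and emitting every pair of painted
blocks whose intervals overlap.  Without physical coordinates this is an
ordinal interleaving: equal lengths are assumed where no lengths are given,
which is exact whenever one side covers a chromosome (or arm) with a single
block, the situation in all worked cases (e.g. PHA 9 ↔ HSA 18+20 on GSO 10,
PHA 3q ↔ HSA 5+7+16 on GSO 4q).  The human→GSO fixture is a synthetic
stand-in assembled from correspondences stated in text, with unscored
regions encoded as unpainted; it is labelled synthetic in its filename and
header.

## Character matrices

Cells are 0, 1 or missing; missing is a distinct state that contributes the
full state set {0,1} at the leaf under parsimony (absence of signal is not
evidence of absence).  Three character kinds are derived automatically from
maps — pairwise associations, and per probe chromosome a whole-chromosome
("intact") synteny character scored 1 when the probe paints exactly one
contiguous signal — while inversion and arm-state characters enter as a
curated supplement, because a signal list alone cannot reveal them.
Constant characters are retained and flagged rather than dropped.  I/O
covers a NEXUS DATA block (STANDARD, SYMBOLS="01", MISSING=-; a `?` missing
symbol is available for readers that reserve `-` for gaps), relaxed PHYLIP,
and a labelled TSV that preserves character labels.

The six-taxon *real track* matrix derives entirely from the transcribed
maps: the PHA probe set scores PHA, RPU, RFI, TNI, GSO and the CBR set
scores CBR, RPU, RFI, TNI, GSO (each probe species enters its own set as an
identity map); concatenation fills the off-set cells with missing.  Labels
are namespaced by probe set ("PHA 12/15", "CBR 2/Y2").

## Maximum parsimony

Fitch (unordered) parsimony on binary characters.  Characters are packed
into two big-integer bitmasks per node — bit *i* of `A` set when character
*i*'s state set contains 0, of `B` when it contains 1 — so one Fitch combine
for the whole matrix is a handful of bigint operations and the union count a
popcount.  Scoring roots the unrooted tree on the edge of the smallest leaf;
the score is rooting-invariant (tested).

Searches:

* **exhaustive** — every unrooted binary topology, for ≤9 taxa;
* **branch and bound** — stepwise addition in a max–mini order (start from
  the most different taxon pair, then greedily add the taxon whose best
  placement lengthens the tree most).  Partial-tree length is monotone under
  leaf addition, so partials longer than the incumbent are pruned; with
  tree collection on, equal-length partials are kept, making the returned
  optimal set provably complete.  Both 14-taxon matrices in this repository
  solve exactly in under a second;
* **TBR hill-climbing** — random-addition starting trees from a seeded
  generator, tree-bisection-reconnection sweeps visiting candidate edges in
  canonical sorted order, first-improvement acceptance, plus an equal-length
  plateau walk (bounded) so ties at the optimum are collected.
  Deterministic given the seed; the tree set is not guaranteed exhaustive.

Homoplasy indices use the classical definitions: CI = Σm/Σs, RI =
(Σg − Σs)/(Σg − Σm), HI = 1 − CI, with m = 1 for a variable binary
character (0 for constant), s its steps on the reported tree, and g the
smaller of its two state counts over non-missing leaves.  For binary
characters Σm equals the variable-character count, so CI =
(variable characters)/(tree length) is an exact identity, asserted to
machine precision.  RI is reported as undefined when Σg = Σm.  Constant
characters are included; they contribute zero to every sum.

**Bootstrap**: characters are resampled with replacement at the original
width; each replicate is re-searched (exhaustively for ≤7 taxa, TBR without
a plateau walk otherwise) and contributes the bipartitions in the strict
consensus of its optimal trees; supports are percentages over replicates and
the consensus tree keeps bipartitions above 50%.  Defaults: 1000 replicates
for the six-taxon track, 200 with two starts per replicate for the
fourteen-taxon track — the problem sizes used throughout this repository's
analyses and reports.

## Ancestral states and branch signatures

On the tree rooted with PHA sister to everything else, per-character
most-parsimonious state sets come from a unit-cost Sankoff pass (subtree
costs down, outside costs up); a node's set holds every state used by at
least one most-parsimonious reconstruction (MPR), and two-state sets flag
ambiguity.  Character changes are placed on branches under three modes:
ACCTRAN and DELTRAN pick the concrete MPR that accelerates changes toward
the root or delays them toward the tips (implemented as the corresponding
local tie-break in a top-down assignment); the default `ambiguous` mode
reports the DELTRAN placement and flags every change whose branch is not
fixed across MPRs, listing the alternative branches.  In all three modes the
number of change records equals the tree length (tested).  Gains and losses
are polarised by the outgroup's state at the root.

## Karyotype simulator

A chromosome is an ordered list of oriented blocks (fragments of ancestral
chromosome arms with relative lengths) plus a centromere position.  Four
event classes: Robertsonian fusion (two whole chromosomes joined at a
centromere; visible as a new association), tandem fusion (concatenation onto
an arm terminus; also an association), fission (break at the centromere, or
at a block boundary/random point when the centromere is terminal; visible as
a lost association or broken synteny), and pericentric inversion
(breakpoints drawn uniformly on each side of the centromere; the reversed
span may split signals, producing interleaved patterns like 2/Y2/2/Y2).
Event counts per branch are Poisson with mean rate × branch length; default
rates (events per unit branch length) are fusion 0.4, fission 0.2, inversion
0.25, tandem fusion 0.15 — totalling 1.0, i.e. one expected event per
unit-length branch, fusion-biased as in the karyotypically reducing lineages
the model emulates.  Arm content is conserved by construction (tested), the
event log replays deterministically, and equal seeds give identical output.

Inversions are not deducible from signal lists, so each deposits a heritable
mark on the blocks it touched, and tips expose their marks as the curated
inversion supplement — mimicking scoring from banding.  Marks are named by
the ancestral chromosome at the centromere *plus the breakpoints*:
independent inversions of one chromosome are cytologically distinguishable
and must not collapse into a single character.  Fusions and fissions, by
contrast, can and do converge on identical characters (two lineages fusing
the same pair), so Robertsonian homoplasy is present in the simulation
exactly as it is in real karyotype data.

What the simulator does **not** emulate: heterochromatin accretion and
unpainted blocks, whole-arm translocations, chromosome-size constraints on
observability, and meiotic-drive biases in fixation.  Passing recovery tests
therefore show that the coding-and-inference chain is sound under clean
painting data, not that real heterochromatin-rich karyotypes are equally
tractable.

## The fourteen-taxon stand-in matrix

The full analysis rests on a 14 × 93 supplementary matrix that is not
printed in the study text, so it cannot be transcribed.  The *synthetic
track* therefore analyses a simulator-generated stand-in: karyotype
evolution along the published topology (PHA outgroup, TNI+CBR sister,
Stenodermatinae with Vampyressina nested) from a PHA-like ancestor of 16
chromosomes, with branch lengths chosen once as karyotype-divergence proxies
(short for the near-ancestral RPU/GSO/TNI, long for the heavily reshuffled
MMA/VTH) and the event-rate scale calibrated once so the matrix width (84
characters, 81 variable) is near the reported 93.  The construction seed is
a fixed constant.  The stand-in reproduces the *shape* of the analysis; its
tree statistics (length 89, CI 0.91, RI 0.85, 54 optimal trees) are free
outputs and differ from the reported ones, as expected for a stand-in — the
summary report prints both side by side.

## Recovery experiment

One hundred replicates on a fixed ten-taxon tree with unit branch lengths
(one expected event per branch), ancestor of 16 chromosomes; the ancestor
itself joins the matrix as the outgroup row.  Definitions:

* *topology recovered* — the generating topology is among the equally
  parsimonious optimal trees, equivalently its score equals the exact
  optimum (branch and bound seeded with the true tree's score as the upper
  bound).  With many branches expected to receive no event, the optimal set
  is routinely large and the generating tree is recovered in ~91% of
  replicates; the shortfall from certainty is convergent fusion/fission
  homoplasy (every observed failure is exactly one step short).
* *event recovered* — some character effect of the logged event changes
  state on the true branch in the signature report (ambiguous placements
  count when the true branch is listed).  ~96% of logged events are
  recovered; the remainder cancel within a branch or convergently duplicate
  another event's character.

## Numerical and design choices

* Missing cells are `-1` internally, written `-` (or `?`), never conflated
  with 0.
* Association labels sort lexicographically; taxa sort alphabetically in
  derived matrices; searches are deterministic given their seed.
* Tree counting uses bipartition-set identity on fully resolved unrooted
  topologies; zero-length branches are not collapsed before counting.
* Composition uses an interval-overlap tolerance of 1e-9 so abutting blocks
  do not register as overlapping.
* The ≤16-taxon branch-and-bound guard reflects where exhaustive pruning
  stays practical for matrices of this kind; beyond it the TBR heuristic is
  the intended tool.

## Known limitations

Binary (not multistate) coding; no rearrangement-distance models (DCJ,
breakpoint graphs); composition is ordinal, not physical; the arm-resolved
PHA→GSO and human→GSO fixtures are reconstructions from stated
correspondences, adequate for the qualitative composition checks only; and
the synthetic track stands in for, and does not reproduce, the unpublished
supplementary matrix.
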