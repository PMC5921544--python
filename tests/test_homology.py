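"""Homology maps: parsing, segment counts, associations, composition."""

import pytest

from paintphylo import fixtures
from paintphylo.homology import (
    HomologyMap,
    HomologyMapError,
    SignalBlock,
    adjacent_pairs,
    canonical_pair,
    compose_maps,
    count_segments,
    detect_associations,
    identity_map,
    parse_homology_map,
    write_homology_map,
)

from conftest import toy_map


class TestParsing:
    def test_round_trip(self, tmp_path):
        original = fixtures.load_map("CBR", "RFI")
        p = tmp_path / "m.tsv"
        write_homology_map(original, p)
        again = parse_homology_map(p)
        assert again.probe_species == original.probe_species
        assert again.signals.keys() == original.signals.keys()
        for chrom in original.signals:
            assert [
                (b.probe_chromosome, b.painted) for b in again.signals[chrom]
            ] == [(b.probe_chromosome, b.painted) for b in original.signals[chrom]]

    def test_split_synteny_signals_preserved(self):
        # one probe chromosome hybridising twice: on its own homologue and on
        # the long arm of another chromosome
        m = fixtures.load_map("PHA", "RPU")
        where = [
            (chrom, b.target_arm)
            for chrom, blocks in m.signals.items()
            for b in blocks
            if b.painted and b.probe_chromosome == "13"
        ]
        assert sorted(where) == [("13", None), ("15", "q")]

    def test_heterochromatic_block_retained_but_unpainted(self):
        m = fixtures.load_map("CBR", "RFI")
        blocks = m.signals["16"]
        assert [b.painted for b in blocks] == [True, False]
        assert blocks[1].target_arm == "q"

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("#probe=A\n#target=B\n1\t0\tx\n")
        with pytest.raises(HomologyMapError, match="bad.tsv:3"):
            parse_homology_map(p)

    def test_duplicate_position_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("#probe=A\n#target=B\n1\t0\tx\t1\n1\t0\ty\t1\n")
        with pytest.raises(HomologyMapError, match="duplicate"):
            parse_homology_map(p)

    def test_empty_signal_section_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("#probe=A\n#target=B\n")
        with pytest.raises(HomologyMapError, match="no signal rows"):
            parse_homology_map(p)

    def test_painted_row_without_label_rejected(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("#probe=A\n#target=B\n1\t0\t.\t1\n")
        with pytest.raises(HomologyMapError):
            parse_homology_map(p)


class TestSegmentCounts:
    @pytest.mark.parametrize(
        "probe,target", sorted(fixtures.PRINTED_SEGMENT_COUNTS)
    )
    def test_printed_totals(self, probe, target):
        printed, use_y = fixtures.PRINTED_SEGMENT_COUNTS[(probe, target)]
        m = fixtures.load_map(probe, target)
        assert count_segments(m, include_y=use_y) == printed

    def test_one_signal_per_probe_counts_n(self):
        m = toy_map("A", "B", {str(i): [str(i)] for i in range(1, 8)})
        assert count_segments(m) == 7

    def test_interleaved_signals_count_separately(self):
        # a chromosome painted 2/Y2/2/Y2 carries four segments
        m = fixtures.load_map("CBR", "RPU")
        assert sum(b.painted for b in m.signals["2"]) == 4

    def test_invariant_under_target_relabeling(self):
        m = fixtures.load_map("PHA", "TNI")
        relabeled = HomologyMap(m.probe_species, m.target_species)
        for i, (chrom, blocks) in enumerate(m.signals.items()):
            relabeled.signals[f"chr{i}"] = blocks
        assert count_segments(relabeled) == count_segments(m)


class TestAssociations:
    def test_pair_on_one_chromosome(self):
        m = fixtures.load_map("PHA", "GSO")
        assocs = {
            a.target_chromosome: a.members for a in detect_associations(m)
        }
        assert assocs["12"] == ("15", "12")

    def test_single_signal_gives_no_association(self):
        m = toy_map("A", "B", {"1": ["5"]})
        assert detect_associations(m) == []

    def test_three_probe_run_and_its_pairs(self):
        m = fixtures.load_map("PHA", "TNI")
        (run,) = [a for a in detect_associations(m) if a.target_chromosome == "11"]
        assert run.members == ("12", "15", "14")
        assert run.pairs() == ["12/15", "14/15"]

    def test_heterochromatin_breaks_adjacency(self):
        m = toy_map("A", "B", {"1": ["3", ".", "7"]})
        assert detect_associations(m) == []

    def test_pairs_invariant_under_signal_reversal(self):
        for key in fixtures.PRINTED_SEGMENT_COUNTS:
            m = fixtures.load_map(*key)
            rev = HomologyMap(m.probe_species, m.target_species)
            for chrom, blocks in m.signals.items():
                rev.signals[chrom] = [
                    SignalBlock(b.probe_chromosome, i, b.painted, b.length)
                    for i, b in enumerate(reversed(blocks))
                ]
            assert adjacent_pairs(rev) == adjacent_pairs(m)

    def test_canonical_pair_is_lexicographic(self):
        assert canonical_pair("15", "12") == "12/15"
        assert canonical_pair("4", "13") == "13/4"
        assert canonical_pair("2", "Y2") == "2/Y2"


class TestComposition:
    def test_identity_returns_original_labeling(self):
        ab = fixtures.load_map("PHA", "GSO")
        ident = identity_map("GSO", ab.signals.keys())
        corr = compose_maps(ab, ident)
        for a_label, targets in corr.items():
            painted_on = {
                chrom
                for chrom, blocks in ab.signals.items()
                for b in blocks
                if b.painted and b.probe_chromosome == a_label
            }
            assert targets == painted_on

    def test_single_block_overlaps_every_partition(self):
        ab = toy_map("A", "R", {"5": ["1"]})
        cb = toy_map("C", "R", {"5": ["2", "7"]})
        assert compose_maps(ab, cb) == {"1": {"2", "7"}}

    def test_symmetric_up_to_role_swap(self):
        ab = fixtures.load_map("PHA", "GSO")
        cb = fixtures.load_map("CBR", "GSO")
        fwd = compose_maps(ab, cb)
        rev = compose_maps(cb, ab)
        pairs_fwd = {(a, c) for a, cs in fwd.items() for c in cs}
        pairs_rev = {(a, c) for c, as_ in rev.items() for a in as_}
        assert pairs_fwd == pairs_rev

    def test_reference_mismatch_rejected(self):
        ab = fixtures.load_map("PHA", "GSO")
        cb = fixtures.load_map("CBR", "TNI")
        with pytest.raises(HomologyMapError, match="reference mismatch"):
            compose_maps(ab, cb)

    def test_unpainted_blocks_never_enter_correspondences(self):
        ab = toy_map("A", "R", {"1": ["9"]})
        cb = toy_map("C", "R", {"1": [".", "3"]})
        assert compose_maps(ab, cb) == {"9": {"3"}}


def test_completeness_flag_ignores_y():
    from paintphylo.homology import Karyotype

    kt = Karyotype("A", 6, 10, (("1", True, True), ("2", True, True), ("Y", False, True)))
    m = toy_map("A", "B", {"1": ["1"], "2": ["2"]})
    assert m.is_complete(kt)
    m2 = toy_map("A", "B", {"1": ["1"]})
    assert not m2.is_complete(kt)
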