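"""SAM reading, duplicate collapsing, marker extraction and adapter trimming."""

import numpy as np
import pysam
import pytest

from clipcall import alignment_io as aio
from tests import oracles
from tests.conftest import HEADER, make_read


class TestMutationSpec:
    def test_empty_kinds_rejected(self):
        with pytest.raises(aio.ConfigurationError):
            aio.MutationSpec(kinds=frozenset())

    def test_unknown_kind_rejected(self):
        with pytest.raises(aio.ConfigurationError, match="unknown"):
            aio.MutationSpec(kinds=frozenset({"inversion"}))

    def test_pairs_require_substitution_kind(self):
        with pytest.raises(aio.ConfigurationError):
            aio.MutationSpec(
                kinds=frozenset({"deletion"}),
                substitution_pairs=frozenset({("T", "C")}),
            )

    def test_combined_kinds_allowed(self):
        spec = aio.MutationSpec(kinds=frozenset({"deletion", "insertion"}))
        assert spec.kinds == {"deletion", "insertion"}


class TestExtractMarkerMutations:
    DEL_SPEC = aio.MutationSpec(kinds=frozenset({"deletion"}))

    def test_single_deletion_position(self):
        read = make_read("r1", start=100, cigar="10M1D10M")
        assert aio.extract_marker_mutations(read, self.DEL_SPEC) == [
            (110, "deletion")
        ]

    def test_multi_base_deletion_reports_every_base(self):
        read = make_read("r1", start=50, cigar="5M3D5M")
        positions = [p for p, _ in aio.extract_marker_mutations(read, self.DEL_SPEC)]
        assert positions == [55, 56, 57]

    def test_perfect_match_read_has_no_events(self):
        read = make_read("r1", cigar="30M")
        assert aio.extract_marker_mutations(read, self.DEL_SPEC) == []

    def test_insertion_anchored_to_left_base(self):
        spec = aio.MutationSpec(kinds=frozenset({"insertion"}))
        read = make_read("r1", start=100, cigar="10M2I10M")
        assert aio.extract_marker_mutations(read, spec) == [(109, "insertion")]

    @pytest.mark.parametrize("seed", range(10))
    def test_deletions_match_independent_cigar_interpreter(self, seed):
        """Random CIGARs: D-consumed positions agree with a direct walk."""
        rng = np.random.default_rng(seed)
        ops = []
        for _ in range(rng.integers(3, 8)):
            op = rng.choice(["M", "D", "I"])
            ops.append((op, int(rng.integers(1, 6))))
        # legal CIGAR: start/end with M, no adjacent non-M
        cleaned = [("M", 5)]
        for op, ln in ops:
            if op != "M" and cleaned[-1][0] != "M":
                cleaned.append(("M", 3))
            cleaned.append((op, ln))
        if cleaned[-1][0] != "M":
            cleaned.append(("M", 5))
        cigar = "".join(f"{ln}{op}" for op, ln in cleaned)
        read = make_read("r1", start=200, cigar=cigar)
        got = [p for p, k in aio.extract_marker_mutations(read, self.DEL_SPEC)]
        assert got == oracles.cigar_deletion_positions(200, cleaned)

    def test_parclip_substitution_plus_strand(self):
        spec = aio.MutationSpec(
            kinds=frozenset({"substitution"}),
            substitution_pairs=frozenset({("T", "C")}),
        )
        # ref TTTT, read TCTT -> T->C at offset 1
        read = make_read("r1", start=100, cigar="4M", seq="TCTT", md="1T2")
        assert aio.extract_marker_mutations(read, spec) == [(101, "substitution")]

    def test_minus_strand_substitution_reverse_complements_pair(self):
        """Genomic A->G on a minus-strand read counts as transcript T->C."""
        spec = aio.MutationSpec(
            kinds=frozenset({"substitution"}),
            substitution_pairs=frozenset({("T", "C")}),
            strand_aware=True,
        )
        read = make_read("r1", start=100, cigar="4M", strand="-", seq="AGAA", md="1A2")
        assert aio.extract_marker_mutations(read, spec) == [(101, "substitution")]
        # the same genomic event on a plus-strand read is NOT a T->C marker
        read_plus = make_read("r2", start=100, cigar="4M", seq="AGAA", md="1A2")
        assert aio.extract_marker_mutations(read_plus, spec) == []

    def test_substitution_without_md_is_configuration_error(self):
        spec = aio.MutationSpec(kinds=frozenset({"substitution"}))
        read = make_read("r1", cigar="30M")
        with pytest.raises(aio.ConfigurationError, match="MD"):
            aio.extract_marker_mutations(read, spec)


class TestCollapseDuplicates:
    def test_identical_coordinates_collapse_with_multiplicity(self):
        recs = [
            aio.ReadRecord("chr1", "+", 100, 130) for _ in range(3)
        ]
        tags = aio.collapse_duplicates(recs)
        assert len(tags) == 1 and tags[0].multiplicity == 3

    def test_strand_separates_duplicates(self):
        recs = [
            aio.ReadRecord("chr1", "+", 100, 130),
            aio.ReadRecord("chr1", "-", 100, 130),
        ]
        assert len(aio.collapse_duplicates(recs)) == 2

    def test_empty_input(self):
        assert aio.collapse_duplicates([]) == []

    def test_mutations_unioned_once_per_position(self):
        recs = [
            aio.ReadRecord("chr1", "+", 100, 130, ((110, "deletion"),)),
            aio.ReadRecord("chr1", "+", 100, 130, ((110, "deletion"), (112, "deletion"))),
        ]
        (tag,) = aio.collapse_duplicates(recs)
        assert tag.mutations == [(110, "deletion"), (112, "deletion")]

    def test_multiplicity_sum_equals_retained_records(self, rng):
        recs = [
            aio.ReadRecord("chr1", "+", int(s), int(s) + 30)
            for s in rng.integers(0, 50, size=200)
        ]
        tags = aio.collapse_duplicates(recs)
        assert sum(t.multiplicity for t in tags) == 200


class TestSamReading:
    def test_secondary_and_unmapped_skipped(self, sam_factory):
        reads = [
            make_read("r1", start=100),
            make_read("r2", start=100, flag_extra=256),  # secondary
            make_read("r3", start=100, flag_extra=2048),  # supplementary
        ]
        spec = aio.MutationSpec(kinds=frozenset({"deletion"}))
        tags = aio.read_tags(sam_factory(reads), spec)
        assert len(tags) == 1 and tags[0].multiplicity == 1

    def test_paired_end_collapses_on_fragment_interval(self, sam_factory):
        spec = aio.MutationSpec(kinds=frozenset({"deletion"}))
        r1 = make_read("p1", start=100, cigar="30M")
        r1.flag |= 1 | 2 | 64 | 32  # paired, proper, read1, mate reverse
        r1.next_reference_id = 0
        r1.next_reference_start = 150
        r1.template_length = 80
        r2 = make_read("p1", start=150, cigar="30M", strand="-")
        r2.flag |= 1 | 2 | 128
        r2.next_reference_id = 0
        r2.next_reference_start = 100
        r2.template_length = -80
        tags = aio.read_tags(sam_factory([r1, r2]), spec)
        assert len(tags) == 1
        assert (tags[0].start, tags[0].end) == (100, 180)
        assert tags[0].strand == "+"


class TestBedRoundTrip:
    def test_coordinates_survive_round_trip(self, tmp_path, rng):
        tags = aio.collapse_duplicates(
            aio.ReadRecord("chr%d" % rng.integers(1, 3), "+-"[rng.integers(2)],
                           int(s), int(s) + int(rng.integers(20, 40)))
            for s in rng.integers(0, 1000, size=100)
        )
        path = tmp_path / "tags.bed"
        aio.write_tags_bed(tags, path)
        back = aio.read_tags_bed(path)
        assert [(t.chrom, t.strand, t.start, t.end) for t in back] == [
            (t.chrom, t.strand, t.start, t.end) for t in tags
        ]


class TestTrimAdapter:
    def test_exact_adapter_suffix_removed(self):
        recs = [("r1", "ACGTACGTTTTT", "IIIIIIIIIIII")]
        out = list(aio.trim_adapter(recs, "TTTT", min_overlap=4, min_length=4))
        assert out == [("r1", "ACGTACGT", "IIIIIIII")]

    def test_read_without_adapter_unchanged(self):
        recs = [("r1", "ACGTACGT", "IIIIIIII")]
        out = list(aio.trim_adapter(recs, "GGGG", min_overlap=4, min_length=4))
        assert out == [("r1", "ACGTACGT", "IIIIIIII")]

    def test_read_equal_to_adapter_dropped(self):
        recs = [("r1", "TTTT", "IIII")]
        assert list(aio.trim_adapter(recs, "TTTT", min_overlap=4, min_length=1)) == []

    def test_partial_suffix_overlap_requires_min_overlap(self):
        recs = [("r1", "ACGTACGGTT", "IIIIIIIIII")]
        kept = list(aio.trim_adapter(recs, "TTTT", min_overlap=3, min_length=4))
        assert kept == [("r1", "ACGTACGGTT", "IIIIIIIIII")]  # only 2-base overlap
        trimmed = list(aio.trim_adapter(recs, "TTTT", min_overlap=2, min_length=4))
        assert trimmed == [("r1", "ACGTACGG", "IIIIIIII")]

    def test_internal_adapter_trims_trailing_sequence(self):
        recs = [("r1", "ACGTTTTTGGCC", "IIIIIIIIIIII")]
        out = list(aio.trim_adapter(recs, "TTTTT", min_overlap=4, min_length=3))
        assert out == [("r1", "ACG", "III")]

    def test_malformed_record_names_index(self):
        recs = [("r1", "ACGT", "IIII"), ("r2", "ACGT", "III")]
        with pytest.raises(aio.FastqParseError, match="record 1"):
            list(aio.trim_adapter(recs, "TTTT"))

    def test_fastq_file_round_trip(self, tmp_path):
        src = tmp_path / "in.fastq"
        src.write_text("@r1\nACGTACGTTTTT\n+\nIIIIIIIIIIII\n@r2\nTTTT\n+\nIIII\n")
        dst = tmp_path / "out.fastq"
        n = aio.trim_fastq_file(src, dst, "TTTT", min_overlap=4, min_length=5)
        assert n == 1
        assert dst.read_text() == "@r1\nACGTACGT\n+\nIIIIIIII\n"
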