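"""Microhomology-aware breakpoint calling, junction sequences, VCF I/O."""

import dataclasses

import pytest

import clipinv as ci
from clipinv.calling import JunctionConflictError, SupportCounts

rc = ci.reverse_complement


@pytest.fixture(scope="module")
def published_call(fixture_pipeline):
    result, _ = fixture_pipeline
    return result


class TestCallInversion:
    def test_breakpoint_left_coordinates_match_publication(self, published_call):
        call = published_call.call
        assert call.bp_a.start == 27_762_423
        assert call.bp_b.start == 93_599_530

    def test_two_base_duplicated_homology(self, published_call):
        call = published_call.call
        assert call.homology_seq == "AT"
        assert call.homology_len == 2
        # interval width equals homology length on both sides
        assert call.bp_a.end - call.bp_a.start == 2
        assert call.bp_b.end - call.bp_b.start == 2

    def test_support_counts(self, published_call):
        call = published_call.call
        assert call.support == SupportCounts(
            discordant_pairs=4, split_reads_junction1=2, split_reads_junction2=4
        )
        assert not call.low_confidence

    def test_interval_equals_placement_enumeration_oracle(
        self, fixture_set, segments, published_call
    ):
        """Brute force: enumerate every junction placement (x, C - x) and
        keep those whose derivative junction sequence reproduces all six
        reads exactly; the surviving x must be exactly the called interval."""
        seg_a, seg_b = segments
        call = published_call.call
        C = call.bp_a.start + call.bp_b.end  # slide-invariant coordinate sum
        reads = [r.seq for r in fixture_set.table2_reads]
        valid = []
        for x in range(seg_a.offset + 1, seg_a.end + 1):
            y = C - x
            if not seg_b.offset <= y <= seg_b.end:
                continue
            junction = seg_a.slice(seg_a.offset, x) + rc(seg_b.slice(seg_b.offset, y))
            if all(r in junction or rc(r) in junction for r in reads):
                valid.append(x)
        assert valid == list(range(call.bp_a.start, call.bp_a.end + 1))

    def test_single_orientation_gives_low_confidence_point_call(
        self, published_call, segments
    ):
        seg_a, seg_b = segments
        one_sided = [
            j for j in published_call.junctions if j.aln_interval.start > 90_000_000
        ]
        call = ci.call_inversion(one_sided, [], seg_a, seg_b)
        assert call.low_confidence
        assert call.bp_a.start == call.bp_a.end == 27_762_423
        assert call.homology_seq == ""

    def test_inconsistent_junction_raises_naming_offender(
        self, published_call, segments
    ):
        seg_a, seg_b = segments
        junctions = list(published_call.junctions)
        bad = dataclasses.replace(
            junctions[0],
            sc_read_start=junctions[0].sc_read_start - 7,
            sc_read_end=junctions[0].sc_read_end - 7,
            sc_interval=ci.GenomicInterval(
                junctions[0].sc_interval.chrom,
                junctions[0].sc_interval.start - 7,
                junctions[0].sc_interval.end - 7,
            ),
        )
        junctions[0] = bad
        with pytest.raises(JunctionConflictError, match=bad.read_id):
            ci.call_inversion(junctions, [], seg_a, seg_b)


class TestJunctionSequences:
    def test_junction1_contains_each_published_read(self, published_call, segments):
        """Every breakpoint-spanning read (in one orientation or the other)
        must be a substring of the reconstructed lower-locus junction."""
        seg_a, seg_b = segments
        call = published_call.call
        j1, _ = ci.junction_sequences(call, seg_a, seg_b, flank=127)
        assert j1[125:127] == "AT"  # duplicated bases end the left flank
        reads = [r.seq for r in ci.load_fixtures().table2_reads]
        for r in reads:
            assert r in j1 or rc(r) in j1

    def test_duplicated_bases_appear_in_both_junctions(self, published_call, segments):
        seg_a, seg_b = segments
        call = published_call.call
        j1, j2 = ci.junction_sequences(call, seg_a, seg_b, flank=20)
        # side-A copy ends junction 1's left flank
        assert j1[18:20] == "AT"
        # the evidence segments stop at the junction, so the reciprocal
        # junction truncates to exactly the side-B copy of the duplication
        assert j2 == "AT"

    def test_assignment_flip_shifts_frame_but_not_sequence(
        self, published_call, segments
    ):
        seg_a, seg_b = segments
        call_a = published_call.call
        call_b = dataclasses.replace(call_a, homology_assignment="side_b")
        j1a, _ = ci.junction_sequences(call_a, seg_a, seg_b, flank=30)
        j1b, _ = ci.junction_sequences(call_b, seg_a, seg_b, flank=30)
        assert j1b[call_a.homology_len :] == j1a[: -call_a.homology_len]

    def test_zero_homology_length_is_twice_flank(self, sim_default):
        ds, result, _ = sim_default
        # build a blunt-junction call on synthetic segments
        seg_a = ci.ReferenceSegment("sim1", 49_000, ds.reference[48_999:51_000])
        seg_b = ci.ReferenceSegment("sim1", 149_000, ds.reference[148_999:151_000])
        call = dataclasses.replace(
            result.call,
            bp_a=ci.GenomicInterval("sim1", 50_000, 50_000),
            bp_b=ci.GenomicInterval("sim1", 150_000, 150_000),
            homology_seq="",
        )
        j1, j2 = ci.junction_sequences(call, seg_a, seg_b, flank=40)
        assert len(j1) == len(j2) == 80


class TestVcf:
    def test_info_fields(self, published_call, fixture_pipeline):
        _, cfg = fixture_pipeline
        doc = ci.write_vcf(published_call.call, "proband")
        body = [l for l in doc.splitlines() if not l.startswith("#")]
        assert len(body) == 1
        fields = body[0].split("\t")
        assert fields[0:2] == ["chr7", "27762423"]
        info = dict(
            kv.split("=", 1) if "=" in kv else (kv, True)
            for kv in fields[7].split(";")
        )
        assert info["SVTYPE"] == "INV"
        assert info["END"] == "93599532"
        assert info["HOMLEN"] == "2" and info["HOMSEQ"] == "AT"
        assert info["CIPOS"] == "0,2" and info["CIEND"] == "-2,0"
        assert (info["PE"], info["SR1"], info["SR2"]) == ("4", "2", "4")
        assert fields[9] == "./."  # genotype never inferred, only asserted

    def test_zero_homology_cipos(self, published_call):
        blunt = dataclasses.replace(
            published_call.call,
            bp_a=ci.GenomicInterval("chr7", 100, 100),
            bp_b=ci.GenomicInterval("chr7", 900, 900),
            homology_seq="",
        )
        doc = ci.write_vcf(blunt, "s")
        assert "CIPOS=0,0" in doc and "CIEND=-0,0" in doc

    def test_round_trip_through_reader(self, published_call, tmp_path):
        call = published_call.call
        path = tmp_path / "call.vcf"
        path.write_text(ci.write_vcf(call, "proband", genotype="1/1"))
        back = ci.read_vcf(path)
        assert back.bp_a == call.bp_a
        assert back.bp_b == call.bp_b
        assert back.homology_seq == call.homology_seq
        assert back.support == call.support
        assert back.low_confidence == call.low_confidence

    def test_no_call_document_round_trips_empty(self, tmp_path):
        path = tmp_path / "none.vcf"
        path.write_text(ci.write_vcf(None, "s"))
        assert ci.read_vcf(path) is None

    def test_bnd_records_optional(self, published_call):
        doc = ci.write_vcf(published_call.call, "s", include_bnd=True)
        body = [l for l in doc.splitlines() if not l.startswith("#")]
        assert len(body) == 3
        assert "]chr7:93599530]" in body[1]


class TestRegionSpan:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (20_900_001, 28_800_000, 7_900_000),
            (77_500_001, 98_000_000, 20_500_000),
            (5, 5, 1),
        ],
    )
    def test_closed_interval_width(self, start, end, expected):
        assert ci.region_span(ci.GenomicInterval("chr7", start, end)) == expected
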