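"""Clip realignment: candidate collection, ungapped mapping, resolution,
and reconstruction of local reference segments from annotated reads."""

import dataclasses
import random

import numpy as np
import pytest

import clipinv as ci
from clipinv.splitread import (
    AmbiguousHit,
    ClipHit,
    NoHit,
    SegmentConflictError,
    SplitReadConfig,
    SplitReadJunction,
    map_clip,
    reconstruct_reference_segments,
)

RNG = random.Random(42)


def _random_seq(n, rng=RNG):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _oracle_map(clip, seg, max_mismatch):
    """Exhaustive both-strand all-offset scorer, vectorised with numpy —
    an independent optimum to compare the seed-and-extend path against."""
    t = np.frombuffer(seg.seq.encode(), dtype=np.uint8)
    best = []
    best_score = None
    for strand, q in (("+", clip), ("-", ci.reverse_complement(clip))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        if len(qa) > len(t):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(t, len(qa))
        mism = (windows != qa).sum(axis=1)
        scores = len(qa) - 2 * mism
        for off in range(len(scores)):
            s = int(scores[off])
            if best_score is None or s > best_score:
                best_score, best = s, [(off, strand, int(mism[off]))]
            elif s == best_score:
                best.append((off, strand, int(mism[off])))
    if best_score is None or best[0][2] > max_mismatch:
        return "no_hit", None
    if len(best) > 1:
        return "ambiguous", best
    off, strand, mism = best[0]
    return "hit", (seg.offset + off, strand, mism)


class TestMapClip:
    def test_published_read1_clip_maps_minus_onto_7p(self, fixture_set, segments):
        seg_a, _ = segments
        row = fixture_set.table2_reads[0]
        clip = row.seq[row.aln_len :]
        hit = map_clip(clip, seg_a)
        assert isinstance(hit, ClipHit)
        assert hit.strand == "-"
        assert (hit.read_start, hit.read_end) == (27_762_423, 27_762_351)
        assert hit.mismatches == 0

    def test_published_read3_clip_maps_minus_onto_7q(self, fixture_set, segments):
        _, seg_b = segments
        row = fixture_set.table2_reads[2]
        clip = row.seq[row.aln_len :]
        hit = map_clip(clip, seg_b)
        assert isinstance(hit, ClipHit)
        assert hit.strand == "-"
        assert (hit.read_start, hit.read_end) == (93_599_530, 93_599_466)

    def test_reverse_complemented_subsequence_found_at_planted_offset(self):
        seg = ci.ReferenceSegment("c", 501, _random_seq(400))
        clip = ci.reverse_complement(seg.seq[120:180])
        hit = map_clip(clip, seg)
        assert isinstance(hit, ClipHit)
        assert (hit.interval.start, hit.interval.end) == (621, 680)
        assert hit.strand == "-" and hit.mismatches == 0

    def test_random_clip_has_no_hit(self):
        seg = ci.ReferenceSegment("c", 1, _random_seq(500))
        assert isinstance(map_clip(_random_seq(60, random.Random(1)), seg), NoHit)

    def test_repeated_motif_is_ambiguous(self):
        unit = _random_seq(40, random.Random(2))
        seg = ci.ReferenceSegment("c", 1, unit + _random_seq(25, random.Random(3)) + unit)
        res = map_clip(unit[5:35], seg)
        assert isinstance(res, AmbiguousHit)
        assert len(res.hits) == 2

    def test_agrees_with_exhaustive_oracle(self):
        """500 random cases: planted hits (either strand, 0-4 mutations),
        decoys, and short targets must classify and place identically."""
        rng = random.Random(202)
        for case in range(500):
            tlen = rng.randrange(200, 2000)
            seg = ci.ReferenceSegment("c", rng.randrange(1, 10**6), _random_seq(tlen, rng))
            kind = case % 3
            if kind == 0:  # planted, possibly mutated, possibly revcomp
                n = rng.randrange(20, min(120, tlen))
                off = rng.randrange(0, tlen - n)
                clip = seg.seq[off : off + n]
                for _ in range(rng.randrange(0, 4)):
                    i = rng.randrange(n)
                    clip = clip[:i] + rng.choice("ACGT") + clip[i + 1 :]
                if rng.random() < 0.5:
                    clip = ci.reverse_complement(clip)
            else:  # unrelated sequence
                clip = _random_seq(rng.randrange(20, 120), rng)
            got = map_clip(clip, seg, max_mismatch=2)
            status, payload = _oracle_map(clip, seg, max_mismatch=2)
            if status == "no_hit":
                assert isinstance(got, NoHit), f"case {case}"
            elif status == "ambiguous":
                assert isinstance(got, AmbiguousHit), f"case {case}"
                assert len(got.hits) == len(payload)
            else:
                assert isinstance(got, ClipHit), f"case {case}"
                start, strand, mism = payload
                assert (got.interval.start, got.strand, got.mismatches) == (
                    start, strand, mism,
                ), f"case {case}"


class TestCandidates:
    def test_all_six_published_reads_are_candidates(self, fixture_sam, fixture_pipeline):
        result, _ = fixture_pipeline
        records = list(ci.read_sam(fixture_sam))
        cands = ci.collect_breakpoint_candidates(records, result.selected_cluster)
        assert len(cands) == 6
        assert all(any(op.op == "S" for op in r.cigar) for r in cands)

    def test_unclipped_read_in_window_excluded(self, fixture_pipeline):
        result, _ = fixture_pipeline
        rec = ci.make_record("m", "chr7", 27_762_200, "50M", seq="A" * 50)
        assert ci.collect_breakpoint_candidates([rec], result.selected_cluster) == []

    def test_min_clip_threshold(self, fixture_sam, fixture_pipeline):
        result, _ = fixture_pipeline
        records = list(ci.read_sam(fixture_sam))
        cands = ci.collect_breakpoint_candidates(
            records, result.selected_cluster, SplitReadConfig(min_clip=80)
        )
        # only the 50M125S read carries a clip of at least 80 nt
        assert [max(op.length for op in r.cigar if op.op == "S") for r in cands] == [125]


class TestResolve:
    @pytest.mark.parametrize("row_idx", range(6))
    def test_published_reads_reproduce_all_printed_values(
        self, fixture_set, segments, row_idx
    ):
        row = fixture_set.table2_reads[row_idx]
        seg_a, seg_b = segments
        rec = ci.make_record(
            row.read_id, row.chrom, row.aln_start,
            f"{row.aln_len}M{row.sc_len}S", seq=row.seq, mapq=60,
        )
        partner = seg_a if row.aln_start > 90_000_000 else seg_b
        j = ci.resolve_split_read(rec, partner)
        assert isinstance(j, SplitReadJunction)
        assert (j.aln_len, j.sc_len) == (row.aln_len, row.sc_len)
        assert (j.aln_interval.start, j.aln_interval.end) == (row.aln_start, row.aln_end)
        assert j.aln_strand == row.aln_strand
        assert (j.sc_read_start, j.sc_read_end) == (row.sc_start, row.sc_end)
        assert j.sc_strand == row.sc_strand
        assert j.mismatches == 0
        assert j.aln_len + j.sc_len == 175  # asymmetric long read, fully accounted

    def test_unmappable_clip_is_rejected_with_reason(self, segments):
        seg_a, _ = segments
        rec = ci.make_record(
            "noise", "chr7", 93_599_431, "102M73S",
            seq=_random_seq(102, random.Random(5)) + _random_seq(73, random.Random(6)),
        )
        rej = ci.resolve_split_read(rec, seg_a)
        assert rej.reason == "no_hit"

    def test_short_clip_rejected(self, segments):
        seg_a, _ = segments
        rec = ci.make_record("short", "chr7", 93_599_431, "165M10S", seq="A" * 175)
        assert ci.resolve_split_read(rec, seg_a).reason == "short_clip"


class TestReconstruction:
    def test_published_rows_assemble_both_localities(self, fixture_set):
        seg_a, seg_b = reconstruct_reference_segments(fixture_set.table2_reads)
        assert (seg_a.offset, seg_a.end) == (27_762_299, 27_762_425)
        assert len(seg_a.seq) == 127
        assert (seg_b.offset, seg_b.end) == (93_599_409, 93_599_532)
        assert len(seg_b.seq) == 124

    def test_single_row_segment_matches_its_aligned_part(self, fixture_set):
        row = fixture_set.table2_reads[0]
        low, high = reconstruct_reference_segments([row])
        # the aligned part sits on the higher-coordinate (7q) locality
        assert high.slice(row.aln_start, row.aln_end) == row.seq[: row.aln_len]
        assert low.interval.length == row.sc_len

    def test_conflicting_base_raises_with_coordinate(self, fixture_set):
        rows = list(fixture_set.table2_reads)
        bad_seq = "T" + rows[0].seq[1:] if rows[0].seq[0] != "T" else "A" + rows[0].seq[1:]
        rows[0] = dataclasses.replace(rows[0], seq=bad_seq)
        with pytest.raises(SegmentConflictError, match=r"93599431|93,599,431"):
            reconstruct_reference_segments(rows)
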