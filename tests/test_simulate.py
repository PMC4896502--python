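"""Synthetic-data generator: genome construction, inversion arithmetic,
read/truth-alignment consistency, and end-to-end recovery."""

import numpy as np
import pytest

import clipinv as ci
from clipinv.samio import QUERY_OPS

rc = ci.reverse_complement


def _cfg(**kw):
    return ci.SimulationConfig(**kw)


class TestGenome:
    def test_length_and_determinism(self):
        g1 = ci.make_genome(_cfg(seed=3))
        g2 = ci.make_genome(_cfg(seed=3))
        assert len(g1) == 200_000
        assert g1 == g2
        assert g1 != ci.make_genome(_cfg(seed=4))

    @pytest.mark.parametrize("h", [1, 2, 5])
    def test_planted_homology_is_reverse_complement_pair(self, h):
        cfg = _cfg(homology_len=h, seed=5)
        g = ci.make_genome(cfg)
        b1, b2 = cfg.breakpoints
        assert g[b1 : b1 + h] == rc(g[b2 : b2 + h])

    @pytest.mark.parametrize("h", [0, 2])
    def test_slide_run_is_exactly_homology_len(self, h):
        cfg = _cfg(homology_len=h, seed=6)
        g = ci.make_genome(cfg)
        b1, b2 = cfg.breakpoints
        comp = lambda x: rc(x)  # single base
        # one more slide in either direction must be blocked
        assert g[b1 + h] != comp(g[b2 - 1])
        assert g[b1 - 1] != comp(g[b2 + h])

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="centromere"):
            _cfg(bp1=150_000, bp2=160_000)


class TestInversion:
    def test_involution_and_length(self):
        cfg = _cfg(seed=7)
        ref = ci.make_genome(cfg)
        der = ci.apply_inversion(ref, cfg)
        assert len(der) == len(ref)
        assert der != ref
        assert ci.apply_inversion(der, cfg) == ref

    def test_junction_sequences_match_derived_allele(self):
        """Cross-module contract: flanks written by the caller's junction
        reconstruction must occur verbatim in the simulated derived allele."""
        cfg = _cfg(homology_len=2, seed=8)
        ref = ci.make_genome(cfg)
        der = ci.apply_inversion(ref, cfg)
        b1, b2 = cfg.breakpoints
        h = cfg.homology_len
        call = ci.InversionCall(
            bp_a=ci.GenomicInterval(cfg.chrom, b1, b1 + h),
            bp_b=ci.GenomicInterval(cfg.chrom, b2, b2 + h),
            homology_seq=ref[b1 : b1 + h],
            homology_assignment="side_a",
            support=ci.SupportCounts(0, 0, 0),
        )
        seg_a = ci.ReferenceSegment(cfg.chrom, b1 - 500, ref[b1 - 501 : b1 + 500])
        seg_b = ci.ReferenceSegment(cfg.chrom, b2 - 500, ref[b2 - 501 : b2 + 500])
        j1, j2 = ci.junction_sequences(call, seg_a, seg_b, flank=30)
        assert j1 in der[b1 - 100 : b1 + h + 100]
        assert j2 in der[b2 - 100 : b2 + h + 100]
        assert j1 not in ref and j2 not in ref


@pytest.fixture(scope="module")
def dataset():
    return ci.simulate(_cfg(seed=1))


class TestReads:
    def test_pair_count_matches_coverage(self, dataset):
        cfg = dataset.config
        expected = round(cfg.coverage * cfg.genome_length / 225)
        assert len(dataset.reads1) == len(dataset.reads2) == expected
        assert len(dataset.records) == 2 * expected

    def test_read_lengths_asymmetric(self, dataset):
        assert {len(r.seq) for r in dataset.reads1} == {175}
        assert {len(r.seq) for r in dataset.reads2} == {50}

    def test_truth_records_satisfy_model_invariants(self, dataset):
        for rec in dataset.records:
            if rec.cigar and rec.seq:
                consumed = sum(op.length for op in rec.cigar if op.op in QUERY_OPS)
                assert consumed == len(rec.seq)
            if not rec.read_unmapped:
                assert rec.pos >= 1 and rec.mapq == 60

    def test_error_free_aligned_bases_match_reference(self, dataset):
        ref = dataset.reference
        checked = 0
        for rec in dataset.records[:2000]:
            if rec.read_unmapped:
                continue
            span = ci.aligned_span(rec)
            left_clip = rec.cigar[0].length if rec.cigar[0].op == "S" else 0
            m = sum(op.length for op in rec.cigar if op.op == "M")
            assert rec.seq[left_clip : left_clip + m] == ref[span.start - 1 : span.end]
            checked += 1
        assert checked > 1000

    def test_mean_insert_within_three_se(self, dataset):
        cfg = dataset.config
        # reconstruct insert from the mapped geometry of each proper pair
        spans = []
        by_id = {}
        for rec in dataset.records:
            if not rec.read_unmapped:
                by_id.setdefault(rec.read_id, []).append(rec)
        for rid, recs in by_id.items():
            if len(recs) == 2 and recs[0].proper_pair:
                fwd = next(r for r in recs if r.strand == "+")
                rev = next(r for r in recs if r.strand == "-")
                spans.append(ci.aligned_span(rev).end - fwd.pos + 1)
        spans = np.array(spans)
        se = cfg.insert_sd / np.sqrt(len(spans))
        assert abs(spans.mean() - cfg.insert_mean) < 3 * se

    def test_het_mix_shows_both_alleles_at_junction(self):
        ds = ci.simulate(_cfg(seed=2, zygosity="het"))
        b1 = ds.config.breakpoints[0]
        clipped = ref_spanning = 0
        for rec in ds.records:
            if rec.read_unmapped:
                continue
            span = ci.aligned_span(rec)
            has_clip = any(op.op == "S" for op in rec.cigar)
            if has_clip and abs(span.end - b1) <= 200:
                clipped += 1  # derived-allele read broken at the junction
            if not has_clip and span.start <= b1 - 5 and span.end >= b1 + 5:
                ref_spanning += 1  # reference-allele read straddling it intact
        assert clipped > 0 and ref_spanning > 0

    def test_junction_pairs_are_same_strand_discordant(self, dataset, sim_default):
        _, result, _ = sim_default
        cluster = result.selected_cluster
        assert cluster.same_strand_fraction == 1.0
        assert all(s > 90_000 for s in cluster.apparent_insert_sizes)


class TestRecovery:
    def test_pipeline_recovers_planted_truth_at_defaults(self, sim_default):
        ds, result, _ = sim_default
        assert result.status == "full"
        call = result.call
        assert call.bp_a == ds.truth_bp_a
        assert call.bp_b == ds.truth_bp_b
        assert call.homology_seq == ds.truth_homology
        assert call.homology_len == 2

    def test_exactly_one_supported_cluster(self, sim_default):
        _, result, _ = sim_default
        supported = [c for c in result.clusters if c.support >= 2]
        assert len(supported) == 1

    def test_dataset_writers_round_trip(self, tmp_path):
        ds = ci.simulate(_cfg(genome_length=30_000, coverage=2, seed=9))
        sam = tmp_path / "truth.sam"
        ds.write_truth_sam(sam)
        back = list(ci.read_sam(sam))
        assert len(back) == len(ds.records)
        ds.write_fastq_pair(tmp_path / "reads")
        fq1 = (tmp_path / "reads_1.fastq").read_text().splitlines()
        assert len(fq1) == 4 * len(ds.reads1)
        assert set(fq1[3]) == {"I"}  # constant quality model
        ds.write_truth_json(tmp_path / "truth.json")
        assert '"homology": "' in (tmp_path / "truth.json").read_text()
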