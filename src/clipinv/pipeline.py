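"""End-to-end orchestration: scan -> resolve -> call, with reproducible reports.

The three stages communicate through plain data (clusters, junctions) and
their on-disk TSV mirrors, so each stage is independently runnable and
testable.  All output bodies are deterministic for identical inputs and
configuration; nothing timestamped is written outside human-readable text.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from . import __version__
from .calling import InversionCall, call_inversion, junction_sequences, write_vcf
from .discordant import (
    DiscordantPairCluster,
    ScanConfig,
    cluster_by_mate_proximity,
    cluster_table,
    extract_inter_region_pairs,
)
from .samio import AlignmentRecord, GenomicInterval, aligned_span, read_sam_document
from .splitread import (
    ReferenceSegment,
    SplitReadConfig,
    SplitReadJunction,
    SplitReadRejection,
    collect_breakpoint_candidates,
    junction_table,
    resolve_split_read,
    segment_from_fasta,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scan: ScanConfig
    split: SplitReadConfig = field(default_factory=SplitReadConfig)
    #: FASTA with the reference chromosome(s); segments are sliced around the
    #: selected cluster's spans.  Alternatively pre-built segments may be
    #: supplied directly (e.g. reconstructed from published evidence).
    reference_fasta: Optional[str] = None
    segments: Optional[tuple[ReferenceSegment, ReferenceSegment]] = None
    #: padding around cluster spans when slicing segments from FASTA; must
    #: exceed candidate flank + read length so clip placements stay inside.
    segment_pad: int = 3000
    min_support: int = 2
    sample_id: str = "sample"
    genotype: Optional[str] = None
    homology_assignment: str = "side_a"

    def __post_init__(self) -> None:
        if self.segment_pad < self.split.flank + 500:
            raise ValueError("segment_pad too small for the candidate flank")


@dataclass
class PipelineResult:
    status: str  # 'full' | 'partial' | 'none'
    clusters: list[DiscordantPairCluster]
    selected_cluster: Optional[DiscordantPairCluster]
    junctions: list[SplitReadJunction]
    rejections: list[SplitReadRejection]
    call: Optional[InversionCall]
    segments: Optional[tuple[ReferenceSegment, ReferenceSegment]]
    input_path: Optional[str] = None
    input_sha256: Optional[str] = None


def _segments_for_cluster(
    cfg: PipelineConfig, cluster: DiscordantPairCluster
) -> tuple[ReferenceSegment, ReferenceSegment]:
    if cfg.segments is not None:
        seg_a, seg_b = cfg.segments
    elif cfg.reference_fasta is not None:
        seg_a = segment_from_fasta(
            cfg.reference_fasta,
            cluster.span_a.chrom,
            cluster.span_a.start - cfg.segment_pad,
            cluster.span_a.end + cfg.segment_pad,
        )
        seg_b = segment_from_fasta(
            cfg.reference_fasta,
            cluster.span_b.chrom,
            cluster.span_b.start - cfg.segment_pad,
            cluster.span_b.end + cfg.segment_pad,
        )
    else:
        raise ValueError("pipeline needs reference_fasta or prebuilt segments")
    if seg_a.chrom == seg_b.chrom and seg_a.offset > seg_b.offset:
        seg_a, seg_b = seg_b, seg_a
    return seg_a, seg_b


def _partner_segment(
    rec: AlignmentRecord, seg_a: ReferenceSegment, seg_b: ReferenceSegment
) -> ReferenceSegment:
    """The clip of a read anchored near one locus belongs to the other."""
    span = aligned_span(rec)

    def dist(seg: ReferenceSegment) -> float:
        if span.chrom != seg.chrom:
            return float("inf")
        return span.distance_to(seg.interval)

    return seg_b if dist(seg_a) <= dist(seg_b) else seg_a


def run_pipeline(sam_source: str | Path, cfg: PipelineConfig) -> PipelineResult:
    """Run the two-step analysis on a SAM file.

    Step 1 narrows the breakpoint loci with discordant inter-region pairs;
    step 2 pins them to single-nucleotide ambiguity intervals from
    soft-clipped split reads.  Empty or signal-free input yields a 'none'
    result, not an exception.
    """
    path = Path(sam_source)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    _, records = read_sam_document(path)
    pairs = extract_inter_region_pairs(records, cfg.scan)
    clusters = cluster_by_mate_proximity(pairs, cfg.scan)
    supported = [c for c in clusters if c.support >= cfg.min_support]
    base = dict(input_path=str(path), input_sha256=digest)
    if not supported:
        log.info("no discordant cluster with support >= %d", cfg.min_support)
        return PipelineResult(
            "none", clusters, None, [], [], None, None, **base
        )
    cluster = max(supported, key=lambda c: c.support)
    seg_a, seg_b = _segments_for_cluster(cfg, cluster)

    candidates = collect_breakpoint_candidates(records, cluster, cfg.split)
    junctions: list[SplitReadJunction] = []
    rejections: list[SplitReadRejection] = []
    for rec in candidates:
        partner = _partner_segment(rec, seg_a, seg_b)
        res = resolve_split_read(rec, partner, cfg.split)
        (junctions if isinstance(res, SplitReadJunction) else rejections).append(res)

    if not junctions:
        log.info("no resolvable split reads near the cluster")
        return PipelineResult(
            "none", clusters, cluster, [], rejections, None, (seg_a, seg_b), **base
        )

    call = call_inversion(
        junctions,
        [cluster],
        seg_a,
        seg_b,
        homology_assignment=cfg.homology_assignment,
    )
    status = "partial" if call.low_confidence else "full"
    return PipelineResult(
        status, clusters, cluster, junctions, rejections, call, (seg_a, seg_b), **base
    )


def _report_text(result: PipelineResult, cfg: PipelineConfig) -> str:
    lines = [
        f"clipinv v{__version__} — balanced-inversion breakpoint report",
        "=" * 60,
        f"input: {result.input_path}",
        f"input sha256: {result.input_sha256}",
        f"regions: A={cfg.scan.region_a}  B={cfg.scan.region_b}",
        f"filters: min_mapq={cfg.scan.min_mapq} max_cluster_gap={cfg.scan.max_cluster_gap}"
        f" min_clip={cfg.split.min_clip} max_mismatch={cfg.split.max_mismatch}",
        f"status: {result.status}",
        "",
        f"discordant clusters: {len(result.clusters)}",
    ]
    for i, cl in enumerate(result.clusters, 1):
        mate_spread = cl.span_b.end - cl.span_b.start
        lines.append(
            f"  cluster {i}: {cl.support} pairs, span_a={cl.span_a}, "
            f"span_b={cl.span_b}, same-strand fraction {cl.same_strand_fraction:.2f}, "
            f"apparent insert sizes {cl.apparent_insert_sizes}, "
            f"mates within {mate_spread} bp "
            f"({'<=' if mate_spread <= cfg.scan.mate_colocation_window else '>'} "
            f"co-location window {cfg.scan.mate_colocation_window} bp)"
        )
    lines.append("")
    lines.append(
        "note: apparent insert size is |pos1 - pos2| + 1 over leftmost mapped "
        "bases (not SAM TLEN)."
    )
    lines.append(f"split reads resolved: {len(result.junctions)}; "
                 f"rejected: {len(result.rejections)}")
    call = result.call
    if call is not None:
        lines += [
            "",
            "call:",
            f"  breakpoint interval A: {call.bp_a}  (printed convention: "
            f"{call.bp_a.start:,}–{str(call.bp_a.start + max(call.homology_len - 1, 0))[-1]})"
            if call.homology_len
            else f"  breakpoint interval A: {call.bp_a}",
            f"  breakpoint interval B: {call.bp_b}",
            f"  homology/duplication: len={call.homology_len} seq={call.homology_seq or '-'}"
            f" (assigned to {call.homology_assignment})",
            f"  support: PE={call.support.discordant_pairs} "
            f"SR1={call.support.split_reads_junction1} SR2={call.support.split_reads_junction2}",
            f"  low confidence: {call.low_confidence}",
        ]
    else:
        lines += ["", "call: none"]
    return "\n".join(lines) + "\n"


def write_outputs(result: PipelineResult, cfg: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Write clusters TSV, junctions TSV, VCF, junction FASTA and the text
    report into ``outdir``; returns the path of each artefact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clusters": outdir / "clusters.tsv",
        "junctions": outdir / "junctions.tsv",
        "vcf": outdir / "call.vcf",
        "fasta": outdir / "junctions.fasta",
        "report": outdir / "report.txt",
    }
    cluster_table(result.clusters).to_csv(paths["clusters"], sep="\t", index=False)
    junction_table(result.junctions, result.rejections).to_csv(
        paths["junctions"], sep="\t", index=False
    )
    paths["vcf"].write_text(
        write_vcf(result.call, cfg.sample_id, genotype=cfg.genotype)
    )
    fasta_lines = []
    if result.call is not None and result.segments is not None:
        j1, j2 = junction_sequences(result.call, *result.segments, flank=50)
        fasta_lines = [
            f">junction_1 {result.call.bp_a}", j1,
            f">junction_2 {result.call.bp_b}", j2,
        ]
    paths["fasta"].write_text("\n".join(fasta_lines) + ("\n" if fasta_lines else ""))
    paths["report"].write_text(_report_text(result, cfg))
    return paths
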