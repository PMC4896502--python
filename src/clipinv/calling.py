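"""Aggregate per-read junction evidence into an inversion call.

Model
-----
A balanced inversion replaces ``R[1..b1] + R[b1+1..b2] + R[b2+1..]`` with
``R[1..b1] + revcomp(R[b1+1..b2]) + R[b2+1..]``.  When the h bases just
right of b1 equal the reverse complement of the h bases just right of b2,
every breakpoint pair ``(b1 + k, b2 + h - k)`` for k in 0..h produces the
identical derived chromosome: the junction can slide over a homology (or
duplicated-motif) window of length h, and the exact breakpoint is only
defined up to a closed interval of width h per side.

Evidence geometry
-----------------
Each breakpoint-spanning read contributes two junction-adjacent coordinates,
one per locus.  An aligner extends the *aligned* part maximally through the
homologous bases, so the aligned side of a read pins the extreme placement
in the direction of extension, while the realigned *clip* (which excludes
those bases) pins the opposite extreme on the partner locus.  Collecting the
minimal and maximal placements per side yields the ambiguity interval
``[min, min + h]`` directly from the reads; the homology window is then
validated against the local reference segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__ as _pkg_version
from .discordant import DiscordantPairCluster
from .samio import GenomicInterval, reverse_complement
from .splitread import ReferenceSegment, SplitReadJunction

__all__ = [
    "InversionCall",
    "SupportCounts",
    "JunctionConflictError",
    "call_inversion",
    "junction_sequences",
    "write_vcf",
    "read_vcf",
    "region_span",
]

log = logging.getLogger(__name__)


class JunctionConflictError(ValueError):
    """Per-read junction coordinates cannot be reconciled by homology sliding."""


@dataclass(frozen=True)
class SupportCounts:
    discordant_pairs: int
    split_reads_junction1: int  # reads whose aligned part sits on the lower locus
    split_reads_junction2: int  # ... on the higher locus

    def __post_init__(self) -> None:
        if min(
            self.discordant_pairs,
            self.split_reads_junction1,
            self.split_reads_junction2,
        ) < 0:
            raise ValueError("support counts must be non-negative")


@dataclass
class InversionCall:
    """The aggregated breakpoint pair.

    ``bp_a``/``bp_b`` are closed breakpoint ambiguity intervals whose width
    (end - start) equals the homology length; a blunt junction gives a
    width-0 point interval.  ``homology_seq`` holds the side-A plus-strand
    copy of the duplicated/homologous bases (those immediately right of the
    interval's left bound); the assignment convention records which side the
    duplicated bases are reported on — both representations are
    sequence-equivalent.
    """

    bp_a: GenomicInterval
    bp_b: GenomicInterval
    homology_seq: str
    homology_assignment: str  # 'side_a' | 'side_b'
    support: SupportCounts
    junction_seqs: Optional[tuple[str, str]] = None
    low_confidence: bool = False
    ref_base_a: str = "N"

    @property
    def homology_len(self) -> int:
        return len(self.homology_seq)


def region_span(interval: GenomicInterval) -> int:
    """Width in bp of a closed 1-based interval (end - start + 1)."""
    return interval.length


def _junction_estimates(
    j: SplitReadJunction,
) -> tuple[tuple[int, str], tuple[int, str]]:
    """(aligned-side estimate, clip-side estimate) as (coordinate, kind).

    kind 'max' marks an upper bound on that side's breakpoint placement,
    'min' a lower bound.  A part whose junction-adjacent base is the genomic
    maximum of its interval is a left flank (material at or below the
    breakpoint, estimate = adjacent coordinate); one adjacent at the genomic
    minimum is a right flank (material above, estimate = adjacent - 1).
    Aligned parts are maximally extended so they pin the extreme in the
    extension direction; clips pin the opposite extreme.
    """
    # Work in SAM stored orientation (reference plus strand), which is how
    # clip sides and clip sequences are recorded: stored sequence ascends
    # with the genome, so a right-side clip always adjoins the aligned
    # interval's end and the clip's first stored base.
    if j.sc_side == "right":
        aln_adjacent = j.aln_interval.end
        sc_adjacent = j.sc_read_start
    else:
        aln_adjacent = j.aln_interval.start
        sc_adjacent = j.sc_read_end
    if aln_adjacent == j.aln_interval.end:
        aln_est = (aln_adjacent, "max")  # left flank, aligner pushed it up
    else:
        aln_est = (aln_adjacent - 1, "min")  # right flank, pushed down

    if sc_adjacent == j.sc_interval.end:
        sc_est = (sc_adjacent, "min")  # left flank seen from the clip
    else:
        sc_est = (sc_adjacent - 1, "max")  # right flank seen from the clip
    return aln_est, sc_est


def _segment_for(interval: GenomicInterval, seg_a: ReferenceSegment, seg_b: ReferenceSegment) -> str:
    """'a' or 'b' depending on which segment the interval overlaps."""
    for label, seg in (("a", seg_a), ("b", seg_b)):
        if interval.chrom == seg.chrom and not (
            interval.end < seg.offset or interval.start > seg.end
        ):
            return label
    raise ValueError(f"interval {interval} overlaps neither reference segment")


def call_inversion(
    junctions: Sequence[SplitReadJunction],
    clusters: Sequence[DiscordantPairCluster],
    seg_a: ReferenceSegment,
    seg_b: ReferenceSegment,
    homology_assignment: str = "side_a",
) -> InversionCall:
    """Combine split-read junctions and discordant-pair support into a call.

    Per side, the breakpoint ambiguity interval is [minimal placement,
    minimal placement + h], h the homology length implied by the spread
    between clip-derived and alignment-derived placements; the homology
    window is verified base-by-base against the reference segments
    (equivalent to sliding the join point and testing sequence identity).
    Junctions from a single orientation only yield a width-0 call flagged
    low-confidence.  Irreconcilable coordinates raise
    :class:`JunctionConflictError` listing the offending reads.
    """
    if homology_assignment not in ("side_a", "side_b"):
        raise ValueError(f"unknown homology assignment {homology_assignment!r}")
    if not junctions:
        raise ValueError("no junctions to call from")
    if seg_a.offset > seg_b.offset and seg_a.chrom == seg_b.chrom:
        seg_a, seg_b = seg_b, seg_a

    estimates = {"a": {"min": [], "max": []}, "b": {"min": [], "max": []}}
    per_read_sum: dict[str, int] = {}
    n_aln_a = n_aln_b = 0
    for j in junctions:
        aln_side = _segment_for(j.aln_interval, seg_a, seg_b)
        sc_side = _segment_for(j.sc_interval, seg_a, seg_b)
        if aln_side == sc_side:
            raise JunctionConflictError(
                f"{j.read_id}: aligned part and clip map to the same locus"
            )
        if aln_side == "a":
            n_aln_a += 1
        else:
            n_aln_b += 1
        (aln_coord, aln_kind), (sc_coord, sc_kind) = _junction_estimates(j)
        estimates[aln_side][aln_kind].append((aln_coord, j.read_id))
        estimates[sc_side][sc_kind].append((sc_coord, j.read_id))
        per_read_sum[j.read_id] = aln_coord + sc_coord

    def bounds(side: str) -> tuple[Optional[int], Optional[int]]:
        mins = [c for c, _ in estimates[side]["min"]]
        maxs = [c for c, _ in estimates[side]["max"]]
        return (min(mins) if mins else None, max(maxs) if maxs else None)

    a_min, a_max = bounds("a")
    b_min, b_max = bounds("b")
    one_orientation = n_aln_a == 0 or n_aln_b == 0

    if one_orientation:
        # only one extreme observable per side: point call, homology unknown
        x = a_min if a_min is not None else a_max
        y = b_min if b_min is not None else b_max
        log.warning("junctions from a single orientation: partial, low-confidence call")
        return InversionCall(
            bp_a=GenomicInterval(seg_a.chrom, x, x),
            bp_b=GenomicInterval(seg_b.chrom, y, y),
            homology_seq="",
            homology_assignment=homology_assignment,
            support=SupportCounts(
                discordant_pairs=sum(len(c.pairs) for c in clusters),
                split_reads_junction1=n_aln_a,
                split_reads_junction2=n_aln_b,
            ),
            low_confidence=True,
            ref_base_a=_safe_base(seg_a, x),
        )

    h_a = a_max - a_min
    h_b = b_max - b_min
    if h_a != h_b or h_a < 0:
        offenders = sorted(
            {rid for side in ("a", "b") for kind in ("min", "max") for _, rid in estimates[side][kind]}
        )
        raise JunctionConflictError(
            f"side spreads disagree (A: {h_a}, B: {h_b}); reads involved: {offenders}"
        )
    h = h_a

    expected_sum = a_min + b_max
    offenders = sorted(
        rid for rid, s in per_read_sum.items() if s != expected_sum
    )
    if offenders:
        raise JunctionConflictError(
            f"junction coordinates inconsistent beyond {h}-bp homology sliding "
            f"for reads: {offenders}"
        )

    homology_seq = ""
    if h > 0:
        try:
            hom_a = seg_a.slice(a_min + 1, a_min + h)
            hom_b = seg_b.slice(b_min + 1, b_min + h)
        except IndexError:
            log.warning("segments do not cover the homology window; skipping validation")
            hom_a = hom_b = None
        if hom_a is not None:
            if hom_a != reverse_complement(hom_b):
                raise JunctionConflictError(
                    f"claimed homology window fails sequence identity: "
                    f"A[{a_min + 1}..{a_min + h}]={hom_a} vs "
                    f"revcomp(B[{b_min + 1}..{b_min + h}])={reverse_complement(hom_b)}"
                )
            homology_seq = hom_a

    call = InversionCall(
        bp_a=GenomicInterval(seg_a.chrom, a_min, a_min + h),
        bp_b=GenomicInterval(seg_b.chrom, b_min, b_min + h),
        homology_seq=homology_seq,
        homology_assignment=homology_assignment,
        support=SupportCounts(
            discordant_pairs=sum(len(c.pairs) for c in clusters),
            split_reads_junction1=n_aln_a,
            split_reads_junction2=n_aln_b,
        ),
        ref_base_a=_safe_base(seg_a, a_min),
    )
    call.junction_seqs = junction_sequences(call, seg_a, seg_b, flank=50)
    return call


def _safe_base(seg: ReferenceSegment, pos: int) -> str:
    try:
        return seg.base(pos)
    except IndexError:
        return "N"


def junction_sequences(
    call: InversionCall,
    seg_a: ReferenceSegment,
    seg_b: ReferenceSegment,
    flank: int = 50,
) -> tuple[str, str]:
    """Derivative-chromosome sequence across the two junctions.

    With duplicated bases assigned to side A (the default, lower-coordinate
    locus), the junction placement is (bp_a.end, bp_b.start); assigning them
    to side B uses (bp_a.start, bp_b.end).  Junction 1 is the lower-locus
    junction: side-A plus strand into reverse-complemented side B (read
    downhill); junction 2 is the reciprocal derivative junction:
    reverse-complemented side A above the breakpoint into side-B plus strand
    above its breakpoint.  The homologous bases therefore appear once in
    each junction sequence.  Flanks are truncated (with a warning) where a
    segment ends.
    """
    if seg_a.offset > seg_b.offset and seg_a.chrom == seg_b.chrom:
        seg_a, seg_b = seg_b, seg_a
    if call.homology_assignment == "side_a":
        x, y = call.bp_a.end, call.bp_b.start
    else:
        x, y = call.bp_a.start, call.bp_b.end

    def left_flank(seg: ReferenceSegment, upto: int) -> str:
        lo = upto - flank + 1
        if lo < seg.offset:
            log.warning("flank truncated at %s start", seg.chrom)
            lo = seg.offset
        return seg.slice(lo, upto) if upto >= seg.offset else ""

    def right_flank(seg: ReferenceSegment, frm: int) -> str:
        hi = frm + flank - 1
        if hi > seg.end:
            log.warning("flank truncated at %s end", seg.chrom)
            hi = seg.end
        return seg.slice(frm, hi) if frm <= seg.end else ""

    seq_j1 = left_flank(seg_a, x) + reverse_complement(left_flank(seg_b, y))
    seq_j2 = reverse_complement(right_flank(seg_a, x + 1)) + right_flank(seg_b, y + 1)
    return seq_j1, seq_j2


# ---------------------------------------------------------------------------
# VCF output


_INFO_HEADER = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS (breakpoint ambiguity)">',
    '##INFO=<ID=CIEND,Number=2,Type=Integer,Description="Confidence interval around END (breakpoint ambiguity)">',
    '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Length of breakpoint micro-homology/duplication">',
    '##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="Sequence of breakpoint micro-homology (side-A plus strand)">',
    '##INFO=<ID=HOMSIDE,Number=1,Type=String,Description="Side the duplicated homology is reported on (side_a/side_b)">',
    '##INFO=<ID=PE,Number=1,Type=Integer,Description="Supporting discordant read pairs">',
    '##INFO=<ID=SR1,Number=1,Type=Integer,Description="Split reads anchored on the lower-coordinate locus">',
    '##INFO=<ID=SR2,Number=1,Type=Integer,Description="Split reads anchored on the higher-coordinate locus">',
    '##INFO=<ID=LOWCONF,Number=0,Type=Flag,Description="Single-orientation, low-confidence call">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
]


def write_vcf(
    call: Optional[InversionCall],
    sample_id: str,
    genotype: Optional[str] = None,
    include_bnd: bool = False,
) -> str:
    """Render the call as a VCF 4.2 document (string).

    One symbolic <INV> record: POS is the left bound of the side-A ambiguity
    interval, INFO/END the right bound of the side-B interval, CIPOS/CIEND
    span the ambiguity, HOMLEN/HOMSEQ describe the duplicated homology.
    ``genotype`` is only emitted if the caller asserts one (zygosity is not
    inferred from read data here); otherwise GT is './.'.  ``call=None``
    produces a header-only (no-call) document.  Optionally a pair of BND
    records spell out both derivative junction strands.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=clipinv-{_pkg_version}",
        '##ALT=<ID=INV,Description="Inversion">',
        *_INFO_HEADER,
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if call is not None:
        lines.insert(2, f"##contig=<ID={call.bp_a.chrom}>")
        if call.bp_b.chrom != call.bp_a.chrom:
            lines.insert(3, f"##contig=<ID={call.bp_b.chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    if call is not None:
        h = call.homology_len
        info = [
            "SVTYPE=INV",
            f"END={call.bp_b.end}",
            f"CIPOS=0,{h}",
            f"CIEND=-{h},0",
            f"HOMLEN={h}",
        ]
        if h:
            info.append(f"HOMSEQ={call.homology_seq}")
        info += [
            f"HOMSIDE={call.homology_assignment}",
            f"PE={call.support.discordant_pairs}",
            f"SR1={call.support.split_reads_junction1}",
            f"SR2={call.support.split_reads_junction2}",
        ]
        if call.low_confidence:
            info.append("LOWCONF")
        gt = genotype if genotype is not None else "./."
        lines.append(
            "\t".join(
                [
                    call.bp_a.chrom,
                    str(call.bp_a.start),
                    "inv_1",
                    call.ref_base_a,
                    "<INV>",
                    ".",
                    "PASS" if not call.low_confidence else "LowQual",
                    ";".join(info),
                    "GT",
                    gt,
                ]
            )
        )
        if include_bnd:
            a, b = call.bp_a, call.bp_b
            bnd1 = (
                f"{a.chrom}\t{a.end}\tinv_bnd_1\t{call.ref_base_a}\t"
                f"{call.ref_base_a}]{b.chrom}:{b.start}]\t.\tPASS\t"
                f"SVTYPE=BND;MATEID=inv_bnd_2\tGT\t{genotype or './.'}"
            )
            bnd2 = (
                f"{a.chrom}\t{a.start + 1}\tinv_bnd_2\tN\t"
                f"[{b.chrom}:{b.start + 1}[N\t.\tPASS\t"
                f"SVTYPE=BND;MATEID=inv_bnd_1\tGT\t{genotype or './.'}"
            )
            lines.append(bnd1)
            lines.append(bnd2)
    return "\n".join(lines) + "\n"


def read_vcf(path) -> Optional[InversionCall]:
    """Re-read a clipinv VCF into call fields (junction sequences are not
    stored in VCF and come back as None).  Returns None for a no-call file."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.info.get("SVTYPE") != "INV":
                continue
            h = int(rec.info["HOMLEN"])
            end = rec.stop  # htslib exposes INFO/END as 0-based-exclusive stop
            homseq = rec.info.get("HOMSEQ", "") if h else ""
            if isinstance(homseq, tuple):
                homseq = homseq[0]
            return InversionCall(
                bp_a=GenomicInterval(rec.chrom, rec.pos, rec.pos + h),
                bp_b=GenomicInterval(rec.chrom, end - h, end),
                homology_seq=homseq,
                homology_assignment=str(rec.info.get("HOMSIDE", "side_a")),
                support=SupportCounts(
                    discordant_pairs=int(rec.info["PE"]),
                    split_reads_junction1=int(rec.info["SR1"]),
                    split_reads_junction2=int(rec.info["SR2"]),
                ),
                low_confidence=bool(rec.info.get("LOWCONF", False)),
                ref_base_a=rec.ref,
            )
    return None
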