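"""Stage 2: realign soft-clipped segments onto the partner locus.

Each candidate breakpoint-spanning read consists of an aligned part (placed
by the upstream aligner) and a soft-clipped part.  The clip is realigned
ungapped against a local reference segment of the partner locus on both
strands (this replaces interactive BLAT interrogation), yielding a per-read
junction: two coordinates, two strands, zero or more mismatches.  Junctions
are clean blunt or microhomology joins, so ungapped full-length placement of
the clip is the model; indel-containing junctions are out of scope.

Clip mapping reports both a normalised genomic interval (start <= end) and
read-orientation endpoints (first/last mapped base in read order), because a
minus-strand clip reads "downhill" through genome coordinates and published
split-read evidence is conventionally printed in read orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .discordant import DiscordantPairCluster
from .samio import (
    AlignmentRecord,
    GenomicInterval,
    aligned_span,
    reverse_complement,
    soft_clipped_segments,
)

__all__ = [
    "ReferenceSegment",
    "SplitReadConfig",
    "ClipHit",
    "AmbiguousHit",
    "NoHit",
    "SplitReadJunction",
    "SplitReadRejection",
    "collect_breakpoint_candidates",
    "map_clip",
    "resolve_split_read",
    "reconstruct_reference_segments",
    "segment_from_fasta",
    "junction_table",
]

log = logging.getLogger(__name__)

#: targets at or below this size are scored exhaustively at every offset;
#: above it, exact-seed candidate generation kicks in first.
_EXHAUSTIVE_TARGET_LIMIT = 5000


@dataclass(frozen=True)
class ReferenceSegment:
    """A plus-strand slice of reference sequence anchored at a 1-based
    genomic offset — the local stand-in for the genome around one locus."""

    chrom: str
    offset: int
    seq: str

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ValueError("segment offset must be >= 1")
        if len(self.seq) < 1:
            raise ValueError("segment must contain sequence")

    @property
    def end(self) -> int:
        return self.offset + len(self.seq) - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.offset, self.end)

    def base(self, pos: int) -> str:
        if not self.offset <= pos <= self.end:
            raise IndexError(f"position {pos} outside segment {self.interval}")
        return self.seq[pos - self.offset]

    def slice(self, start: int, end: int) -> str:
        """Plus-strand bases of the closed interval [start, end]."""
        if start > end:
            raise ValueError("slice start after end")
        if start < self.offset or end > self.end:
            raise IndexError(
                f"[{start},{end}] outside segment {self.interval}"
            )
        return self.seq[start - self.offset : end - self.offset + 1]


def segment_from_fasta(
    fasta_path, chrom: str, start: int, end: int
) -> ReferenceSegment:
    """Slice ``chrom:start-end`` (1-based closed) out of a FASTA file."""
    from pyfaidx import Fasta

    with Fasta(str(fasta_path)) as fa:
        record = fa[chrom]
        start = max(1, start)
        end = min(len(record), end)
        seq = record[start - 1 : end].seq.upper()
    return ReferenceSegment(chrom=chrom, offset=start, seq=seq)


@dataclass(frozen=True)
class SplitReadConfig:
    """Thresholds for candidate collection and clip realignment.

    ``min_clip`` (20 nt) keeps only clips long enough to seed reliably;
    ``max_mismatch`` (2) allows for sequencing error while rejecting chance
    placements; ``seed_len`` (15) is the exact-seed length used against
    large targets; ``flank`` (1000 bp) is how far from a discordant cluster
    span a clipped read may sit and still count as a candidate.
    """

    min_clip: int = 20
    max_mismatch: int = 2
    seed_len: int = 15
    flank: int = 1000


@dataclass(frozen=True)
class ClipHit:
    """A full-length ungapped placement of a clip on a segment."""

    interval: GenomicInterval  # normalised: start <= end
    strand: str
    mismatches: int
    read_start: int  # genomic coordinate of the clip's first base in read order
    read_end: int  # ... and its last base

    @property
    def score(self) -> int:
        return self.interval.length - 2 * self.mismatches  # matches - mismatches


@dataclass(frozen=True)
class AmbiguousHit:
    """Multiple equal-best placements; data, not an exception."""

    hits: tuple[ClipHit, ...]


@dataclass(frozen=True)
class NoHit:
    """No placement within the mismatch budget."""

    best_mismatches: Optional[int] = None


MapClipResult = Union[ClipHit, AmbiguousHit, NoHit]


def _placements_to_score(
    query: str, target: str, offsets: Iterable[int]
) -> dict[int, int]:
    """Mismatch count of the full-length placement of ``query`` at each
    0-based target offset."""
    out: dict[int, int] = {}
    for off in offsets:
        window = target[off : off + len(query)]
        mism = sum(a != b for a, b in zip(query, window))
        out[off] = mism
    return out


def _candidate_offsets(query: str, target: str, seed_len: int) -> set[int]:
    """Offsets implied by exact seed matches of ``query`` k-mers in ``target``."""
    k = min(seed_len, len(query))
    index: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        index.setdefault(target[i : i + k], []).append(i)
    candidates: set[int] = set()
    for qpos in range(len(query) - k + 1):
        for tpos in index.get(query[qpos : qpos + k], ()):
            off = tpos - qpos
            if 0 <= off <= len(target) - len(query):
                candidates.add(off)
    return candidates


def map_clip(
    clip_seq: str,
    target: ReferenceSegment,
    max_mismatch: int = 2,
    seed_len: int = 15,
) -> MapClipResult:
    """Best ungapped full-length placement of ``clip_seq`` on either strand.

    Score is matches minus mismatches.  Small targets are scored at every
    offset on both strands, which makes the result exactly the optimum; for
    targets beyond a few kb, candidate offsets come from exact seeds of
    length ``min(seed_len, |clip|)`` first (with an exhaustive fallback if no
    seed fires).  Ties at the best score across distinct placements yield
    :class:`AmbiguousHit`; a best placement with more than ``max_mismatch``
    mismatches yields :class:`NoHit`.
    """
    n = len(clip_seq)
    if n < 1 or n > len(target.seq):
        return NoHit()
    queries = {"+": clip_seq.upper(), "-": reverse_complement(clip_seq).upper()}
    tseq = target.seq.upper()
    hits: list[ClipHit] = []
    for strand, query in queries.items():
        if len(tseq) <= _EXHAUSTIVE_TARGET_LIMIT:
            offsets: Iterable[int] = range(len(tseq) - n + 1)
        else:
            offsets = _candidate_offsets(query, tseq, seed_len)
            if not offsets:
                offsets = range(len(tseq) - n + 1)
        for off, mism in _placements_to_score(query, tseq, offsets).items():
            start = target.offset + off
            end = start + n - 1
            if strand == "+":
                read_start, read_end = start, end
            else:
                read_start, read_end = end, start
            hits.append(
                ClipHit(
                    interval=GenomicInterval(target.chrom, start, end),
                    strand=strand,
                    mismatches=mism,
                    read_start=read_start,
                    read_end=read_end,
                )
            )
    if not hits:
        return NoHit()
    best_score = max(h.score for h in hits)
    best = [h for h in hits if h.score == best_score]
    if best[0].mismatches > max_mismatch:
        return NoHit(best_mismatches=min(h.mismatches for h in best))
    if len(best) > 1:
        best.sort(key=lambda h: (h.interval.start, h.strand))
        return AmbiguousHit(hits=tuple(best))
    return best[0]


@dataclass(frozen=True)
class SplitReadJunction:
    """One resolved breakpoint-spanning read: the aligner's placement of the
    matched part plus the realigned placement of its dominant clip."""

    read_id: str
    aln_interval: GenomicInterval
    aln_strand: str
    aln_len: int  # read nucleotides in the aligned part
    sc_interval: GenomicInterval  # normalised genomic span of the clip
    sc_strand: str
    sc_len: int
    sc_side: str  # 'left' or 'right', in SAM stored orientation
    sc_read_start: int  # clip's first mapped base, in clip (stored) orientation
    sc_read_end: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.sc_side not in ("left", "right"):
            raise ValueError(f"bad clip side {self.sc_side!r}")


@dataclass(frozen=True)
class SplitReadRejection:
    """A candidate that could not be resolved; rejections are data."""

    read_id: str
    reason: str  # 'no_hit' | 'ambiguous' | 'short_clip'


def collect_breakpoint_candidates(
    records: Iterable[AlignmentRecord],
    cluster: DiscordantPairCluster,
    cfg: SplitReadConfig = SplitReadConfig(),
) -> list[AlignmentRecord]:
    """Mapped, sequence-bearing records with a dominant soft clip of at least
    ``min_clip`` nt whose aligned span lies within ``flank`` of either cluster
    span.  Pairing status is irrelevant here: junction-spanning reads whose
    mates were uninformative are recovered by this step.
    """
    out: list[AlignmentRecord] = []
    for rec in records:
        if rec.read_unmapped or rec.seq is None:
            continue
        if rec.secondary or rec.duplicate or rec.supplementary:
            continue
        clip_lens = [op.length for op in rec.cigar if op.op == "S"]
        if not clip_lens or max(clip_lens) < cfg.min_clip:
            continue
        span = aligned_span(rec)
        near = False
        for ref_span in (cluster.span_a, cluster.span_b):
            if span.chrom == ref_span.chrom and span.distance_to(ref_span) <= cfg.flank:
                near = True
        if near:
            out.append(rec)
    return out


def resolve_split_read(
    rec: AlignmentRecord,
    partner: ReferenceSegment,
    cfg: SplitReadConfig = SplitReadConfig(),
) -> SplitReadJunction | SplitReadRejection:
    """Map the dominant (largest) soft clip of ``rec`` onto ``partner``.

    Returns a junction on success, or a rejection carrying the reason
    (``short_clip``, ``no_hit``, ``ambiguous``).
    """
    clips = soft_clipped_segments(rec)
    if not clips:
        return SplitReadRejection(rec.read_id, "short_clip")
    side, clip_seq, clip_len = max(clips, key=lambda c: c[2])
    if clip_len < cfg.min_clip:
        return SplitReadRejection(rec.read_id, "short_clip")
    result = map_clip(clip_seq, partner, cfg.max_mismatch, cfg.seed_len)
    if isinstance(result, NoHit):
        return SplitReadRejection(rec.read_id, "no_hit")
    if isinstance(result, AmbiguousHit):
        return SplitReadRejection(rec.read_id, "ambiguous")
    aln_len = sum(op.length for op in rec.cigar if op.op in ("M", "I", "=", "X"))
    return SplitReadJunction(
        read_id=rec.read_id,
        aln_interval=aligned_span(rec),
        aln_strand=rec.strand,
        aln_len=aln_len,
        sc_interval=result.interval,
        sc_strand=result.strand,
        sc_len=clip_len,
        sc_side=side,
        sc_read_start=result.read_start,
        sc_read_end=result.read_end,
        mismatches=result.mismatches,
    )


# ---------------------------------------------------------------------------
# reference-segment reconstruction from annotated split reads


class SegmentConflictError(ValueError):
    """Two overlapping read contributions disagree at a coordinate."""


def reconstruct_reference_segments(
    rows: Sequence, locality_gap: int = 100_000
) -> tuple[ReferenceSegment, ReferenceSegment]:
    """Assemble plus-strand local reference segments from annotated
    split-read evidence (the published-table route to reference sequence
    when no FASTA is at hand).

    Each row must expose ``seq, aln_len, aln_start, aln_end, aln_strand,
    sc_start, sc_end, sc_strand`` with clip coordinates in read orientation.
    Aligned portions are used as-is; clipped portions are reverse-complemented
    onto the plus strand when the clip mapped "-".  Contributions whose
    coordinates are separated by more than ``locality_gap`` belong to
    different localities; exactly two localities must emerge, returned in
    coordinate order.  Any base conflict raises
    :class:`SegmentConflictError` naming the coordinate.
    """
    contributions: dict[int, str] = {}
    chrom = None

    def put(pos: int, base: str, who: str) -> None:
        old = contributions.get(pos)
        if old is not None and old != base:
            raise SegmentConflictError(
                f"conflicting base at {pos}: {old} vs {base} (from {who})"
            )
        contributions[pos] = base

    for row in rows:
        chrom = getattr(row, "chrom", None) or chrom
        seq = row.seq.upper()
        if row.aln_strand == "+":
            aln_read = seq[: row.aln_len]
        else:  # aligned on minus: stored SEQ is already reference plus strand
            aln_read = seq[: row.aln_len]
        for i, base in enumerate(aln_read):
            put(row.aln_start + i, base, f"{row.read_id} aligned")
        clip = seq[row.aln_len :]
        if row.sc_strand == "-":
            plus, lo = reverse_complement(clip), min(row.sc_start, row.sc_end)
        else:
            plus, lo = clip, min(row.sc_start, row.sc_end)
        for i, base in enumerate(plus):
            put(lo + i, base, f"{row.read_id} clip")

    if not contributions:
        raise ValueError("no rows to reconstruct from")
    chrom = chrom or "chr7"
    positions = sorted(contributions)
    groups: list[list[int]] = [[positions[0]]]
    for pos in positions[1:]:
        if pos - groups[-1][-1] > locality_gap:
            groups.append([])
        groups[-1].append(pos)
    if len(groups) != 2:
        raise ValueError(
            f"expected two localities, found {len(groups)} "
            f"(gap threshold {locality_gap})"
        )
    segments = []
    for grp in groups:
        lo, hi = grp[0], grp[-1]
        missing = [p for p in range(lo, hi + 1) if p not in contributions]
        if missing:
            raise ValueError(f"uncovered positions within locality: {missing[:5]} ...")
        segments.append(
            ReferenceSegment(
                chrom=chrom,
                offset=lo,
                seq="".join(contributions[p] for p in range(lo, hi + 1)),
            )
        )
    segments.sort(key=lambda s: s.offset)
    return segments[0], segments[1]


def junction_table(
    junctions: Sequence[SplitReadJunction],
    rejections: Sequence[SplitReadRejection] = (),
) -> pd.DataFrame:
    """Per-read junction report mirroring the published split-read table
    (aligned/clipped lengths, coordinates in read orientation, strands)."""
    rows = []
    for j in junctions:
        rows.append(
            {
                "read_id": j.read_id,
                "status": "resolved",
                "chrom": j.aln_interval.chrom,
                "sc_chrom": j.sc_interval.chrom,
                "aln_nts": j.aln_len,
                "sc_nts": j.sc_len,
                "aln_start": j.aln_interval.start,
                "aln_end": j.aln_interval.end,
                "aln_strand": j.aln_strand,
                "sc_start": j.sc_read_start,
                "sc_end": j.sc_read_end,
                "sc_strand": j.sc_strand,
                "sc_side": j.sc_side,
                "mismatches": j.mismatches,
            }
        )
    for r in rejections:
        rows.append({"read_id": r.read_id, "status": f"rejected:{r.reason}"})
    cols = [
        "read_id",
        "status",
        "chrom",
        "sc_chrom",
        "aln_nts",
        "sc_nts",
        "aln_start",
        "aln_end",
        "aln_strand",
        "sc_start",
        "sc_end",
        "sc_strand",
        "sc_side",
        "mismatches",
    ]
    return pd.DataFrame(rows, columns=cols)
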