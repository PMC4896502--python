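"""Stage 1: discordant inter-region read-pair selection and proximity clustering.

Given two candidate windows (for a karyotype-detected inversion these are the
two cytogenetic bands), the scan keeps read pairs with one read in each
window that are not flagged as proper pairs, both mates mapped, and mapping
quality above a floor — the classic same-strand, huge-apparent-insert
signature of an inversion — then chains them into clusters by mate proximity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .samio import AlignmentRecord, GenomicInterval, ReadPair, cigar_string

__all__ = [
    "ScanConfig",
    "DiscordantPairCluster",
    "passes_discordant_filter",
    "extract_inter_region_pairs",
    "cluster_by_mate_proximity",
    "apparent_insert_size",
    "same_strand",
    "cluster_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the discordant scan.

    ``min_mapq`` defaults to 1, i.e. MAPQ > 0 (discards multi-mapping reads);
    ``max_cluster_gap`` is the "within 1 kb of the preceding read" chaining
    distance, applied inclusively at the boundary; ``chain_on`` selects
    whether chaining constrains both mates ("both") or only the region-B mate
    ("mate_only") — on clean data the resulting partition is the same.
    """

    region_a: GenomicInterval
    region_b: GenomicInterval
    min_mapq: int = 1
    max_cluster_gap: int = 1000
    mate_colocation_window: int = 200
    min_support: int = 2
    chain_on: str = "both"

    def __post_init__(self) -> None:
        if self.min_mapq < 1:
            raise ValueError("min_mapq must be >= 1")
        if self.max_cluster_gap <= 0:
            raise ValueError("max_cluster_gap must be positive")
        if self.chain_on not in ("both", "mate_only"):
            raise ValueError(f"unknown chain_on mode {self.chain_on!r}")
        a, b = self.region_a, self.region_b
        if a.chrom == b.chrom and not (a.end < b.start or b.end < a.start):
            raise ValueError("candidate regions must not overlap")


def passes_discordant_filter(rec: AlignmentRecord, cfg: ScanConfig) -> bool:
    """True iff the record survives the ``-q 1 -F 14``-style per-read filter:
    MAPQ at or above the floor, not a proper pair, read and mate both mapped."""
    return (
        rec.mapq >= cfg.min_mapq
        and not rec.proper_pair
        and not rec.read_unmapped
        and not rec.mate_unmapped
    )


def apparent_insert_size(pair: ReadPair) -> int:
    """Inclusive distance between the two leftmost mapped bases.

    This (|pos1 - pos2| + 1) is the convention that reproduces the published
    per-pair values exactly; it deliberately differs from SAM TLEN, which is
    end-aware.  For an inversion-crossing pair it approximates the size of
    the inverted segment.
    """
    r1, r2 = pair.read1, pair.read2
    if r1.read_unmapped or r2.read_unmapped:
        raise ValueError(f"{r1.read_id}: both mates must be mapped")
    if r1.chrom != r2.chrom:
        raise ValueError(
            f"{r1.read_id}: mates on different chromosomes "
            f"({r1.chrom} vs {r2.chrom}) have no apparent insert size"
        )
    return abs(r1.pos - r2.pos) + 1


def same_strand(pair: ReadPair) -> bool:
    """Strand equality of the two mates — expected for inversion junctions,
    never for a well-formed FR proper pair."""
    if pair.read1.read_unmapped or pair.read2.read_unmapped:
        raise ValueError(f"{pair.read1.read_id}: both mates must be mapped")
    return pair.read1.strand == pair.read2.strand


@dataclass
class DiscordantPairCluster:
    """A chained run of inter-region pairs supporting one junction locus."""

    pairs: list[ReadPair]
    span_a: GenomicInterval
    span_b: GenomicInterval
    apparent_insert_sizes: list[int]
    same_strand_fraction: float

    @property
    def support(self) -> int:
        return len(self.pairs)

    @property
    def is_singleton(self) -> bool:
        return len(self.pairs) == 1


def _build_cluster(members: list[ReadPair]) -> DiscordantPairCluster:
    pos_a = [p.read1.pos for p in members]
    pos_b = [p.read2.pos for p in members]
    chrom_a = members[0].read1.chrom
    chrom_b = members[0].read2.chrom
    return DiscordantPairCluster(
        pairs=list(members),
        span_a=GenomicInterval(chrom_a, min(pos_a), max(pos_a)),
        span_b=GenomicInterval(chrom_b, min(pos_b), max(pos_b)),
        apparent_insert_sizes=[apparent_insert_size(p) for p in members],
        same_strand_fraction=(
            sum(same_strand(p) for p in members) / len(members)
        ),
    )


def extract_inter_region_pairs(
    records: Iterable[AlignmentRecord], cfg: ScanConfig
) -> list[ReadPair]:
    """Select pairs with one read in region A and its mate in region B.

    Membership is by leftmost mapped position.  Secondary and duplicate
    records are dropped before pairing (duplicate marking is assumed done
    upstream; duplicates would inflate cluster support).  When the mate
    record is absent from the input, a stub is synthesised from the mate
    fields of the region-A record; records without usable mate information
    are skipped with a warning.  Output is ordered by region-A position.
    """
    primary = [r for r in records if not (r.secondary or r.duplicate or r.supplementary)]
    by_id: dict[tuple[str, bool], AlignmentRecord] = {}
    for rec in primary:
        by_id[(rec.read_id, rec.first_in_pair)] = rec

    pairs: list[ReadPair] = []
    seen: set[str] = set()
    for rec in primary:
        if rec.read_unmapped or not rec.paired or rec.read_id in seen:
            continue
        if not cfg.region_a.contains(rec.chrom, rec.pos):
            continue
        if not passes_discordant_filter(rec, cfg):
            continue
        mate = by_id.get((rec.read_id, not rec.first_in_pair))
        if mate is None:
            if rec.mate_chrom is None or rec.mate_pos is None:
                log.warning(
                    "read %s in region A has no mate record and no mate fields; skipped",
                    rec.read_id,
                )
                continue
            mate = _mate_stub(rec)
        else:
            if not passes_discordant_filter(mate, cfg):
                continue
        if mate.read_unmapped or not cfg.region_b.contains(mate.chrom, mate.pos):
            continue
        pairs.append(ReadPair(read1=rec, read2=mate))
        seen.add(rec.read_id)
    pairs.sort(key=lambda p: p.read1.pos)
    return pairs


def _mate_stub(rec: AlignmentRecord) -> AlignmentRecord:
    """Mate placeholder reconstructed from RNEXT/PNEXT and the mate flags."""
    from . import samio

    flag = samio.FLAG_PAIRED
    flag |= samio.FLAG_REVERSE if rec.mate_reverse else 0
    flag |= samio.FLAG_MATE_REVERSE if rec.read_reverse else 0
    flag |= 0 if rec.first_in_pair else samio.FLAG_FIRST
    return AlignmentRecord(
        read_id=rec.read_id,
        flag=flag,
        chrom=rec.mate_chrom,
        pos=rec.mate_pos,
        mapq=255,  # unknown
        cigar=(),
        mate_chrom=rec.chrom,
        mate_pos=rec.pos,
    )


def cluster_by_mate_proximity(
    pairs: Sequence[ReadPair], cfg: ScanConfig
) -> list[DiscordantPairCluster]:
    """Single-linkage chaining of pairs sorted by region-A position.

    A pair joins the open cluster iff its region-A position is within
    ``max_cluster_gap`` of the previous pair's region-A position and (in
    ``chain_on="both"`` mode) its mate is within the same distance of the
    previous pair's mate.  Boundary ties (exactly the gap) are inclusive.
    Singleton clusters are returned too; callers decide on a support floor.
    """
    clusters: list[DiscordantPairCluster] = []
    open_members: list[ReadPair] = []
    for pair in pairs:
        if open_members:
            prev = open_members[-1]
            ok_mate = abs(pair.read2.pos - prev.read2.pos) <= cfg.max_cluster_gap
            ok_a = abs(pair.read1.pos - prev.read1.pos) <= cfg.max_cluster_gap
            chained = ok_mate if cfg.chain_on == "mate_only" else (ok_a and ok_mate)
            if not chained:
                clusters.append(_build_cluster(open_members))
                open_members = []
        open_members.append(pair)
    if open_members:
        clusters.append(_build_cluster(open_members))
    for cl in clusters:
        if cl.is_singleton:
            log.info(
                "singleton cluster at %s / %s reported but weakly supported",
                cl.span_a,
                cl.span_b,
            )
    return clusters


def cluster_table(clusters: Sequence[DiscordantPairCluster]) -> pd.DataFrame:
    """Tabular cluster report, one row per pair, columns mirroring the
    published evidence table plus a cluster id."""
    rows = []
    for idx, cl in enumerate(clusters, start=1):
        for pair in cl.pairs:
            r1, r2 = pair.read1, pair.read2
            rows.append(
                {
                    "cluster_id": idx,
                    "cluster_support": cl.support,
                    "read_id": r1.read_id,
                    "chrom_a": r1.chrom,
                    "pos_a": r1.pos,
                    "strand_a": r1.strand,
                    "mapq_a": r1.mapq,
                    "cigar_a": cigar_string(r1.cigar),
                    "chrom_b": r2.chrom,
                    "pos_b": r2.pos,
                    "strand_b": r2.strand,
                    "mapq_b": r2.mapq,
                    "cigar_b": cigar_string(r2.cigar),
                    "apparent_insert_size": apparent_insert_size(pair),
                    "same_strand": same_strand(pair),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "cluster_support",
            "read_id",
            "chrom_a",
            "pos_a",
            "strand_a",
            "mapq_a",
            "cigar_a",
            "chrom_b",
            "pos_b",
            "strand_b",
            "mapq_b",
            "cigar_b",
            "apparent_insert_size",
            "same_strand",
        ],
    )
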