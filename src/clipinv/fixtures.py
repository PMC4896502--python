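"""Published evidence for the chromosome 7 pericentric inversion case,
embedded as machine-readable fixtures.

The hand-foot-genital syndrome case that motivates this package was resolved
from four discordant read pairs (cluster evidence) and six soft-clipped
175-nt breakpoint-spanning reads (split-read evidence) on hg19 chr7.  Those
reads, their coordinates and the candidate cytoband windows are shipped as
package data so the whole analysis can be replayed end to end without the
deposited sequencing run.  SHA-256 checksums guard against transcription
drift in the shipped tables.

Read ids for the two IGV-recovered singleton reads carry the same
instrument/run prefix as the paired reads; only the tile coordinates were
printed for them.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .samio import (
    AlignmentRecord,
    GenomicInterval,
    ReadPair,
    make_record,
    parse_cigar,
    sam_header,
)

__all__ = ["Table2Read", "FixtureSet", "load_fixtures", "build_fixture_sam"]

CHROM = "chr7"
#: hg19 chr7 length, for the @SQ header line.
CHR7_LEN = 159_138_663

#: 7p15 and 7q21 cytoband windows used to restrict the discordant scan.
REGION_7P15 = GenomicInterval(CHROM, 20_900_001, 28_800_000)
REGION_7Q21 = GenomicInterval(CHROM, 77_500_001, 98_000_000)

#: Published breakpoint left coordinates and duplicated homology.
PUBLISHED_BP_A_LEFT = 27_762_423
PUBLISHED_BP_B_LEFT = 93_599_530
PUBLISHED_HOMOLOGY = "AT"

_CHECKSUMS = {
    "table1_pairs.tsv": "f3f1b2162547f55d6ee0f4478ac8b6273604f7d4153dcc2fe7b80d653bbb6d5c",
    "table2_reads.tsv": "c7de9deb149a1a28a3323adcdc6d199376cf5a2515b72bf3d43082a26886fbeb",
}


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture content does not match its frozen checksum."""


@dataclass(frozen=True)
class Table2Read:
    """One annotated breakpoint-spanning read (split-read evidence row)."""

    pair_index: int
    read_id: str
    seq: str
    aln_len: int
    sc_len: int
    aln_start: int
    aln_end: int
    aln_strand: str
    sc_start: int  # read-orientation first mapped base of the clip
    sc_end: int
    sc_strand: str
    chrom: str = CHROM


@dataclass
class FixtureSet:
    table1_pairs: list[ReadPair]
    table2_reads: list[Table2Read]
    region_a: GenomicInterval
    region_b: GenomicInterval
    published_bp_a_left: int = PUBLISHED_BP_A_LEFT
    published_bp_b_left: int = PUBLISHED_BP_B_LEFT
    published_homology: str = PUBLISHED_HOMOLOGY


def _read_data(name: str) -> list[dict[str, str]]:
    data = resources.files("clipinv.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} != expected {_CHECKSUMS[name]}"
        )
    return list(csv.DictReader(data.decode().splitlines(), delimiter="\t"))


def load_fixtures() -> FixtureSet:
    """Load the embedded evidence tables into domain objects."""
    t2 = [
        Table2Read(
            pair_index=int(r["pair_index"]),
            read_id=r["read_id"],
            seq=r["sequence"],
            aln_len=int(r["aln_nts"]),
            sc_len=int(r["sc_nts"]),
            aln_start=int(r["aln_start"]),
            aln_end=int(r["aln_end"]),
            aln_strand=r["aln_strand"],
            sc_start=int(r["sc_start"]),
            sc_end=int(r["sc_end"]),
            sc_strand=r["sc_strand"],
        )
        for r in _read_data("table2_reads.tsv")
    ]
    seqs = {row.read_id: row for row in t2}

    pairs: list[ReadPair] = []
    for r in _read_data("table1_pairs.tsv"):
        recs = []
        for n in ("1", "2"):
            pos = int(r[f"pos_{n}"])
            cigar = r[f"cigar_{n}"]
            other = "2" if n == "1" else "1"
            clipped = "S" in cigar
            seq: Optional[str] = None
            if clipped and r["read_id"] in seqs:
                seq = seqs[r["read_id"]].seq
            recs.append(
                make_record(
                    r["read_id"],
                    CHROM,
                    pos,
                    cigar,
                    strand=r[f"strand_{n}"],
                    mapq=int(r[f"mapq_{n}"]),
                    seq=seq,
                    paired=True,
                    proper_pair=False,
                    mate_strand=r[f"strand_{other}"],
                    first_in_pair=(n == "1"),
                    second_in_pair=(n == "2"),
                    mate_chrom=CHROM,
                    mate_pos=int(r[f"pos_{other}"]),
                )
            )
        pairs.append(ReadPair(read1=recs[0], read2=recs[1]))

    return FixtureSet(
        table1_pairs=pairs,
        table2_reads=t2,
        region_a=REGION_7P15,
        region_b=REGION_7Q21,
    )


def _table2_cigar(row: Table2Read) -> str:
    # all published reads carry a single right-side clip
    return f"{row.aln_len}M{row.sc_len}S"


def build_fixture_sam(fixtures: FixtureSet) -> tuple[list[str], list[AlignmentRecord]]:
    """A minimal coordinate-sorted SAM of the published reads.

    Paired reads get FLAG and mate fields satisfying exactly the stated
    filters (paired, mapped, mates mapped, not proper); the two reads found
    by eyeballing the alignment rather than by pairing are emitted as
    unpaired clip-bearing records.  Mates whose bases were never published
    are carried with SEQ '*'.
    """
    records: list[AlignmentRecord] = []
    paired_ids = set()
    for pair in fixtures.table1_pairs:
        records.extend([pair.read1, pair.read2])
        paired_ids.add(pair.read1.read_id)
    for row in fixtures.table2_reads:
        if row.read_id in paired_ids:
            continue  # already present via its Table 1 pairing
        records.append(
            make_record(
                row.read_id,
                row.chrom,
                row.aln_start,
                _table2_cigar(row),
                strand=row.aln_strand,
                mapq=60,
                seq=row.seq,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    header = sam_header({CHROM: CHR7_LEN})
    return header, records
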