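"""Alignment data model and SAM/FASTA plumbing.

The pipeline consumes coordinate-level alignment evidence, so the in-memory
unit is a small :class:`AlignmentRecord` rather than a full-featured aligner
object.  SAM text is parsed through :mod:`pysam` and converted; writing is
done by an in-package formatter so that a read -> write -> read round trip is
byte-identical (pysam's writer is not guaranteed to preserve formatting).

Conventions
-----------
* All genomic coordinates are 1-based inclusive (SAM convention).  Any
  half-open arithmetic is private to a function.
* Unmapped records carry ``chrom=None`` and ``pos=None``.
* Records with SEQ ``*`` (mate stubs) are allowed; operations that need the
  read bases reject them explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam

__all__ = [
    "GenomicInterval",
    "CigarOp",
    "AlignmentRecord",
    "ReadPair",
    "SamFormatError",
    "parse_cigar",
    "cigar_string",
    "aligned_span",
    "soft_clipped_segments",
    "reverse_complement",
    "read_sam",
    "read_sam_document",
    "write_sam",
    "make_record",
]

# SAM FLAG bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

#: CIGAR operations that consume query bases.
QUERY_OPS = frozenset("MIS=X")
#: CIGAR operations that consume reference bases.
REF_OPS = frozenset("MDN=X")
#: Operations accepted by :func:`parse_cigar`.
VALID_OPS = frozenset("MIDSHN=X")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_SEQ_RE = re.compile(r"^[ACGTNacgtn]*$")
_CIGAR_TOKEN = re.compile(r"(\d+)([A-Za-z=])")


class SamFormatError(ValueError):
    """Raised for malformed SAM text or CIGAR strings."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed 1-based interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} precedes start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chromosome (0 if they
        touch or overlap)."""
        if other.chrom != self.chrom:
            raise ValueError("intervals on different chromosomes")
        if other.start > self.end:
            return other.start - self.end - 1
        if self.start > other.end:
            return self.start - other.end - 1
        return 0

    @classmethod
    def from_string(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (commas in numbers tolerated)."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
        start = int(m.group(2).replace(",", ""))
        end = int(m.group(3).replace(",", ""))
        return cls(m.group(1), start, end)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CigarOp:
    length: int
    op: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"CIGAR op length must be >= 1, got {self.length}")
        if self.op not in VALID_OPS:
            raise ValueError(f"unknown CIGAR op {self.op!r}")

    def __str__(self) -> str:
        return f"{self.length}{self.op}"


def parse_cigar(text: str) -> tuple[CigarOp, ...]:
    """Parse a SAM CIGAR string; ``*`` yields an empty tuple.

    Raises :class:`SamFormatError` naming the offending token for malformed
    input (counts without letters, letters without counts, unknown codes).
    """
    if text == "*":
        return ()
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(text):
        if m.start() != pos:
            raise SamFormatError(
                f"malformed CIGAR {text!r}: unexpected token {text[pos:m.start()]!r}"
            )
        length, code = int(m.group(1)), m.group(2)
        if code not in VALID_OPS:
            raise SamFormatError(f"malformed CIGAR {text!r}: unknown op {code!r}")
        ops.append(CigarOp(length, code))
        pos = m.end()
    if pos != len(text) or not ops:
        raise SamFormatError(
            f"malformed CIGAR {text!r}: unexpected token {text[pos:]!r}"
        )
    return tuple(ops)


def cigar_string(cigar: Sequence[CigarOp]) -> str:
    return "".join(str(op) for op in cigar) if cigar else "*"


@dataclass
class AlignmentRecord:
    """One aligned (or unmapped) read with its mate bookkeeping.

    ``flag`` stores the raw SAM FLAG integer; the individual booleans the
    pipeline cares about are exposed as properties, which keeps unknown bits
    intact across a round trip.
    """

    read_id: str
    flag: int
    chrom: Optional[str]
    pos: Optional[int]  # 1-based leftmost mapped base
    mapq: int
    cigar: tuple[CigarOp, ...]
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    tlen: int = 0
    seq: Optional[str] = None
    qual: Optional[str] = None
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.read_unmapped:
            if self.pos is None or self.pos < 1:
                raise ValueError(f"{self.read_id}: mapped record needs pos >= 1")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"{self.read_id}: MAPQ {self.mapq} out of range")
        if self.seq is not None and self.cigar:
            consumed = sum(op.length for op in self.cigar if op.op in QUERY_OPS)
            if consumed != len(self.seq):
                raise ValueError(
                    f"{self.read_id}: CIGAR consumes {consumed} query bases "
                    f"but SEQ has {len(self.seq)}"
                )

    # -- FLAG accessors -------------------------------------------------
    @property
    def paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER_PAIR)

    @property
    def read_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def read_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def mate_reverse(self) -> bool:
        return bool(self.flag & FLAG_MATE_REVERSE)

    @property
    def first_in_pair(self) -> bool:
        return bool(self.flag & FLAG_FIRST)

    @property
    def secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUP)

    @property
    def supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def strand(self) -> str:
        return "-" if self.read_reverse else "+"

    @property
    def mate_strand(self) -> str:
        return "-" if self.mate_reverse else "+"

    def to_sam_line(self) -> str:
        rname = self.chrom if self.chrom is not None else "*"
        if self.mate_chrom is None:
            rnext = "*"
        elif self.mate_chrom == self.chrom:
            rnext = "="
        else:
            rnext = self.mate_chrom
        fields = [
            self.read_id,
            str(self.flag),
            rname,
            str(self.pos if self.pos is not None else 0),
            str(self.mapq),
            cigar_string(self.cigar),
            rnext,
            str(self.mate_pos if self.mate_pos is not None else 0),
            str(self.tlen),
            self.seq if self.seq is not None else "*",
            self.qual if self.qual is not None else "*",
            *self.tags,
        ]
        return "\t".join(fields)


def make_record(
    read_id: str,
    chrom: Optional[str],
    pos: Optional[int],
    cigar: str | Sequence[CigarOp],
    *,
    strand: str = "+",
    mapq: int = 60,
    seq: Optional[str] = None,
    paired: bool = False,
    proper_pair: bool = False,
    read_unmapped: bool = False,
    mate_unmapped: bool = False,
    mate_strand: str = "+",
    first_in_pair: bool = False,
    second_in_pair: bool = False,
    secondary: bool = False,
    duplicate: bool = False,
    mate_chrom: Optional[str] = None,
    mate_pos: Optional[int] = None,
    qual: Optional[str] = None,
    tags: Sequence[str] = (),
) -> AlignmentRecord:
    """Convenience constructor assembling the FLAG field from booleans."""
    flag = 0
    flag |= FLAG_PAIRED if paired else 0
    flag |= FLAG_PROPER_PAIR if proper_pair else 0
    flag |= FLAG_UNMAPPED if read_unmapped else 0
    flag |= FLAG_MATE_UNMAPPED if mate_unmapped else 0
    flag |= FLAG_REVERSE if strand == "-" else 0
    flag |= FLAG_MATE_REVERSE if mate_strand == "-" else 0
    flag |= FLAG_FIRST if first_in_pair else 0
    flag |= FLAG_SECOND if second_in_pair else 0
    flag |= FLAG_SECONDARY if secondary else 0
    flag |= FLAG_DUP if duplicate else 0
    ops = parse_cigar(cigar) if isinstance(cigar, str) else tuple(cigar)
    return AlignmentRecord(
        read_id=read_id,
        flag=flag,
        chrom=chrom,
        pos=pos,
        mapq=mapq,
        cigar=ops,
        mate_chrom=mate_chrom,
        mate_pos=mate_pos,
        seq=seq,
        qual=qual,
        tags=tuple(tags),
    )


@dataclass
class ReadPair:
    """A mate pair; for inter-region pairs ``read1`` is the lower-coordinate
    (region A) read by convention."""

    read1: AlignmentRecord
    read2: AlignmentRecord

    def __post_init__(self) -> None:
        if self.read1.read_id != self.read2.read_id:
            raise ValueError(
                f"pair members disagree on read id: "
                f"{self.read1.read_id!r} vs {self.read2.read_id!r}"
            )


# ---------------------------------------------------------------------------
# record-level operations


def aligned_span(rec: AlignmentRecord) -> GenomicInterval:
    """Reference interval covered by the alignment: ``[pos, pos + refspan - 1]``.

    Clips never move the span; an unmapped record is an error.
    """
    if rec.read_unmapped or rec.pos is None or rec.chrom is None:
        raise ValueError(f"{rec.read_id}: unmapped record has no aligned span")
    ref_len = sum(op.length for op in rec.cigar if op.op in REF_OPS)
    if ref_len == 0:
        raise ValueError(f"{rec.read_id}: CIGAR consumes no reference bases")
    return GenomicInterval(rec.chrom, rec.pos, rec.pos + ref_len - 1)


def soft_clipped_segments(
    rec: AlignmentRecord,
) -> list[tuple[str, str, int]]:
    """Return ``(side, sequence, length)`` for each terminal soft clip.

    Sequences are reported in read orientation (as stored in SEQ).  Records
    without stored sequence (mate stubs) and hard-clip-only records are
    rejected because the clipped bases are not recoverable.
    """
    if rec.read_unmapped:
        raise ValueError(f"{rec.read_id}: unmapped record")
    if not any(op.op == "S" for op in rec.cigar):
        if any(op.op == "H" for op in rec.cigar):
            raise ValueError(
                f"{rec.read_id}: hard-clipped record carries no clipped sequence"
            )
        return []
    if rec.seq is None:
        raise ValueError(f"{rec.read_id}: record has no stored sequence (SEQ '*')")
    out: list[tuple[str, str, int]] = []
    # leading clip
    first = rec.cigar[0]
    if first.op == "S":
        out.append(("left", rec.seq[: first.length], first.length))
    last = rec.cigar[-1]
    if last.op == "S" and len(rec.cigar) > 1:
        out.append(("right", rec.seq[-last.length :], last.length))
    return out


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}, case-insensitive; N maps to N."""
    if not _SEQ_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTNacgtn"))
        raise ValueError(f"sequence contains non-nucleotide characters: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# SAM I/O


def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    unmapped = seg.is_unmapped
    raw = seg.to_string().split("\t")
    return AlignmentRecord(
        read_id=seg.query_name,
        flag=seg.flag,
        chrom=None if unmapped else seg.reference_name,
        pos=None if unmapped else seg.reference_start + 1,
        mapq=seg.mapping_quality,
        cigar=parse_cigar(seg.cigarstring) if seg.cigarstring else (),
        mate_chrom=seg.next_reference_name,
        mate_pos=None if seg.next_reference_start < 0 else seg.next_reference_start + 1,
        tlen=seg.template_length,
        seq=seg.query_sequence,
        qual=raw[10] if raw[10] != "*" else None,
        tags=tuple(raw[11:]),
    )


def _locate_bad_line(path: Path) -> Optional[int]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) < 11:
                return lineno
    return None


def read_sam_document(
    source: str | Path,
) -> tuple[list[str], list[AlignmentRecord]]:
    """Read a SAM text file into (header lines, records)."""
    path = Path(source)
    try:
        with pysam.AlignmentFile(str(path), "r") as fh:
            header = str(fh.header).rstrip("\n").split("\n") if fh.header else []
            records = [_from_pysam(seg) for seg in fh]
    except (ValueError, OSError) as exc:
        bad = _locate_bad_line(path)
        if bad is not None:
            raise SamFormatError(
                f"{path}: line {bad}: missing mandatory SAM columns"
            ) from exc
        raise SamFormatError(f"{path}: {exc}") from exc
    return header, records


def read_sam(source: str | Path) -> Iterator[AlignmentRecord]:
    """Iterate alignment records of a SAM text file, in file order."""
    _, records = read_sam_document(source)
    yield from records


def write_sam(
    dest: str | Path,
    records: Iterable[AlignmentRecord],
    header: Sequence[str],
) -> None:
    """Write SAM text: header lines (already including '@') then records."""
    with open(dest, "w") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        for rec in records:
            fh.write(rec.to_sam_line() + "\n")


def sam_header(chrom_lengths: dict[str, int], sort_order: str = "coordinate") -> list[str]:
    lines = [f"@HD\tVN:1.6\tSO:{sort_order}"]
    for name, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    return lines
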