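"""Synthetic pericentric-inversion datasets with ground-truth alignments.

The generator emulates the sequencing design the pipeline was built for:
asymmetric paired-end reads (175 nt + 50 nt) from 300-400 bp inserts at
around 9-fold coverage, over a single-chromosome toy genome carrying one
planted inversion whose junctions may have a sliding-homology window.

The simulator acts as its own oracle aligner: every read is emitted with
the alignment a well-behaved aligner would report against the *reference*
allele — junction-crossing reads are soft-clipped with the anchor maximally
extended through any junction homology (mimicking how bwa places clean
split reads), pairs whose fragment crosses a junction become same-strand
discordant pairs, and the proper-pair flag is computed from the mapped
geometry.  That removes any external-aligner dependency while preserving
exactly the signal structure the pipeline consumes.

Homology planting
-----------------
For an inversion of (bp1, bp2], the junction can slide over h bases iff
``ref[bp1+1 .. bp1+h] == revcomp(ref[bp2+1 .. bp2+h])``; the generator
therefore writes the reverse complement of the h bases right of bp2 into
the h bases right of bp1 (a plain same-strand copy only creates sliding
for reverse-complement-palindromic words such as the AT of the motivating
case).  Genome bases flanking the planted window are adjusted so the
homology run has exactly length h, making recovery deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .samio import (
    AlignmentRecord,
    GenomicInterval,
    make_record,
    parse_cigar,
    reverse_complement,
    sam_header,
    write_sam,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "make_genome",
    "apply_inversion",
    "simulate_reads",
    "simulate",
]

_BASES = np.array(list("ACGT"))
_OTHER = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of one synthetic dataset.

    Defaults mirror the motivating sequencing run: 175 + 50 nt mates,
    truncated-normal insert in [300, 400] bp (mean 350, sd 25), ~9x
    coverage, error-free bases.  ``bp1`` and ``bp2`` are the *minimal*
    junction placements (the left bounds of the ambiguity intervals the
    caller should recover); the pericentric aspect is positional only —
    the centromere is a coordinate the planted breakpoints must straddle.
    """

    genome_length: int = 200_000
    centromere_pos: Optional[int] = None  # default: genome midpoint
    bp1: Optional[int] = None  # default: 1/4 of the genome
    bp2: Optional[int] = None  # default: 3/4 of the genome
    homology_len: int = 2
    zygosity: str = "hom"  # 'hom' | 'het'
    read_len_1: int = 175
    read_len_2: int = 50
    insert_mean: float = 350.0
    insert_sd: float = 25.0
    insert_min: int = 300
    insert_max: int = 400
    coverage: float = 9.0
    error_rate: float = 0.0
    min_anchor: int = 20
    seed: int = 0
    chrom: str = "sim1"

    def __post_init__(self) -> None:
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.homology_len < 0:
            raise ValueError("homology_len must be >= 0")
        if self.insert_min < self.read_len_1:
            raise ValueError("insert lower bound must accommodate the long read")
        b1, cen, b2 = self.breakpoints[0], self.centromere, self.breakpoints[1]
        if not (0 < b1 < cen < b2 < self.genome_length - self.homology_len - 1):
            raise ValueError(
                f"need 0 < bp1 ({b1}) < centromere ({cen}) < bp2 ({b2}) "
                f"< genome end; inversion must straddle the centromere"
            )

    @property
    def centromere(self) -> int:
        return self.centromere_pos or self.genome_length // 2

    @property
    def breakpoints(self) -> tuple[int, int]:
        return (
            self.bp1 or self.genome_length // 4,
            self.bp2 or (3 * self.genome_length) // 4,
        )

    @property
    def n_pairs(self) -> int:
        return round(
            self.coverage * self.genome_length / (self.read_len_1 + self.read_len_2)
        )


def make_genome(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> str:
    """Uniform random A/C/G/T genome with the homology window planted and
    its flanks adjusted so the junction slide run is exactly homology_len."""
    rng = rng or np.random.default_rng(cfg.seed)
    bases = _BASES[rng.integers(0, 4, size=cfg.genome_length)]
    seq = list("".join(bases))
    b1, b2 = cfg.breakpoints
    h = cfg.homology_len

    def comp(x: str) -> str:
        return reverse_complement(x)  # single base: complement

    if h > 0:
        word = "".join(seq[b2 : b2 + h])  # ref[bp2+1 .. bp2+h]
        seq[b1 : b1 + h] = list(reverse_complement(word))
    # block sliding past the planted window on both ends
    if seq[b1 + h] == comp(seq[b2 - 1]):  # ref[bp1+h+1] vs comp(ref[bp2])
        seq[b1 + h] = _OTHER[comp(seq[b2 - 1])][0]
    if seq[b1 - 1] == comp(seq[b2 + h]):  # ref[bp1] vs comp(ref[bp2+h+1])
        seq[b1 - 1] = _OTHER[comp(seq[b2 + h])][0]
    return "".join(seq)


def apply_inversion(reference: str, cfg: SimulationConfig) -> str:
    """Derived allele: the segment between the junctions reverse-complemented
    in place (constructed at the (bp1, bp2 + h) placement; every placement
    in the slide window yields this same sequence)."""
    b1, b2 = cfg.breakpoints
    hi = b2 + cfg.homology_len
    return (
        reference[:b1]
        + reverse_complement(reference[b1:hi])
        + reference[hi:]
    )


# ---------------------------------------------------------------------------
# truth alignment


def _derived_blocks(cfg: SimulationConfig) -> list[tuple[int, int, str]]:
    """(allele_start, allele_end, strand) blocks of the derived allele in
    reference coordinates; inverted block maps pos d -> b1 + hi + 1 - d."""
    b1, b2 = cfg.breakpoints
    hi = b2 + cfg.homology_len
    return [(1, b1, "+"), (b1 + 1, hi, "-"), (hi + 1, cfg.genome_length, "+")]


def _map_allele_interval(
    cfg: SimulationConfig, from_derived: bool, lo: int, hi: int
) -> list[tuple[int, int, int, str]]:
    """Split allele interval [lo, hi] into (a_lo, a_hi, ref_left, strand)
    segments, in ascending allele order."""
    if not from_derived:
        return [(lo, hi, lo, "+")]
    b1 = cfg.breakpoints[0]
    top = cfg.breakpoints[1] + cfg.homology_len
    segs = []
    for blo, bhi, strand in _derived_blocks(cfg):
        u, v = max(lo, blo), min(hi, bhi)
        if u > v:
            continue
        if strand == "+":
            segs.append((u, v, u, "+"))
        else:
            # allele pos d <-> ref pos b1 + top + 1 - d
            segs.append((u, v, b1 + top + 1 - v, "-"))
    return segs


@dataclass
class _TruthAln:
    pos: Optional[int]  # leftmost M base, 1-based; None if unmapped
    strand: str
    cigar: str
    mapped: bool
    end: Optional[int] = None  # rightmost M base


def _align_read(
    cfg: SimulationConfig,
    reference: str,
    read: str,
    from_derived: bool,
    allele_lo: int,
    read_strand: str,
) -> _TruthAln:
    """Oracle alignment of one read against the reference allele.

    The anchor is the longest contiguous block (ties -> lower reference
    coordinate), maximally extended base-by-base through any homologous
    sequence; remaining bases are soft clips.  Anchors shorter than
    ``min_anchor`` leave the read unmapped.
    """
    n = len(read)
    segs = _map_allele_interval(cfg, from_derived, allele_lo, allele_lo + n - 1)
    # to read orientation: (q_offset, length, ref_left, eff_strand)
    ordered = segs if read_strand == "+" else list(reversed(segs))
    q = 0
    rsegs = []
    for a_lo, a_hi, ref_left, seg_strand in ordered:
        length = a_hi - a_lo + 1
        eff = seg_strand if read_strand == "+" else ("-" if seg_strand == "+" else "+")
        rsegs.append((q, length, ref_left, eff))
        q += length
    anchor = max(rsegs, key=lambda s: (s[1], -s[2]))
    qs, length, ref_left, eff = anchor
    qe = qs + length - 1

    # maximal extension through matching reference bases
    def ref_base(p: int) -> Optional[str]:
        return reference[p - 1] if 1 <= p <= len(reference) else None

    if eff == "+":
        # read q maps to ref_left + (q - qs)
        while qs > 0 and ref_base(ref_left - 1) == read[qs - 1]:
            qs, ref_left = qs - 1, ref_left - 1
        ref_right = ref_left + (qe - qs)
        while qe < n - 1 and ref_base(ref_right + 1) == read[qe + 1]:
            qe, ref_right = qe + 1, ref_right + 1
    else:
        ref_right = ref_left + length - 1
        # read q maps to ref_right - (q - qs)
        while qs > 0 and ref_base(ref_right + 1) == reverse_complement(read[qs - 1]):
            qs, ref_right = qs - 1, ref_right + 1
        ref_left = ref_right - (qe - qs)
        while qe < n - 1 and ref_base(ref_left - 1) == reverse_complement(read[qe + 1]):
            qe, ref_left = qe + 1, ref_left - 1

    mlen = qe - qs + 1
    if mlen < cfg.min_anchor:
        return _TruthAln(pos=None, strand="+", cigar="*", mapped=False)
    left, right = qs, n - 1 - qe
    if eff == "+":
        parts = [(left, "S"), (mlen, "M"), (right, "S")]
    else:  # stored in reference orientation: clip sides swap
        parts = [(right, "S"), (mlen, "M"), (left, "S")]
    cigar = "".join(f"{l}{op}" for l, op in parts if l > 0)
    return _TruthAln(pos=ref_left, strand=eff, cigar=cigar, mapped=True, end=ref_right)


# ---------------------------------------------------------------------------
# dataset


@dataclass
class SimulatedRead:
    read_id: str
    seq: str  # as sequenced (read orientation)
    qual: str


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: str
    derived: str
    truth_bp_a: GenomicInterval
    truth_bp_b: GenomicInterval
    truth_homology: str
    records: list[AlignmentRecord]  # truth alignments, coordinate-sorted
    reads1: list[SimulatedRead]
    reads2: list[SimulatedRead]
    junction_covered: bool

    @property
    def header(self) -> list[str]:
        return sam_header({self.config.chrom: self.config.genome_length})

    def write_reference_fasta(self, path) -> None:
        _write_fasta(path, self.config.chrom, self.reference)

    def write_derived_fasta(self, path) -> None:
        _write_fasta(path, f"{self.config.chrom}_derived", self.derived)

    def write_truth_sam(self, path) -> None:
        write_sam(path, self.records, self.header)

    def write_fastq_pair(self, prefix) -> tuple[Path, Path]:
        paths = (Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq"))
        for path, reads in zip(paths, (self.reads1, self.reads2)):
            with open(path, "w") as fh:
                for r in reads:
                    fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
        return paths

    def write_truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "chrom": self.config.chrom,
                    "bp_a": [self.truth_bp_a.start, self.truth_bp_a.end],
                    "bp_b": [self.truth_bp_b.start, self.truth_bp_b.end],
                    "homology": self.truth_homology,
                    "zygosity": self.config.zygosity,
                    "seed": self.config.seed,
                    "junction_covered": self.junction_covered,
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def _write_fasta(path, name: str, seq: str, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")


def simulate_reads(
    reference: str,
    derived: str,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AlignmentRecord], list[SimulatedRead], list[SimulatedRead]]:
    """Draw read pairs from the configured allele mix and emit truth
    alignments against the reference coordinates."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n = cfg.n_pairs
    a = (cfg.insert_min - cfg.insert_mean) / cfg.insert_sd
    b = (cfg.insert_max - cfg.insert_mean) / cfg.insert_sd
    inserts = np.rint(
        truncnorm.rvs(a, b, loc=cfg.insert_mean, scale=cfg.insert_sd, size=n, random_state=rng)
    ).astype(int)
    from_derived_draw = (
        np.ones(n, dtype=bool)
        if cfg.zygosity == "hom"
        else rng.random(n) < 0.5
    )
    orient = rng.random(n) < 0.5  # True: long read from the left fragment end
    starts = rng.integers(1, cfg.genome_length - inserts + 2)

    records: list[AlignmentRecord] = []
    reads1: list[SimulatedRead] = []
    reads2: list[SimulatedRead] = []
    for i in range(n):
        ins = int(inserts[i])
        fstart = int(starts[i])
        use_derived = bool(from_derived_draw[i])
        allele = derived if use_derived else reference
        rid = f"sim:{i:06d}"
        frag = allele[fstart - 1 : fstart + ins - 1]
        if orient[i]:
            s1 = frag[: cfg.read_len_1]
            lo1, rs1 = fstart, "+"
            s2 = reverse_complement(frag[-cfg.read_len_2 :])
            lo2, rs2 = fstart + ins - cfg.read_len_2, "-"
        else:
            s1 = reverse_complement(frag[-cfg.read_len_1 :])
            lo1, rs1 = fstart + ins - cfg.read_len_1, "-"
            s2 = frag[: cfg.read_len_2]
            lo2, rs2 = fstart, "+"
        s1 = _apply_errors(s1, cfg.error_rate, rng)
        s2 = _apply_errors(s2, cfg.error_rate, rng)
        aln1 = _align_read(cfg, reference, s1, use_derived, lo1, rs1)
        aln2 = _align_read(cfg, reference, s2, use_derived, lo2, rs2)
        rec1, rec2 = _pair_records(cfg, rid, s1, aln1, s2, aln2)
        records.extend([rec1, rec2])
        reads1.append(SimulatedRead(rid, s1, "I" * len(s1)))
        reads2.append(SimulatedRead(rid, s2, "I" * len(s2)))
    records.sort(key=lambda r: (r.read_unmapped, r.pos or 0))
    return records, reads1, reads2


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = _OTHER[out[i]][rng.integers(0, 3)]
    return "".join(out)


def _pair_records(
    cfg: SimulationConfig,
    rid: str,
    s1: str,
    aln1: _TruthAln,
    s2: str,
    aln2: _TruthAln,
) -> tuple[AlignmentRecord, AlignmentRecord]:
    proper = False
    if aln1.mapped and aln2.mapped and aln1.strand != aln2.strand:
        fwd, rev = (aln1, aln2) if aln1.strand == "+" else (aln2, aln1)
        if fwd.pos <= rev.pos:
            span = rev.end - fwd.pos + 1
            proper = cfg.insert_min <= span <= cfg.insert_max

    def build(seq: str, aln: _TruthAln, mate: _TruthAln, first: bool) -> AlignmentRecord:
        stored = seq if (not aln.mapped or aln.strand == "+") else reverse_complement(seq)
        return make_record(
            rid,
            cfg.chrom if aln.mapped else None,
            aln.pos,
            aln.cigar if aln.mapped else "*",
            strand=aln.strand if aln.mapped else "+",
            mapq=60 if aln.mapped else 0,
            seq=stored,
            paired=True,
            proper_pair=proper,
            read_unmapped=not aln.mapped,
            mate_unmapped=not mate.mapped,
            mate_strand=mate.strand if mate.mapped else "+",
            first_in_pair=first,
            second_in_pair=not first,
            mate_chrom=cfg.chrom if mate.mapped else None,
            mate_pos=mate.pos,
        )

    return build(s1, aln1, aln2, True), build(s2, aln2, aln1, False)


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate genome, derived allele, reads and truth alignments."""
    rng = np.random.default_rng(cfg.seed)
    reference = make_genome(cfg, rng)
    derived = apply_inversion(reference, cfg)
    records, reads1, reads2 = simulate_reads(reference, derived, cfg, rng)
    b1, b2 = cfg.breakpoints
    h = cfg.homology_len
    return SimulatedDataset(
        config=cfg,
        reference=reference,
        derived=derived,
        truth_bp_a=GenomicInterval(cfg.chrom, b1, b1 + h),
        truth_bp_b=GenomicInterval(cfg.chrom, b2, b2 + h),
        truth_homology=reference[b1 : b1 + h],
        records=records,
        reads1=reads1,
        reads2=reads2,
        junction_covered=any("S" in str(op) for r in records for op in r.cigar),
    )
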