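# Methods

## Problem and model

A balanced pericentric inversion replaces the reference chromosome
`R[1..b1] · R[b1+1..b2] · R[b2+1..]` with
`R[1..b1] · revcomp(R[b1+1..b2]) · R[b2+1..]`, with `b1` and `b2` on
opposite sides of the centromere. No sequence is gained or lost, so depth
and array signals are silent; the information lives entirely in read
*placement*:

* a mate pair whose fragment straddles a junction maps with both reads on
  the **same strand** and an enormous apparent inter-mate distance
  (approximately the inverted segment length);
* a read that crosses a junction is reported by the aligner as a partial
  (soft-clipped) alignment, and its clipped tail belongs to the partner
  locus on the opposite strand.

`clipinv` consumes exactly these two signals, in that order: pairs narrow
the search to two sub-kilobase loci, clips then give base resolution.

### Junction sliding and the ambiguity interval

If the h bases immediately right of `b1` equal the reverse complement of
the h bases immediately right of `b2`
(`R[b1+1..b1+h] == revcomp(R[b2+1..b2+h])`), every breakpoint pair
`(b1+k, b2+h−k)` for `k = 0..h` produces the *identical* derived
chromosome. One unit of slide requires exactly
`R[b1+1] == complement(R[b2])`; induction gives the window condition. No
read data can distinguish placements inside the window, so the honest
call is a closed interval of width h per side (width 0 = blunt junction).
In the motivating case h = 2 with the duplicated word `AT` — which is its
own reverse complement, making the duplication describable as a
same-strand "AT duplication assignable to either breakpoint".

A maximally-extending aligner (bwa-style) pushes the *aligned* part of a
junction-crossing read through the homologous bases, so alignment ends
observe one extreme placement; the realigned clip (which excludes those
bases) observes the opposite extreme on the partner side. Per side the
caller takes the minimum over clip-derived ("min-kind") and the maximum
over alignment-derived ("max-kind") junction-adjacent coordinates; the
spread is h, the interval is `[min, min+h]`, and two checks guard the
geometry: each read's coordinate pair must satisfy the slide-invariant
sum `x_i + y_i = const`, and the claimed homology window must verify
base-by-base against the reference segments (equivalent to sliding the
join point and testing sequence identity — the test suite compares
against a brute-force enumeration of all placements). Reads violating
either check raise a conflict error naming the offenders. All coordinate
book-keeping is done in SAM stored orientation (reference plus strand),
where a right-side clip always adjoins the aligned interval's end;
read-orientation endpoints are carried alongside because published
split-read evidence is conventionally printed read-wise (minus-strand
clips run "downhill": start > end).

Junction evidence from only one orientation cannot expose the homology
spread; such calls collapse to point intervals and are flagged
low-confidence (VCF FILTER `LowQual`, INFO `LOWCONF`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_mapq` | 1 | MAPQ floor (> 0 removes multi-mapping reads) |
| `max_cluster_gap` | 1000 bp | chaining distance for pair clusters, boundary inclusive |
| `min_support` | 2 pairs | cluster support floor for proceeding to stage 2 (the motivating cluster had 4) |
| `min_clip` | 20 nt | smallest clip worth realigning; shorter clips cannot seed reliably (shortest published clip: 51 nt) |
| `max_mismatch` | 2 | mismatch budget for a clip placement (sequencing-error allowance; published clips map exactly) |
| `seed_len` | 15 nt | exact-seed length for large targets |
| `flank` | 1000 bp | how far from a cluster span a candidate clipped read may sit |
| `segment_pad` | 3000 bp | reference slice radius around cluster spans; must exceed flank + read length |

Apparent insert size is deliberately `|pos₁ − pos₂| + 1` over leftmost
mapped bases — an inclusive distance, not SAM TLEN — because that is the
convention under which the published per-pair values reproduce exactly;
the report states this. Chaining constrains both the window-A read and
its mate by default (`chain_on="both"`); a `mate_only` mode exists
because the prose description of the procedure is ambiguous on this
point, and on clean data the partition is identical.

## Numerical choices

* **Clip realignment** is ungapped and full-length: inversion junctions
  are clean blunt/microhomology joins, and indel-containing junctions are
  out of scope. Score is matches − mismatches; ties across distinct
  placements return an explicit ambiguous result (data, not an
  exception), and a best placement over budget returns no-hit. For
  targets ≤ 5 kb (every use in this tool) all placements on both strands
  are scored outright, which makes the reported optimum exact; beyond
  that, candidate offsets come from exact seeds of length
  `min(15, |clip|)` with an exhaustive fallback if no seed fires. The
  seed length is below no pigeonhole guarantee for clips shorter than
  `(max_mismatch+1)·seed_len`, which is why small targets bypass seeding
  entirely.
* **Duplication assignment.** Both representations of a slid junction are
  sequence-equivalent; canonical output assigns the duplicated bases to
  the lower-coordinate (p-side) locus, and a flag flips this. Junction
  sequences are emitted for the two *physical* derivative junctions
  (p-flank → reverse-complemented q-flank, and reverse-complemented
  p-above → q-above); the duplicated bases therefore appear once in each.
* **Coordinates** are 1-based inclusive throughout (SAM convention); any
  half-open arithmetic is private. Breakpoint intervals are closed and of
  width h, so the printed two-coordinate convention ("…423–4") is the
  interval's first two positions when h = 2.
* **VCF**: version 4.2, one symbolic `<INV>` record (POS = side-A left
  bound, END = side-B right bound, `CIPOS=0,h`, `CIEND=-h,0`,
  `HOMLEN`/`HOMSEQ`, PE/SR1/SR2 support), optional BND pair. Genotype is
  never inferred — homozygosity in the motivating case came from
  karyotype and parental studies, not read data — so GT is `./.` unless
  asserted by the user.
* **Degenerate inputs**: empty SAM, no inter-region pairs, or no
  resolvable clips produce a "none" result and a header-only VCF, not an
  exception; mate-stub records (SEQ `*`) are accepted for pairing but
  rejected by any operation needing bases; hard-clip-only records are
  rejected where clipped sequence is required.

## Synthetic data

The simulator emulates the study design the tool targets: a
single-chromosome uniform-random genome (200 kb by default, scaled from
the genuine whole-genome setting so a full run takes seconds on one
core), one planted inversion straddling a centromere coordinate,
asymmetric 175 + 50 nt read pairs with truncated-normal inserts in
[300, 400] bp (mean 350, sd 25), ~9× coverage, error-free bases by
default (a substitution rate is available). Homology is planted by
writing `revcomp` of the h bases right of `bp2` into the h bases right of
`bp1` — the reverse-complement relation is what creates junction sliding
for arbitrary h; a literal same-strand copy only works for
reverse-complement-palindromic words like `AT` — and the flanking bases
are adjusted so the slide run has exactly length h, making recovery
deterministic up to junction coverage.

The simulator emits its own truth alignments (anchor = longest contiguous
block, ties to the lower coordinate, greedily extended through matching
reference bases to mimic bwa's behaviour at clean junctions; anchors
under 20 nt are emitted unmapped), so tests need no external aligner.
What it does *not* model: base-quality profiles (qualities are constant
`I`), repeats and multi-mapping (MAPQ is 60 for every mapped read), indel
junctions, chimeric or >2-segment reads, GC bias, and real centromeric
sequence (the centromere is a coordinate, not sequence). Passing
recovery tests therefore demonstrate the *geometry* of the caller —
filter logic, clustering, clip placement, homology arithmetic — not
robustness to the mapping artefacts of real repetitive genomes.

## Published-case fixtures

The printed evidence of the motivating case (four discordant pairs; six
175-nt soft-clipped reads with full sequences and coordinates; the 7p15
and 7q21 windows) is shipped as checksummed package data. The six reads
mutually overlap, so plus-strand local reference segments
(chr7:27,762,299–27,762,425 and chr7:93,599,409–93,599,532) can be
reconstructed from them alone — aligned portions used as-is, minus-strand
clips reverse-complemented — with any overlap disagreement a hard error;
this removes the need for hg19 itself. FLAG and mate fields of the
fixture SAM are synthesised (only position/strand/MAPQ/CIGAR were
printed) to satisfy exactly the stated filters; the unpublished 50-bp
mate sequences travel as SEQ `*` stubs; the two reads found by visual
inspection rather than pairing are modelled as unpaired clip-bearing
records. The 7q21 window is taken as chr7:77,500,001–98,000,000,
consistent with its stated 20.5 Mb span.

## Limitations

* One inversion per run: the caller reconciles all junctions near the
  single best-supported cluster; nested or multiple rearrangements
  between the two windows would trip the consistency checks rather than
  be decomposed.
* The scan is restricted to two user-supplied windows by design;
  genome-wide discordant clustering and other SV classes (deletion,
  duplication, translocation signatures) are out of scope.
* Ungapped clip placement cannot represent junctions with inserted or
  deleted bases.
* The 609 genome-wide inter-region pairs and ~225 million aligned reads
  of the original dataset require the deposited sequencing run; at desk
  scale those counts are replaced by exhaustive-oracle equivalence tests
  and seeded full-parameter simulations (20 runs across homology lengths
  {0, 1, 2, 5}).
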