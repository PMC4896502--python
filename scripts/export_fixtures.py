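#!/usr/bin/env python
"""Materialise the embedded published-case fixtures as plain files.

Writes the evidence SAM, the two reconstructed local reference segments as
FASTA, and copies of the evidence TSV tables into a directory, so the
fixture inputs can be inspected or fed to external tools.

Usage:
    python scripts/export_fixtures.py --out fixtures_export/
"""

import argparse
import shutil
from importlib import resources
from pathlib import Path

import clipinv as ci
from clipinv.splitread import reconstruct_reference_segments


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fx = ci.load_fixtures()
    header, records = ci.build_fixture_sam(fx)
    ci.write_sam(args.out / "published.sam", records, header)

    seg_a, seg_b = reconstruct_reference_segments(fx.table2_reads)
    with open(args.out / "segments.fasta", "w") as fh:
        for name, seg in (("segment_7p15", seg_a), ("segment_7q21", seg_b)):
            fh.write(f">{name} {seg.interval}\n{seg.seq}\n")

    for name in ("table1_pairs.tsv", "table2_reads.tsv"):
        data = resources.files("clipinv.data").joinpath(name).read_bytes()
        (args.out / name).write_bytes(data)

    print(f"wrote published.sam, segments.fasta and evidence TSVs to {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
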