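#!/usr/bin/env python
"""Optional check against user-downloaded genome data.

Published genome-derived numbers (the 17-gene family on a specific
assembly release, absolute promoter motif totals, printed MW/pI values)
depend on the exact genome/proteome release and cannot be reproduced
from the package's synthetic data.  This script reruns the survey on
files the user has downloaded themselves:

    python scripts/external_validation.py \
        --genome genome.fa --gff genes.gff3 --proteome proteome.fa \
        [--pattern CONSENSUS ...] --out report.json

It is not part of the required acceptance surface and is never run
automatically.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from auxfam import family_identify as fi
from auxfam import io_core, promoter_scan as ps


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--genome", type=Path)
    parser.add_argument("--gff", type=Path)
    parser.add_argument("--proteome", type=Path, required=True)
    parser.add_argument(
        "--pattern", action="append", default=None,
        help="Conserved-region consensus (repeatable); defaults to the "
             "package's PB1-like blocks, which are tuned to synthetic "
             "data — real surveys should supply a family-specific "
             "consensus.",
    )
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    report: dict = {}
    proteins = io_core.read_fasta(args.proteome, alphabet="protein")
    patterns = (
        tuple(args.pattern) if args.pattern else fi.DEFAULT_FAMILY_PATTERNS
    )
    members = fi.scan_proteome(proteins, patterns=patterns)
    report["family_members_detected"] = len(members)
    report["member_ids"] = members

    if args.genome and args.gff:
        genome = io_core.read_fasta(args.genome, alphabet="dna")
        annotation = io_core.read_gff3(args.gff)
        keep = [g for g in annotation.genes if g.name in set(members)]
        proms = ps.extract_promoters(
            genome, io_core.AnnotationSet(keep), window=1000
        )
        hits = ps.scan_promoters(proms)
        report["motif_totals"] = ps.count_table(hits)
        report["motif_totals_aux1_excluded_from_aux2"] = ps.count_table(
            hits, exclude_aux1_from_aux2=True
        )

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(report, fh, indent=1)
    print(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
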