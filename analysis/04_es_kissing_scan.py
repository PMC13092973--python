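#!/usr/bin/env python
"""Expansion-segment hairpin / kissing-loop scan.

Folds each sequence of an expansion-segment FASTA panel, characterizes
its terminal stem-loop (stem length, loop length, loop GC), and scores
the loop against itself for antiparallel complementarity.  A flagged
(self-complementary) loop can form a reciprocal kissing contact with a
second copy of itself — the interaction geometry of a C2 ribosome
homodimer — whereas an inert loop cannot.

The packaged panel (analysis/data/synthetic_es_panel.fa) consists of
clearly-labelled synthetic stand-in sequences; point --fasta at a panel
of real rRNA expansion-segment sequences to run the same scan on them.

Usage: python analysis/04_es_kissing_scan.py [--fasta F.fa] [--allow-gu]
"""

import argparse
from pathlib import Path

from ribotopo import species_scan

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fasta", type=Path, default=HERE / "data" / "synthetic_es_panel.fa")
    ap.add_argument("--min-loop", type=int, default=3)
    ap.add_argument("--allow-gu", action="store_true",
                    help="allow GU wobble in the kissing register")
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    table = species_scan(args.fasta, min_loop=args.min_loop, allow_gu=args.allow_gu)
    out = RESULTS / "es_scan.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(table.drop(columns="dot_bracket").to_string(index=False))
    flagged = table[table["self_complementary"]]
    print(f"\n{len(flagged)}/{len(table)} records carry a self-complementary "
          f"terminal loop (kissing-capable, C2-homodimer geometry) -> {out}")


if __name__ == "__main__":
    main()
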