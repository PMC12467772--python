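#!/usr/bin/env python
"""Scan every transcript for its maximal contiguous match to the construct.

Bins genes at their maximum (classes are disjoint) from the 7 bp floor —
the shortest run reported to trigger interference — and verifies the
scan against the generator's ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from ota_sentinel.matchscan import classify_transcriptome, write_classes_tsv
from ota_sentinel.sequences import read_construct


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    construct = read_construct(args.datadir / "construct.fasta")
    classes, counts = classify_transcriptome(
        args.datadir / "transcriptome.fasta", construct, min_length=7
    )
    args.outdir.mkdir(parents=True, exist_ok=True)
    write_classes_tsv(args.outdir / "match_classes.tsv", classes)

    truth = pd.read_csv(args.datadir / "truth_matches.tsv", sep="\t")
    expected = truth[truth.planted_length > 0].planted_length \
        .value_counts().sort_index().to_dict()
    print("match-length ladder (scanned vs planted):")
    for length in sorted(counts):
        flag = "ok" if counts[length] == expected.get(length) else "MISMATCH"
        print(f"  {length:>3} bp  {counts[length]:>4} genes  ({flag})")
    print(f"total genes with a match >= 7 bp: {len(classes)}")
    assert counts == expected, "scanner disagrees with planted ground truth"


if __name__ == "__main__":
    main()
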