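#!/usr/bin/env python
"""Screen the count matrix for regulated genes, one stage at a time.

A gene is a DEG when |log2 fold change| > 1 and BH-FDR < 0.05 (sign gives
direction).  Prints per-stage DEG counts and how many planted knockdowns
the screen found.
"""

import argparse
from pathlib import Path

import pandas as pd

from ota_sentinel.expression import read_counts, simple_de_screen, write_deg_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts, sheet = read_counts(args.datadir / "counts.tsv",
                                args.datadir / "samples.tsv")
    truth = pd.read_csv(args.datadir / "truth_degs.tsv", sep="\t")
    args.outdir.mkdir(parents=True, exist_ok=True)
    for stage in dict.fromkeys(sheet["stage"]):
        degs = simple_de_screen(counts, sheet, stage=stage)
        write_deg_table(args.outdir / f"degs_{stage}.tsv", degs)
        n_up = sum(d.status == "up" for d in degs)
        n_down = sum(d.status == "down" for d in degs)
        planted = set(truth.loc[truth.stage == stage, "gene_id"])
        found = {d.gene_id for d in degs if d.status != "ns"} & planted
        print(f"{stage}: {n_up} up, {n_down} down "
              f"({len(found)}/{len(planted)} planted knockdowns recovered)")


if __name__ == "__main__":
    main()
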