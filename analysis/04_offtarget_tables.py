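#!/usr/bin/env python
"""Cross-tabulate matches vs regulation, correlate, and ring out pathways.

Per stage: the per-length silencing cross-table (one row per maximal
match length plus a Total row), the rank correlation between match
length and |log2FC|, the construct homolog search, the pathway
level-2/3 table around the seed gene, and hypergeometric enrichment of
the DEG set.
"""

import argparse
from pathlib import Path

from ota_sentinel.expression import read_deg_table
from ota_sentinel.matchscan import read_classes_tsv
from ota_sentinel.offtarget import (correlate_match_foldchange,
                                    crosstab_matches, crosstab_to_frame,
                                    enrich_hypergeometric, find_homologs,
                                    level_table, pathway_levels)
from ota_sentinel.sequences import read_construct, read_fasta
from ota_sentinel.simulate import read_gmt


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed-gene", default="g0001")
    args = ap.parse_args()

    classes = read_classes_tsv(args.outdir / "match_classes.tsv")
    annotation = read_gmt(args.datadir / "pathways.gmt")
    universe = {gene_id for gene_id, _ in read_fasta(args.datadir / "transcriptome.fasta")}

    construct = read_construct(args.datadir / "construct.fasta")
    hits = find_homologs(construct.sense, args.datadir / "transcriptome.fasta",
                         evalue_threshold=1e-10, query_id=construct.id)
    print(f"construct homologs at E < 1e-10: {len(hits)} "
          "(a clean construct should find none)")

    levels = pathway_levels(annotation, {args.seed_gene})
    print(f"pathway ring around {args.seed_gene}: "
          + ", ".join(f"level {l}: {sum(1 for v in levels.values() if v == l)} genes"
                      for l in sorted(set(levels.values()))))

    for stage in ("larva", "adult"):
        degs = read_deg_table(args.outdir / f"degs_{stage}.tsv")
        ct = crosstab_matches(classes, degs)
        crosstab_to_frame(ct).to_csv(args.outdir / f"crosstab_{stage}.tsv",
                                     sep="\t", index=False)
        total = ct[-1]
        print(f"\n{stage} cross-table Total: {total.n_total} matched genes, "
              f"{total.n_up} up ({total.pct_up}%), {total.n_down} down "
              f"({total.pct_down}%), {total.n_ns} ns ({total.pct_ns}%)")

        corr = correlate_match_foldchange(classes, degs)
        corr.table.to_csv(args.outdir / f"scatter_{stage}.tsv", sep="\t", index=False)
        print(f"{stage} match length vs |log2FC|: rho = {corr.coefficient:.3f} "
              f"(p = {corr.pvalue:.3g}, n = {corr.n})")

        lt = level_table(levels, degs)
        crosstab_to_frame(lt).to_csv(args.outdir / f"level_table_{stage}.tsv",
                                     sep="\t", index=False)
        deg_set = {d.gene_id for d in degs if d.status != "ns"} & universe
        if deg_set:
            enr = enrich_hypergeometric(deg_set, annotation, universe)
            enr.to_csv(args.outdir / f"enrichment_{stage}.tsv", sep="\t", index=False)
            top = enr.iloc[0]
            print(f"{stage} top enriched pathway: {top.term} "
                  f"(overlap {top.n_overlap}, p = {top.pvalue:.3g})")


if __name__ == "__main__":
    main()
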