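# ota-sentinel

Off-target risk assessment for RNAi crops on non-target insects.

RNAi crops express a double-stranded RNA (here modelled after a 432 bp
construct) that silences a pest gene; regulators ask what that dsRNA does
to the beneficial insects that eat the pest. Bioassays catch gross
effects, but sublethal off-target silencing has to be read from the
transcriptome. `ota-sentinel` packages that computation for researchers
and risk assessors:

* **Match scanning** — for every transcript, the maximal contiguous
  exact match to either strand of the construct (interference can be
  triggered by runs as short as 7 bp); genes are binned by that maximum
  into disjoint per-length classes.
* **Expression screen** — a gene is a DEG when |log2FC| > 1 and BH-FDR
  < 0.05; counts are screened per stage (larva/adult) against controls,
  or an external DESeq2-style table is imported. The 2^−ΔΔCt qPCR
  calculation is included for validation work.
* **Off-target tables** — match classes cross-tabulated against
  regulation status (counts + half-up 2-decimal percentages with a Total
  row); Spearman correlation of match length vs |log2FC|.
* **Homology** — a seed-and-extend local aligner with Karlin–Altschul
  E-values (E = K·m·n·e^(−λS)) asks whether the construct has a
  homologous fragment in the transcriptome; global-alignment percent
  identity for pairwise homology statements.
* **Pathway levels** — breadth-first rings around the target-homolog
  genes (level 1 = their pathways, level 2 = pathways sharing genes with
  level-1 genes, …) cross-tabulated against regulation; hypergeometric
  enrichment.
* **Transcriptome homeostasis** — per-sample Shannon entropy
  H = −Σ p_i log2 p_i over expression proportions, compared between
  groups by Student's t-test.
* **Synthetic data** — a seeded generator fabricates every input
  (transcriptome with oracle-verified planted matches, negative-binomial
  counts with planted fold changes, chain-structured pathway sets) so the
  whole pipeline is testable without sequencing data.

See `docs/methods.md` for the models, defaults and numerical decisions.

## Worked example

The numbered scripts under `analysis/` run the demo assessment end to
end (a 300-gene transcriptome with a planted 7–15 bp match ladder, and
2 larval / 8 adult knockdowns at log2FC −3):

```bash
python analysis/01_simulate.py          # writes results/data/
python analysis/02_scan_matches.py
python analysis/03_expression_screen.py
python analysis/04_offtarget_tables.py
python analysis/05_entropy_homeostasis.py
```

which prints (seed 7):

```
match-length ladder (scanned vs planted):
    7 bp    55 genes  (ok)
    8 bp    37 genes  (ok)
    9 bp    13 genes  (ok)
   10 bp     3 genes  (ok)
   ...
total genes with a match >= 7 bp: 113

larva: 0 up, 2 down (2/2 planted knockdowns recovered)
adult: 0 up, 3 down (3/8 planted knockdowns recovered)

construct homologs at E < 1e-10: 0 (a clean construct should find none)
larva cross-table Total: 113 matched genes, 0 up (0.0%), 0 down (0.0%), 113 ns (100.0%)
larva match length vs |log2FC|: rho = 0.013 (p = 0.888, n = 113)
larva: H(treatment) = 7.328 +/- 0.002, H(control) = 7.336 +/- 0.019, t = -0.784, p = 0.477
```

Read: every planted match class is recovered exactly; the screen finds
both larval knockdowns (the adult ones at low expression stay below
3-replicate power, deliberately — see the methods note); none of the
matched genes is regulated, match length does not predict fold change,
the construct has no transcriptome homolog, and entropy is stable — the
profile of a construct with no off-target signal.

The same stages are available as a library (`import ota_sentinel`) and
as a CLI (`ota-sentinel simulate|scan|deg|crosstab|correlate|homologs|
levels|enrich|entropy|run`); `ota-sentinel run --config cfg.yaml
--outdir out/` executes everything from one declarative config and
writes a manifest with input digests for reproducible runs.

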