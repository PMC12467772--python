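"""End-to-end orchestration: simulate -> scan -> screen -> assess -> entropy.

One declarative YAML config drives a full run; every stage writes its
table under the output directory, a manifest records input digests and
seeds, and a summary report collects the headline numbers (match-length
cross-table, pathway level table, match/fold-change correlation, entropy
comparison, DEG counts per stage).  Runs are deterministic: the same
config produces byte-identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .entropy import compare_entropy, entropy_per_sample
from .expression import (read_counts, read_deg_table, simple_de_screen,
                         write_deg_table)
from .matchscan import classify_transcriptome, write_classes_tsv
from .offtarget import (AlignmentParams, correlate_match_foldchange,
                        crosstab_matches, crosstab_to_frame,
                        enrich_hypergeometric, find_homologs, level_table,
                        pathway_levels)
from .sequences import read_construct
from .simulate import config_from_yaml, read_gmt, write_dataset

log = logging.getLogger("ota_sentinel")


class ValidationError(ValueError):
    """Configuration or input problem detected before any stage runs."""


@dataclasses.dataclass(frozen=True)
class ExposureConfig:
    """Worst-case dietary exposure arithmetic.

    The in-planta dsRNA expression level is multiplied by a worst-case
    factor (regulatory practice: at least 10x the field concentration)
    to set the diet dose.  Defaults: 0.7 ug/g in leaf tissue, 10x.
    """

    field_expression_ug_per_g: float = 0.7
    worst_case_factor: float = 10.0

    @property
    def worst_case_dose_ug_per_g(self) -> float:
        return self.field_expression_ug_per_g * self.worst_case_factor


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_pipeline_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"pipeline config {path} must be a mapping")
    return cfg


def _validate(cfg: dict[str, Any], config_dir: Path) -> dict[str, Path]:
    """Resolve and existence-check every referenced input before running."""
    inputs = cfg.get("inputs") or {}
    resolved: dict[str, Path] = {}
    for key, value in inputs.items():
        p = Path(value)
        if not p.is_absolute():
            p = config_dir / p
        if not p.exists():
            raise ValidationError(f"input {key!r}: file not found: {p}")
        resolved[key] = p
    if "simulate" not in cfg:
        for key in ("construct", "transcriptome", "counts", "samples"):
            if key not in resolved:
                raise ValidationError(
                    f"no 'simulate' section and no inputs.{key} supplied"
                )
    return resolved


def run_pipeline(config_path: str | Path, outdir: str | Path) -> dict[str, Any]:
    """Run every stage; returns the manifest dict (also written to disk)."""
    t0 = time.time()
    config_path = Path(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = load_pipeline_config(config_path)
    inputs = _validate(cfg, config_path.parent)

    manifest: dict[str, Any] = {
        "tool_version": __version__,
        "config": cfg,
        "config_digest": _sha256(config_path),
        "stages": {},
        "completed": False,
    }

    def stage_done(name: str, paths: dict[str, Path]) -> None:
        manifest["stages"][name] = {k: str(p) for k, p in paths.items()}
        log.info("[%s] wrote %s", name, ", ".join(str(p) for p in paths.values()))

    try:
        # -- simulate ------------------------------------------------------
        if "simulate" in cfg:
            sim_cfg = config_from_yaml(yaml.safe_dump(cfg["simulate"]))
            data_paths = write_dataset(sim_cfg, outdir / "data")
            inputs = {**data_paths, **inputs}
            manifest["seed"] = sim_cfg.seed
            stage_done("simulate", data_paths)

        construct = read_construct(inputs["construct"])
        scan_cfg = cfg.get("scan") or {}
        min_len = int(scan_cfg.get("min_length", 7))

        # -- scan ----------------------------------------------------------
        classes, length_counts = classify_transcriptome(
            inputs["transcriptome"], construct, min_length=min_len
        )
        classes_path = outdir / "match_classes.tsv"
        write_classes_tsv(classes_path, classes)
        counts_path = outdir / "match_length_counts.tsv"
        with open(counts_path, "w") as fh:
            fh.write("match_length\tn_genes\n")
            for length, n in length_counts.items():
                fh.write(f"{length}\t{n}\n")
        stage_done("scan", {"classes": classes_path, "length_counts": counts_path})

        # -- expression screen (per stage) --------------------------------
        deg_cfg = cfg.get("deg") or {}
        lfc = float(deg_cfg.get("lfc", 1.0))
        fdr = float(deg_cfg.get("fdr", 0.05))
        counts, sheet = read_counts(inputs["counts"], inputs["samples"])
        stages = list(dict.fromkeys(sheet["stage"]))
        degs_by_stage = {}
        deg_paths: dict[str, Path] = {}
        for st in stages:
            if "deg_table" in inputs:
                degs = read_deg_table(inputs["deg_table"],
                                      lfc_threshold=lfc, fdr_threshold=fdr)
            else:
                degs = simple_de_screen(counts, sheet, stage=st,
                                        lfc_threshold=lfc, fdr_threshold=fdr)
            degs_by_stage[st] = degs
            p = outdir / f"degs_{st}.tsv"
            write_deg_table(p, degs)
            deg_paths[st] = p
        stage_done("deg", deg_paths)

        # -- cross-tab + correlation per stage ----------------------------
        report: dict[str, Any] = {"stages": {}}
        for st in stages:
            degs = degs_by_stage[st]
            ct = crosstab_matches(classes, degs, min_length=min_len)
            ct_path = outdir / f"crosstab_{st}.tsv"
            crosstab_to_frame(ct).to_csv(ct_path, sep="\t", index=False)
            corr = correlate_match_foldchange(classes, degs, min_length=min_len)
            corr.table.to_csv(outdir / f"scatter_{st}.tsv", sep="\t", index=False)
            report["stages"][st] = {
                "n_up": sum(1 for d in degs if d.status == "up"),
                "n_down": sum(1 for d in degs if d.status == "down"),
                "crosstab_total": dataclasses.asdict(ct[-1]),
                "correlation": {"rho": corr.coefficient, "p": corr.pvalue,
                                "n": corr.n, "degenerate": corr.degenerate},
            }
        stage_done("crosstab", {st: outdir / f"crosstab_{st}.tsv" for st in stages})

        # -- homologs ------------------------------------------------------
        hom_cfg = cfg.get("homologs") or {}
        params = AlignmentParams(
            word_size=int(hom_cfg.get("word_size", 11)),
            x_drop=int(hom_cfg.get("x_drop", 20)),
        )
        evalue_threshold = float(hom_cfg.get("evalue", 1e-10))
        hits = find_homologs(construct.sense, inputs["transcriptome"], params,
                             evalue_threshold=evalue_threshold,
                             query_id=construct.id)
        hits_path = outdir / "homolog_hits.tsv"
        with open(hits_path, "w") as fh:
            fh.write("query_id\tsubject_id\tscore\tbit_score\tidentity\t"
                     "evalue\tstrand\n")
            for h in hits:
                fh.write(f"{h.query_id}\t{h.subject_id}\t{h.score}\t"
                         f"{h.bit_score:.2f}\t{h.identity:.2f}\t{h.evalue:.3g}\t"
                         f"{h.strand}\n")
        report["n_homolog_hits"] = len(hits)
        stage_done("homologs", {"hits": hits_path})

        # -- pathway levels ------------------------------------------------
        if "pathways" in inputs:
            annotation = read_gmt(inputs["pathways"])
            lvl_cfg = cfg.get("levels") or {}
            seeds = lvl_cfg.get("seed_genes") or [h.subject_id for h in hits]
            level_paths: dict[str, Path] = {}
            if seeds:
                levels = pathway_levels(annotation, seeds,
                                        max_level=int(lvl_cfg.get("max_level", 3)))
                for st in stages:
                    lt = level_table(levels, degs_by_stage[st])
                    p = outdir / f"level_table_{st}.tsv"
                    crosstab_to_frame(lt).to_csv(p, sep="\t", index=False)
                    level_paths[st] = p
                    report["stages"][st]["level_total"] = dataclasses.asdict(lt[-1])
                report["n_leveled_genes"] = len(levels)
            else:
                report["n_leveled_genes"] = 0
                log.info("[levels] no seed genes (no homolog hits); stage skipped")
            stage_done("levels", level_paths if seeds else {})

            # -- enrichment ------------------------------------------------
            universe = set(counts.index.astype(str))
            enrich_paths: dict[str, Path] = {}
            for st in stages:
                deg_set = {d.gene_id for d in degs_by_stage[st]
                           if d.status != "ns"} & universe
                if deg_set:
                    enr = enrich_hypergeometric(deg_set, annotation, universe)
                    p = outdir / f"enrichment_{st}.tsv"
                    enr.to_csv(p, sep="\t", index=False)
                    enrich_paths[st] = p
            stage_done("enrich", enrich_paths)

        # -- entropy -------------------------------------------------------
        ent_rows = []
        for st in stages:
            sub = sheet[sheet["stage"] == st]
            groups = list(dict.fromkeys(sub["group"]))
            per_group = {}
            for g in groups:
                ids = sub.loc[sub["group"] == g, "sample_id"].tolist()
                per_group[g] = entropy_per_sample(counts[ids])
            for g, results in per_group.items():
                ent_rows += [{"sample_id": r.sample_id, "stage": st, "group": g,
                              "H": r.H, "n_expressed": r.n_expressed}
                             for r in results]
            if len(groups) == 2:
                cmp_res = compare_entropy(per_group[groups[0]], per_group[groups[1]])
                report["stages"][st]["entropy"] = dataclasses.asdict(cmp_res)
        ent_path = outdir / "entropy.tsv"
        with open(ent_path, "w") as fh:
            fh.write("sample_id\tstage\tgroup\tH\tn_expressed\n")
            for r in ent_rows:
                fh.write(f"{r['sample_id']}\t{r['stage']}\t{r['group']}\t"
                         f"{r['H']:.6f}\t{r['n_expressed']}\n")
        stage_done("entropy", {"entropy": ent_path})

        # -- exposure + report --------------------------------------------
        exp_cfg = cfg.get("exposure") or {}
        exposure = ExposureConfig(**exp_cfg)
        report["exposure"] = {
            "field_expression_ug_per_g": exposure.field_expression_ug_per_g,
            "worst_case_factor": exposure.worst_case_factor,
            "worst_case_dose_ug_per_g": exposure.worst_case_dose_ug_per_g,
        }
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        text_path = outdir / "report.txt"
        text_path.write_text(_render_report(report))
        stage_done("report", {"json": report_path, "text": text_path})
        manifest["completed"] = True
    except Exception:
        manifest["completed"] = False
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    manifest["input_digests"] = {k: _sha256(p) for k, p in sorted(inputs.items())}
    manifest["elapsed_seconds"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _render_report(report: dict[str, Any]) -> str:
    lines = ["off-target assessment summary", "=" * 29, ""]
    for st, r in report.get("stages", {}).items():
        lines.append(f"stage: {st}")
        lines.append(f"  DEGs: {r['n_up']} up, {r['n_down']} down")
        tot = r["crosstab_total"]
        lines.append(
            f"  matched genes (>= min length): {tot['n_total']}"
            f" | up {tot['n_up']} ({tot['pct_up']}%)"
            f" | down {tot['n_down']} ({tot['pct_down']}%)"
            f" | ns {tot['n_ns']} ({tot['pct_ns']}%)"
        )
        c = r["correlation"]
        lines.append(f"  match-length vs |log2FC| rho = {c['rho']:.3f} (p = {c['p']:.3g})")
        if "entropy" in r:
            e = r["entropy"]
            lines.append(
                f"  entropy: {e['mean_a']:.3f} +/- {e['sd_a']:.3f} vs"
                f" {e['mean_b']:.3f} +/- {e['sd_b']:.3f}"
                f" (t = {e['t_statistic']:.3f}, p = {e['pvalue']:.3f})"
            )
        lines.append("")
    lines.append(f"homolog hits at threshold: {report.get('n_homolog_hits', 0)}")
    exp = report.get("exposure", {})
    if exp:
        lines.append(
            f"worst-case diet dose: {exp['field_expression_ug_per_g']} ug/g x "
            f"{exp['worst_case_factor']:g} = {exp['worst_case_dose_ug_per_g']:g} ug/g"
        )
    return "\n".join(lines) + "\n"
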