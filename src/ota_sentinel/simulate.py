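"""Synthetic study-data generator.

Fabricates every input the off-target pipeline needs, with full seed
control, so each downstream stage is testable without sequencing data:

* a non-target transcriptome in which a chosen number of genes carry a
  planted contiguous match of controlled *maximal* length (7–15+ nt) to a
  chosen strand of the dsRNA construct, all other genes verified to stay
  below the reporting floor;
* a negative-binomial count matrix (treatment vs control, larva and adult
  stages, three replicates each) with planted log2 fold changes for a
  chosen DEG subset;
* overlapping pathway gene sets arranged as a chain around a seed gene so
  that a breadth-first level-1/2/3 neighbourhood structure is realised by
  construction.

Every planted match is verified against the dynamic-programming
longest-common-substring oracle; accidental longer matches trigger
resampling (budget 100 attempts per gene) so requested class sizes stay
exact.  Ground-truth tables accompany every artefact.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .matchscan import DEFAULT_MIN_MATCH, lcs_length_both_strands
from .sequences import DsRNAConstruct, gen_dsrna, write_fasta

_RESAMPLE_BUDGET = 100
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Infeasible or ill-formed simulation configuration."""


@dataclasses.dataclass(frozen=True)
class PlantedMatch:
    """Request for ``n_genes`` genes whose maximal match is exactly ``length``."""

    length: int
    n_genes: int
    strand: str = "sense"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ConfigError("planted match length must be >= 1")
        if self.n_genes < 0:
            raise ConfigError("planted n_genes must be >= 0")
        if self.strand not in ("sense", "antisense"):
            raise ConfigError(f"unknown strand {self.strand!r}")


@dataclasses.dataclass(frozen=True)
class PathwaySpec:
    """Chain of pathways: each shares a fixed fraction of genes with its predecessor."""

    n_pathways: int = 4
    genes_per_pathway: int = 25
    overlap_fraction: float = 0.2
    seed_gene: str | None = None  # default: first pathway's first member
    place_seed: bool = True       # False: seed left out of every pathway

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ConfigError(
                f"overlap_fraction must be in [0, 1], got {self.overlap_fraction}"
            )
        if self.n_pathways < 1 or self.genes_per_pathway < 1:
            raise ConfigError("pathway counts must be >= 1")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one synthetic dataset; a fixed seed yields byte-identical files.

    ``planted_matches`` emulates the per-length gene classes of the study's
    match table at desk scale; ``planted_degs`` maps stage -> list of
    (gene_id, log2 fold change) emulating the handful of regulated genes
    observed per stage.  Counts use a single shared NB dispersion.
    """

    seed: int = 0
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (200, 400)
    dsrna_length: int = 432
    planted_matches: tuple[PlantedMatch, ...] = ()
    n_replicates: int = 3
    groups: tuple[str, str] = ("treatment", "control")
    stages: tuple[str, ...] = ("larva", "adult")
    nb_mean_log_range: tuple[float, float] = (1.0, 3.0)  # log10 of baseline mean
    nb_dispersion: float = 0.05
    planted_degs: Mapping[str, Sequence[tuple[str, float]]] = dataclasses.field(
        default_factory=dict
    )
    pathway_spec: PathwaySpec = dataclasses.field(default_factory=PathwaySpec)
    background_max_match: int = DEFAULT_MIN_MATCH  # background genes stay below this

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.dsrna_length < 1:
            raise ConfigError("dsrna_length must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.n_replicates < 2:
            raise ConfigError("need >= 2 replicates per group")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"bad gene_length_range {self.gene_length_range}")
        for pm in self.planted_matches:
            if pm.length > self.dsrna_length:
                raise ConfigError(
                    f"planted match of {pm.length} nt exceeds construct length"
                    f" {self.dsrna_length}"
                )
            if pm.length > lo:
                raise ConfigError(
                    f"planted match of {pm.length} nt exceeds shortest gene ({lo} nt)"
                )
            if pm.length < self.background_max_match:
                raise ConfigError(
                    f"planted match length {pm.length} is below the background"
                    f" exclusion floor {self.background_max_match}; exact-length"
                    " planting below that floor is not statistically realisable"
                )
        n_planted = sum(pm.n_genes for pm in self.planted_matches)
        if n_planted > self.n_genes:
            raise ConfigError(
                f"{n_planted} planted genes requested but only {self.n_genes} genes"
            )

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def demo_config(seed: int = 0) -> SimulationConfig:
    """The bundled demo: the study's match-length ladder scaled down ~100x.

    Class sizes follow the proportions of the study transcriptome's
    per-length table (7 bp most common, single gene at 15 bp), with every
    length 7–15 represented.  Two genes are knocked down in larvae and
    eight in adults, mirroring the observed per-stage DEG counts.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=300,
        planted_matches=(
            PlantedMatch(7, 55, "sense"),
            PlantedMatch(8, 37, "antisense"),
            PlantedMatch(9, 13, "sense"),
            PlantedMatch(10, 3, "antisense"),
            PlantedMatch(11, 1, "sense"),
            PlantedMatch(12, 1, "antisense"),
            PlantedMatch(13, 1, "sense"),
            PlantedMatch(14, 1, "antisense"),
            PlantedMatch(15, 1, "sense"),
        ),
    )
    ids = cfg.gene_ids()
    planted_degs = {
        "larva": [(g, -3.0) for g in ids[200:202]],
        "adult": [(g, -3.0) for g in ids[200:208]],
    }
    return dataclasses.replace(
        cfg,
        planted_degs=planted_degs,
        pathway_spec=PathwaySpec(n_pathways=4, genes_per_pathway=25,
                                 overlap_fraction=0.2, seed_gene=ids[0]),
    )


# ---------------------------------------------------------------------------
# transcriptome with planted matches


def _background_gene(rng: np.random.Generator, length: int,
                     forbidden: set[bytes], k: int) -> str:
    """Random A/C/G/T sequence avoiding every construct *k*-mer.

    Bases are drawn left to right; when the trailing window would hit a
    construct k-mer the base is redrawn from the remaining alphabet.  The
    avoidance keeps acceptance high for genes of any length; the oracle
    check downstream remains authoritative.
    """
    while True:
        buf = bytearray(rng.choice(_BASES, size=length).tobytes())
        ok = True
        for i in range(k - 1, length):
            if bytes(buf[i - k + 1 : i + 1]) in forbidden:
                choices = list(rng.permutation(_BASES))
                for b in choices:
                    buf[i] = b
                    if bytes(buf[i - k + 1 : i + 1]) not in forbidden:
                        break
                else:
                    ok = False
                    break
        if ok:
            return buf.decode("ascii")


def _construct_kmers(construct: DsRNAConstruct, k: int) -> set[bytes]:
    kmers: set[bytes] = set()
    for _, seq in construct.strands:
        b = seq.encode("ascii")
        for i in range(len(b) - k + 1):
            kmers.add(b[i : i + k])
    return kmers


def gen_transcriptome_with_planted_matches(
    config: SimulationConfig, construct: DsRNAConstruct
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate the transcriptome and its ground-truth match table.

    Returns ``(records, truth)`` where records are (gene_id, sequence)
    pairs and ``truth`` has columns gene_id, planted_length (0 for
    background), strand, oracle_max — with ``oracle_max`` recomputed for
    every gene by the DP oracle, never assumed.
    """
    if len(construct) != config.dsrna_length:
        raise ConfigError(
            f"construct length {len(construct)} != configured {config.dsrna_length}"
        )
    rng = np.random.default_rng([config.seed, 101])
    k = config.background_max_match
    forbidden = _construct_kmers(construct, k)
    ids = config.gene_ids()
    lo, hi = config.gene_length_range

    assignments: list[tuple[int, str]] = []  # (planted length, strand) per planted gene
    for pm in config.planted_matches:
        assignments.extend([(pm.length, pm.strand)] * pm.n_genes)
    assignments.extend([(0, "")] * (config.n_genes - len(assignments)))

    records: list[tuple[str, str]] = []
    rows = []
    for gene_id, (planted_len, strand) in zip(ids, assignments):
        length = int(rng.integers(lo, hi + 1))
        for attempt in range(_RESAMPLE_BUDGET):
            seq = _background_gene(rng, length, forbidden, k)
            if planted_len:
                source = construct.sense if strand == "sense" else construct.antisense
                off = int(rng.integers(0, len(source) - planted_len + 1))
                pos = int(rng.integers(0, length - planted_len + 1))
                seq = seq[:pos] + source[off : off + planted_len] + seq[pos + planted_len :]
                target = planted_len
            else:
                target_lt = k  # background: anything below the floor
                target = None
            oracle = lcs_length_both_strands(seq, construct)
            if (oracle == target) if planted_len else (oracle < target_lt):
                records.append((gene_id, seq))
                rows.append(
                    {"gene_id": gene_id, "planted_length": planted_len,
                     "strand": strand, "oracle_max": oracle}
                )
                break
        else:
            raise RuntimeError(
                f"resample budget ({_RESAMPLE_BUDGET}) exhausted planting a "
                f"{planted_len}-nt match in gene {gene_id!r}"
            )
    truth = pd.DataFrame(rows)
    return records, truth


# ---------------------------------------------------------------------------
# counts


def _planted_degs_for_stage(config: SimulationConfig, stage: str
                            ) -> dict[str, float]:
    table = config.planted_degs or {}
    if stage not in table:
        return {}
    out: dict[str, float] = {}
    for gene_id, lfc in table[stage]:
        if gene_id in out:
            raise ConfigError(f"gene {gene_id!r} planted twice for stage {stage!r}")
        out[gene_id] = float(lfc)
    return out


def gen_counts(config: SimulationConfig
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted fold changes.

    Returns (counts genes x samples, sample sheet, ground-truth DEG table).
    Baseline means are drawn per gene from 10**Uniform(nb_mean_log_range)
    and shared across stages; for a planted (gene, stage) pair the
    treatment-group mean is multiplied by 2**log2fc.  Variance follows
    var = mu + dispersion * mu^2 with one dispersion for the whole run.
    """
    rng = np.random.default_rng([config.seed, 202])
    ids = config.gene_ids()
    known = set(ids)
    for stage, pairs in (config.planted_degs or {}).items():
        if stage not in config.stages:
            raise ConfigError(f"planted DEG stage {stage!r} not in stages {config.stages}")
        for gene_id, _ in pairs:
            if gene_id not in known:
                raise ConfigError(f"planted DEG gene {gene_id!r} not in transcriptome")

    lo, hi = config.nb_mean_log_range
    base_mean = 10.0 ** rng.uniform(lo, hi, size=config.n_genes)
    r = 1.0 / config.nb_dispersion  # NB size: var = mu + mu^2 / r

    samples = []
    columns: dict[str, np.ndarray] = {}
    treatment = config.groups[0]
    for stage in config.stages:
        planted = _planted_degs_for_stage(config, stage)
        lfc = np.zeros(config.n_genes)
        for i, g in enumerate(ids):
            if g in planted:
                lfc[i] = planted[g]
        for group in config.groups:
            mu = base_mean * (2.0 ** lfc) if group == treatment else base_mean
            p = r / (r + mu)
            for rep in range(1, config.n_replicates + 1):
                sid = f"{group}_{stage}_r{rep}"
                columns[sid] = rng.negative_binomial(r, p)
                samples.append(
                    {"sample_id": sid, "group": group, "stage": stage, "replicate": rep}
                )
    counts = pd.DataFrame(columns, index=pd.Index(ids, name="gene_id"))
    sample_sheet = pd.DataFrame(samples)
    truth_rows = [
        {"gene_id": g, "stage": stage, "log2fc": float(l)}
        for stage in config.stages
        for g, l in _planted_degs_for_stage(config, stage).items()
    ]
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "stage", "log2fc"])
    return counts, sample_sheet, truth


# ---------------------------------------------------------------------------
# pathways


def gen_pathways(config: SimulationConfig
                 ) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Chain-structured pathway gene sets realising a level-1/2/3 neighbourhood.

    Pathway ``i`` shares ``round(overlap_fraction * genes_per_pathway)``
    genes with pathway ``i-1`` and otherwise draws fresh genes, so genes
    first appearing in pathway ``i`` sit at breadth-first level ``i+1``
    from the seed gene (placed in pathway 0).  Returns the GMT-style
    mapping and the intended gene -> level map for parameter-recovery
    tests (empty when the seed gene is placed in no pathway).
    """
    spec = config.pathway_spec
    rng = np.random.default_rng([config.seed, 303])
    ids = config.gene_ids()
    seed_gene = spec.seed_gene or ids[0]

    gpp = spec.genes_per_pathway
    n_overlap = min(int(round(spec.overlap_fraction * gpp)), gpp - 1)
    pool = list(rng.permutation([g for g in ids if g != seed_gene]))
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        if cursor + n > len(pool):
            raise ConfigError(
                f"pathway spec needs more than {config.n_genes} distinct genes"
            )
        out = pool[cursor : cursor + n]
        cursor += n
        return out

    if spec.place_seed:
        members0 = [seed_gene] + take(gpp - 1)
    else:
        members0 = take(gpp)
    pathways: dict[str, list[str]] = {"PW0001": sorted(members0)}
    intended: dict[str, int] = {g: 1 for g in members0} if spec.place_seed else {}
    # carried genes come only from the previous ring's fresh genes (never the
    # seed gene), so genes first seen in pathway i sit at BFS level i+1 exactly
    prev_fresh = [g for g in members0 if g != seed_gene]
    connected = True
    for i in range(1, spec.n_pathways):
        k_i = min(n_overlap, len(prev_fresh))
        carried = sorted(rng.choice(prev_fresh, size=k_i, replace=False)) if k_i else []
        fresh = take(gpp - k_i)
        pathways[f"PW{i + 1:04d}"] = sorted(carried + fresh)
        if k_i == 0:
            connected = False
        if connected:
            for g in fresh:
                intended.setdefault(g, i + 1)
        prev_fresh = fresh
    if seed_gene not in set().union(*map(set, pathways.values())):
        intended = {}
    return pathways, intended


# ---------------------------------------------------------------------------
# serialization


def write_gmt(path: str | Path, pathways: Mapping[str, Sequence[str]],
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in pathways:
            desc = (descriptions or {}).get(name, name)
            fh.write("\t".join([name, desc, *pathways[name]]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs id, description, >=1 gene")
            if parts[0] in out:
                raise ValueError(f"{path}:{ln}: duplicate pathway id {parts[0]!r}")
            out[parts[0]] = set(parts[2:])
    return out


def config_to_yaml(config: SimulationConfig) -> str:
    d = dataclasses.asdict(config)
    d["planted_matches"] = [list(dataclasses.astuple(pm)) for pm in config.planted_matches]
    d["planted_degs"] = {
        stage: [[g, float(l)] for g, l in pairs]
        for stage, pairs in (config.planted_degs or {}).items()
    }
    d["pathway_spec"] = dataclasses.asdict(config.pathway_spec)
    return yaml.safe_dump(d, sort_keys=True)


def config_from_yaml(text: str) -> SimulationConfig:
    d = yaml.safe_load(text)
    d["planted_matches"] = tuple(PlantedMatch(*pm) for pm in d.get("planted_matches", []))
    d["planted_degs"] = {
        stage: [(g, float(l)) for g, l in pairs]
        for stage, pairs in (d.get("planted_degs") or {}).items()
    }
    d["pathway_spec"] = PathwaySpec(**d.get("pathway_spec", {}))
    for key in ("gene_length_range", "nb_mean_log_range", "groups", "stages"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every artefact; returns a name -> path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    construct = gen_dsrna(config.dsrna_length, config.seed, construct_id="ds_construct")
    transcriptome, truth_matches = gen_transcriptome_with_planted_matches(
        config, construct
    )
    counts, sample_sheet, truth_degs = gen_counts(config)
    pathways, intended = gen_pathways(config)

    paths = {
        "config": outdir / "config.yaml",
        "construct": outdir / "construct.fasta",
        "transcriptome": outdir / "transcriptome.fasta",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "pathways": outdir / "pathways.gmt",
        "truth_matches": outdir / "truth_matches.tsv",
        "truth_degs": outdir / "truth_degs.tsv",
        "intended_levels": outdir / "intended_levels.tsv",
    }
    paths["config"].write_text(config_to_yaml(config))
    write_fasta(paths["construct"], [(construct.id, construct.sense)])
    write_fasta(paths["transcriptome"], transcriptome)
    counts.to_csv(paths["counts"], sep="\t")
    sample_sheet.to_csv(paths["samples"], sep="\t", index=False)
    write_gmt(paths["pathways"], pathways)
    truth_matches.to_csv(paths["truth_matches"], sep="\t", index=False)
    truth_degs.to_csv(paths["truth_degs"], sep="\t", index=False)
    with open(paths["intended_levels"], "w") as fh:
        fh.write("gene_id\tlevel\n")
        for g in sorted(intended):
            fh.write(f"{g}\t{intended[g]}\n")
    return paths
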