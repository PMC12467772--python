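"""Off-target assessment: cross-tabulation, correlation, homology, pathways.

This module holds the study-level analyses that sit on top of the match
scanner and the expression screen:

* :func:`crosstab_matches` — genes binned by maximal contiguous match
  length, cross-tabulated against regulation status (the match-length
  silencing table);
* :func:`correlate_match_foldchange` — rank correlation between match
  length and fold-change magnitude (the match-vs-response scatter);
* :func:`find_homologs` — seed-and-extend local alignment with
  Karlin–Altschul E-values, the screen used to ask whether the construct
  has a homologous fragment in the non-target transcriptome;
* :func:`pathway_levels` — breadth-first pathway neighbourhood levels
  around the target-homolog seed genes (level 1 = pathways containing a
  seed gene, level 2 = pathways sharing genes with level-1 genes, ...);
* :func:`enrich_hypergeometric` — upper-tail hypergeometric enrichment.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .expression import DEGRecord, bh_fdr
from .matchscan import DEFAULT_MIN_MATCH, GeneMatchClass
from .sequences import read_fasta, reverse_complement

# ---------------------------------------------------------------------------
# cross-tabulation


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage 100*n/d rounded half-up to 2 decimals, from exact integers."""
    if denominator == 0:
        return 0.0
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclasses.dataclass(frozen=True)
class CrossTabRow:
    """One row of a regulation cross-table; ``label`` is a length or a level."""

    label: str
    n_total: int
    n_up: int
    pct_up: float
    n_down: int
    pct_down: float
    n_ns: int
    pct_ns: float


def tabulate_counts(rows: Sequence[tuple[str, int, int, int]],
                    total_label: str = "Total") -> list[CrossTabRow]:
    """Build cross-table rows plus a Total row from (label, total, up, down).

    ns counts are total - up - down; percentages are recomputed from the
    integer counts under half-up 2-decimal rounding.  The Total row is the
    column sum, never re-entered by hand.
    """
    out: list[CrossTabRow] = []
    for label, n_total, n_up, n_down in rows:
        n_ns = n_total - n_up - n_down
        if n_ns < 0:
            raise ValueError(f"row {label!r}: up+down exceed total")
        out.append(CrossTabRow(
            label, n_total,
            n_up, round_pct(n_up, n_total),
            n_down, round_pct(n_down, n_total),
            n_ns, round_pct(n_ns, n_total),
        ))
    tot = sum(r.n_total for r in out)
    up = sum(r.n_up for r in out)
    down = sum(r.n_down for r in out)
    ns = sum(r.n_ns for r in out)
    out.append(CrossTabRow(
        total_label, tot,
        up, round_pct(up, tot), down, round_pct(down, tot), ns, round_pct(ns, tot),
    ))
    return out


def _status_map(degs: Sequence[DEGRecord]) -> dict[str, DEGRecord]:
    by_gene: dict[str, DEGRecord] = {}
    for rec in degs:
        if rec.gene_id in by_gene:
            raise ValueError(f"duplicate gene {rec.gene_id!r} in DEG records")
        by_gene[rec.gene_id] = rec
    return by_gene


def crosstab_matches(classes: Sequence[GeneMatchClass],
                     degs: Sequence[DEGRecord],
                     min_length: int = DEFAULT_MIN_MATCH) -> list[CrossTabRow]:
    """Cross-tabulate match-length classes against regulation status.

    One row per observed maximal match length >= ``min_length`` plus a
    Total row.  Genes absent from the DEG records count as ``ns`` (with a
    warning): an unscreened gene is an unaffected gene for this table.
    """
    by_gene = _status_map(degs)
    missing = [c.gene_id for c in classes
               if c.max_match_length >= min_length and c.gene_id not in by_gene]
    if missing:
        warnings.warn(
            f"{len(missing)} classified gene(s) missing from DEG records;"
            " counted as ns", stacklevel=2,
        )
    per_len: dict[int, list[int]] = {}
    for c in classes:
        if c.max_match_length < min_length:
            continue
        rec = by_gene.get(c.gene_id)
        status = rec.status if rec is not None else "ns"
        tally = per_len.setdefault(c.max_match_length, [0, 0, 0])
        tally[0] += 1
        if status == "up":
            tally[1] += 1
        elif status == "down":
            tally[2] += 1
    rows = [(str(length), t[0], t[1], t[2])
            for length, t in sorted(per_len.items())]
    return tabulate_counts(rows)


def crosstab_to_frame(rows: Sequence[CrossTabRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


# ---------------------------------------------------------------------------
# match length vs fold change


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    pvalue: float
    n: int
    degenerate: bool            # True when either series has zero variance
    table: pd.DataFrame         # gene_id, match_length, log2fc, status


def correlate_match_foldchange(classes: Sequence[GeneMatchClass],
                               degs: Sequence[DEGRecord], *,
                               min_length: int = DEFAULT_MIN_MATCH,
                               signed: bool = False,
                               method: str = "spearman") -> CorrelationResult:
    """Rank correlation between maximal match length and fold-change size.

    The response is |log2FC| by default (silencing strength regardless of
    direction); ``signed=True`` correlates the signed value instead.
    Genes without a DEG record enter with log2fc 0.  With zero variance in
    either series the coefficient is reported as 0 with the degenerate
    flag set rather than NaN.
    """
    if method not in ("spearman", "kendall"):
        raise ValueError(f"unsupported correlation method {method!r}")
    by_gene = _status_map(degs)
    rows = []
    for c in classes:
        if c.max_match_length < min_length:
            continue
        rec = by_gene.get(c.gene_id)
        lfc = rec.log2fc if rec is not None else 0.0
        status = rec.status if rec is not None else "ns"
        rows.append({"gene_id": c.gene_id, "match_length": c.max_match_length,
                     "log2fc": lfc, "status": status})
    table = pd.DataFrame(rows, columns=["gene_id", "match_length", "log2fc", "status"])
    if len(table) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(table)}")
    y = table["log2fc"] if signed else table["log2fc"].abs()
    x = table["match_length"]
    if x.nunique() < 2 or y.nunique() < 2:
        return CorrelationResult(0.0, 1.0, len(table), True, table)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    else:
        rho, p = stats.kendalltau(x, y)
    return CorrelationResult(float(rho), float(p), len(table), False, table)


# ---------------------------------------------------------------------------
# seed-and-extend homology search


@dataclasses.dataclass(frozen=True)
class AlignmentParams:
    """Scoring and statistics for the local homology search.

    Defaults are the classic ungapped nucleotide scoring (+1/−2 with its
    Karlin–Altschul constants λ = 1.33 nats, K = 0.621); gap costs follow
    the usual affine convention (first gap residue costs open + extend).
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5       # positive cost
    gap_extend: int = 2     # positive cost
    lambda_: float = 1.33   # nats per score unit
    k: float = 0.621
    word_size: int = 11
    x_drop: int = 20
    gap_trigger: int = 25   # ungapped score required before gapped refinement

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")
        if self.word_size < 4:
            raise ValueError("seed word size must be >= 4")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match score must be positive, mismatch negative")


@dataclasses.dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    score: int
    bit_score: float
    identity: float            # percent of alignment columns
    query_start: int           # 0-based half-open span on the query strand used
    query_end: int
    subject_start: int
    subject_end: int
    strand: str                # query strand: "sense" | "antisense"
    evalue: float


def evalue(score: float, m: int, n: int, params: AlignmentParams) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    return params.k * m * n * math.exp(-params.lambda_ * score)


def bit_score(score: float, params: AlignmentParams) -> float:
    return (params.lambda_ * score - math.log(params.k)) / math.log(2.0)


def _ungapped_extend(q: str, s: str, qpos: int, spos: int, w: int,
                     params: AlignmentParams) -> tuple[int, int, int, int, int]:
    """X-drop extension of an exact seed word; returns (qs, qe, ss, se, score)."""
    match, mismatch, x = params.match, params.mismatch, params.x_drop
    score = best = w * match
    # right
    qi, si = qpos + w, spos + w
    best_q, best_s = qi, si
    run = score
    while qi < len(q) and si < len(s):
        run += match if q[qi] == s[si] else mismatch
        qi += 1
        si += 1
        if run > best:
            best, best_q, best_s = run, qi, si
        elif best - run > x:
            break
    qe, se = best_q, best_s
    # left
    score = best
    qi, si = qpos - 1, spos - 1
    best_q, best_s = qpos, spos
    run = best
    while qi >= 0 and si >= 0:
        run += match if q[qi] == s[si] else mismatch
        if run > score:
            score, best_q, best_s = run, qi, si
        elif score - run > params.x_drop:
            break
        qi -= 1
        si -= 1
    return best_q, qe, best_s, se, score


def _smith_waterman(a: str, b: str, params: AlignmentParams
                    ) -> tuple[int, int, int, int, int, int, int]:
    """Affine-gap local alignment with traceback.

    Returns (score, a_start, a_end, b_start, b_end, n_identical, n_columns).
    Pure-Python DP; callers keep the windows small.
    """
    la, lb = len(a), len(b)
    neg = -(10 ** 9)
    go, ge = params.gap_open + params.gap_extend, params.gap_extend
    H = [[0] * (lb + 1) for _ in range(la + 1)]
    E = [[neg] * (lb + 1) for _ in range(la + 1)]   # gap in a (move along b)
    F = [[neg] * (lb + 1) for _ in range(la + 1)]   # gap in b (move along a)
    best, bi, bj = 0, 0, 0
    for i in range(1, la + 1):
        ai = a[i - 1]
        Hi, Hm = H[i], H[i - 1]
        Ei, Fi, Fm = E[i], F[i], F[i - 1]
        for j in range(1, lb + 1):
            Ei[j] = max(Hi[j - 1] - go, Ei[j - 1] - ge)
            Fi[j] = max(Hm[j] - go, Fm[j] - ge)
            diag = Hm[j - 1] + (params.match if ai == b[j - 1] else params.mismatch)
            h = max(0, diag, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i, j, state = bi, bj, "H"
    n_id = n_col = 0
    while i > 0 and j > 0 and not (state == "H" and H[i][j] == 0):
        if state == "H":
            h = H[i][j]
            diag = H[i - 1][j - 1] + (params.match if a[i - 1] == b[j - 1] else params.mismatch)
            if h == diag:
                n_col += 1
                if a[i - 1] == b[j - 1]:
                    n_id += 1
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            n_col += 1
            if E[i][j] == E[i][j - 1] - ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            n_col += 1
            if F[i][j] == F[i - 1][j] - ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    return best, i, bi, j, bj, n_id, n_col


def _word_index(seq: str, w: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        idx.setdefault(seq[i : i + w], []).append(i)
    return idx


def _best_hsp_for_subject(query: str, subject: str, params: AlignmentParams,
                          qindex: dict[str, list[int]], *, gapped: bool
                          ) -> tuple[int, int, int, int, int, int, int] | None:
    """Best-scoring HSP of query vs subject, or None without a seed.

    Returns (score, qs, qe, ss, se, n_identical, n_columns).
    """
    w = params.word_size
    covered: dict[int, int] = {}  # diagonal -> subject end already extended past
    best = None
    for spos in range(len(subject) - w + 1):
        word = subject[spos : spos + w]
        for qpos in qindex.get(word, ()):
            diag = spos - qpos
            if covered.get(diag, -1) >= spos:
                continue
            qs, qe, ss, se, score = _ungapped_extend(query, subject, qpos, spos, w, params)
            covered[diag] = se
            if best is None or score > best[0]:
                n = qe - qs
                best = (score, qs, qe, ss, se,
                        sum(query[qs + t] == subject[ss + t] for t in range(n)), n)
    if best is None or not gapped or best[0] < params.gap_trigger:
        # chance-level segments keep their ungapped score, matching the
        # ungapped Karlin-Altschul constants used for the E-value
        return best
    g_score, a0, a1, b0, b1, n_id, n_col = _smith_waterman(query, subject, params)
    if g_score > best[0]:
        return (g_score, a0, a1, b0, b1, n_id, n_col)
    return best


def find_homologs(query: str, transcriptome: str | Path | Iterable[tuple[str, str]],
                  params: AlignmentParams | None = None, *,
                  evalue_threshold: float = 1e-10,
                  query_id: str = "query",
                  both_strands: bool = True,
                  gapped: bool = True) -> list[AlignmentHit]:
    """Seed-and-extend homology search of a query against a transcriptome.

    Exact ``word_size``-mers seed ungapped X-drop extensions; the best
    ungapped segment per subject is refined by a windowed affine-gap local
    alignment.  Each subject contributes at most its best HSP (per
    strand); hits with ``E < evalue_threshold`` are returned sorted by
    E-value then subject id.  The search space for the E-value is
    query length x total transcriptome length.
    """
    params = params or AlignmentParams()
    if len(query) < params.word_size:
        raise ValueError(
            f"query ({len(query)} nt) shorter than seed word size {params.word_size}"
        )
    if isinstance(transcriptome, (str, Path)):
        subjects = list(read_fasta(transcriptome))
    else:
        subjects = list(transcriptome)
    n_db = sum(len(s) for _, s in subjects)
    if n_db == 0:
        return []
    strands = [("sense", query)]
    if both_strands:
        strands.append(("antisense", reverse_complement(query)))
    indices = {strand: _word_index(seq, params.word_size) for strand, seq in strands}
    hits: list[AlignmentHit] = []
    for subject_id, subject in subjects:
        best: tuple | None = None
        for strand, qseq in strands:
            hsp = _best_hsp_for_subject(qseq, subject, params,
                                        indices[strand], gapped=gapped)
            if hsp is not None and (best is None or hsp[0] > best[0][0]):
                best = (hsp, strand)
        if best is None:
            continue
        (score, qs, qe, ss, se, n_id, n_col), strand = best
        e = evalue(score, len(query), n_db, params)
        if e < evalue_threshold:
            hits.append(AlignmentHit(
                query_id=query_id, subject_id=subject_id, score=score,
                bit_score=bit_score(score, params),
                identity=100.0 * n_id / n_col if n_col else 0.0,
                query_start=qs, query_end=qe,
                subject_start=ss, subject_end=se,
                strand=strand, evalue=e,
            ))
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits


def pairwise_identity(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Global-alignment identity: matched columns / alignment columns x 100."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    params = params or AlignmentParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0
    return 100.0 * counts.identities / columns


# ---------------------------------------------------------------------------
# pathway levels


def pathway_levels(annotation: Mapping[str, Iterable[str]],
                   seed_genes: Iterable[str],
                   max_level: int = 3) -> dict[str, int]:
    """Breadth-first pathway neighbourhood levels around seed genes.

    Level-1 pathways contain a seed gene; their members are level-1 genes.
    Level-(k+1) pathways share at least one gene with level-k genes and
    are not already levelled; their unlevelled members become level-(k+1)
    genes.  Every gene keeps its minimal level.  Returns an empty map
    (with a warning) when no seed gene occurs in any pathway.
    """
    seeds = set(seed_genes)
    if not seeds:
        raise ValueError("seed_genes must be non-empty")
    sets = {name: frozenset(genes) for name, genes in annotation.items()}
    if not any(seeds & s for s in sets.values()):
        warnings.warn("no seed gene occurs in any pathway; empty level map",
                      stacklevel=2)
        return {}
    gene_level: dict[str, int] = {}
    used_pathways: set[str] = set()
    frontier = seeds
    for level in range(1, max_level + 1):
        ring = [name for name, s in sorted(sets.items())
                if name not in used_pathways and s & frontier]
        if not ring:
            break
        new_genes: set[str] = set()
        for name in ring:
            used_pathways.add(name)
            for g in sets[name]:
                if g not in gene_level:
                    gene_level[g] = level
                    new_genes.add(g)
        frontier = new_genes
        if not frontier:
            break
    return gene_level


def level_table(levels: Mapping[str, int], degs: Sequence[DEGRecord],
                include_levels: Sequence[int] = (2, 3)) -> list[CrossTabRow]:
    """Cross-table of regulation status per pathway level (plus Total row).

    Mirrors the published level table: level-1 genes (the target-homolog
    pathways themselves) are excluded by default, levels 2 and 3 reported.
    Genes without a DEG record count as ns.
    """
    by_gene = _status_map(degs)
    rows = []
    for lvl in include_levels:
        members = [g for g, l in levels.items() if l == lvl]
        up = sum(1 for g in members if by_gene.get(g) and by_gene[g].status == "up")
        down = sum(1 for g in members if by_gene.get(g) and by_gene[g].status == "down")
        rows.append((f"Level {lvl}", len(members), up, down))
    return tabulate_counts(rows)


# ---------------------------------------------------------------------------
# enrichment


def enrich_hypergeometric(deg_set: Iterable[str],
                          term_sets: Mapping[str, Iterable[str]],
                          universe: Iterable[str]) -> pd.DataFrame:
    """One-sided upper-tail hypergeometric enrichment with BH adjustment.

    P(X >= overlap) drawing |deg_set| genes from a universe of size
    |universe| containing |term| successes; term sets are intersected with
    the universe first.  Returns a frame sorted by p-value.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    degs = set(deg_set)
    if not degs <= uni:
        raise ValueError("deg_set must be a subset of the universe")
    rows = []
    for name in sorted(term_sets):
        term = set(term_sets[name]) & uni
        k = len(term & degs)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(term), len(degs)))
        rows.append({"term": name, "n_term": len(term), "n_overlap": k,
                     "pvalue": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "n_term", "n_overlap", "pvalue"])
    df["fdr"] = bh_fdr(df["pvalue"].to_numpy()) if len(df) else []
    return df.sort_values(["pvalue", "term"], ignore_index=True)
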