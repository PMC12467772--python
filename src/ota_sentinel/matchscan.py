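"""Maximal contiguous dsRNA–transcript match scanning.

For every transcript we report the length of the longest exact, gap-free
run of nucleotides it shares with either strand of the dsRNA construct —
the quantity that drives off-target silencing risk: interference can be
triggered by runs as short as seven matched base pairs.  Each gene is
binned once, at its maximum, so per-length class counts are disjoint and
sum to the number of genes at or above the reporting threshold.

Two routes compute the same quantity:

* :func:`max_contiguous_match` — production scanner; streams the transcript
  through a suffix automaton built once per construct strand, O(transcript
  length) per gene.
* :func:`lcs_length` — a dense dynamic-programming longest-common-substring
  recurrence (numpy row sweep), used by the synthetic-data generator to
  verify every planted match and available as a cross-check.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .sequences import DsRNAConstruct, SequenceError, read_fasta, validate_dna

DEFAULT_MIN_MATCH = 7  # shortest contiguous run reported; RNAi-relevant floor


@dataclasses.dataclass(frozen=True)
class MatchHit:
    """One exact contiguous match between a transcript and a construct strand."""

    gene_id: str
    length: int
    gene_start: int       # 0-based offset in the transcript
    construct_start: int  # 0-based offset in the matched construct strand
    strand: str           # "sense" | "antisense"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("match length must be >= 1")
        if self.gene_start < 0 or self.construct_start < 0:
            raise ValueError("match offsets must be non-negative")
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclasses.dataclass(frozen=True)
class GeneMatchClass:
    """A gene's maximal contiguous match length, with one witness hit.

    ``max_match_length`` is 0 (and ``witness`` None) when the transcript
    shares no single base with either construct strand.  Witness ties are
    broken deterministically: smallest gene offset, then smallest construct
    offset, then sense before antisense.
    """

    gene_id: str
    max_match_length: int
    witness: MatchHit | None


class _SuffixAutomaton:
    """Suffix automaton of one string; supports streaming longest-match queries."""

    __slots__ = ("link", "length", "next", "_last")

    def __init__(self, s: str) -> None:
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        self.next: list[dict[str, int]] = [{}]
        self._last = 0
        for ch in s:
            self._extend(ch)

    def _extend(self, ch: str) -> None:
        cur = len(self.length)
        self.length.append(self.length[self._last] + 1)
        self.link.append(-1)
        self.next.append({})
        p = self._last
        while p != -1 and ch not in self.next[p]:
            self.next[p][ch] = cur
            p = self.link[p]
        if p == -1:
            self.link[cur] = 0
        else:
            q = self.next[p][ch]
            if self.length[p] + 1 == self.length[q]:
                self.link[cur] = q
            else:
                clone = len(self.length)
                self.length.append(self.length[p] + 1)
                self.link.append(self.link[q])
                self.next.append(dict(self.next[q]))
                while p != -1 and self.next[p].get(ch) == q:
                    self.next[p][ch] = clone
                    p = self.link[p]
                self.link[q] = clone
                self.link[cur] = clone
        self._last = cur

    def match_lengths(self, text: str) -> np.ndarray:
        """len(text) array: longest substring of the automaton's string ending at i."""
        out = np.zeros(len(text), dtype=np.int64)
        v, length = 0, 0
        nxt, link, st_len = self.next, self.link, self.length
        for i, ch in enumerate(text):
            while v != 0 and ch not in nxt[v]:
                v = link[v]
                length = st_len[v]
            if ch in nxt[v]:
                v = nxt[v][ch]
                length += 1
            out[i] = length
        return out


def lcs_length(a: str, b: str) -> int:
    """Longest common substring length by the dense DP recurrence.

    Row sweep over *a* with a numpy-vectorised column update; O(|a|·|b|)
    work but C-speed per row.  Independent of the automaton code path.
    """
    if not a or not b:
        return 0
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    row = np.zeros(len(bb) + 1, dtype=np.int64)
    best = 0
    for ch in np.frombuffer(a.encode("ascii"), dtype=np.uint8):
        new = np.zeros_like(row)
        new[1:] = np.where(bb == ch, row[:-1] + 1, 0)
        m = int(new.max())
        if m > best:
            best = m
        row = new
    return best


def lcs_length_both_strands(gene_seq: str, construct: DsRNAConstruct) -> int:
    """DP-oracle maximal contiguous match over both construct strands."""
    return max(
        lcs_length(gene_seq, construct.sense),
        lcs_length(gene_seq, construct.antisense),
    )


class ConstructScanner:
    """Reusable scanner: automata built once, queried per transcript."""

    def __init__(self, construct: DsRNAConstruct) -> None:
        self.construct = construct
        self._automata = [
            (strand, seq, _SuffixAutomaton(seq)) for strand, seq in construct.strands
        ]

    def scan(self, gene_id: str, gene_seq: str) -> GeneMatchClass:
        gene_seq = validate_dna(gene_seq, name=f"gene {gene_id!r}")
        best_len = 0
        per_strand: list[tuple[str, str, np.ndarray]] = []
        for strand, seq, sam in self._automata:
            lengths = sam.match_lengths(gene_seq)
            per_strand.append((strand, seq, lengths))
            best_len = max(best_len, int(lengths.max()))
        if best_len == 0:
            return GeneMatchClass(gene_id=gene_id, max_match_length=0, witness=None)
        # witness tie-break: gene_start, then construct_start, then sense first
        candidates: list[tuple[int, int, int, str]] = []
        for order, (strand, seq, lengths) in enumerate(per_strand):
            idx = np.flatnonzero(lengths == best_len)
            if idx.size == 0:
                continue
            end = int(idx[0])  # earliest end == earliest start at fixed length
            gene_start = end - best_len + 1
            sub = gene_seq[gene_start : end + 1]
            candidates.append((gene_start, seq.find(sub), order, strand))
        gene_start, construct_start, _, strand = min(candidates)
        witness = MatchHit(
            gene_id=gene_id,
            length=best_len,
            gene_start=gene_start,
            construct_start=construct_start,
            strand=strand,
        )
        return GeneMatchClass(gene_id, best_len, witness)


def max_contiguous_match(gene_seq: str, construct: DsRNAConstruct, *,
                         gene_id: str = "gene") -> GeneMatchClass:
    """Maximal contiguous exact match of one transcript to either strand."""
    return ConstructScanner(construct).scan(gene_id, gene_seq)


def classify_transcriptome(
    transcriptome: str | Path | Iterable[tuple[str, str]],
    construct: DsRNAConstruct,
    min_length: int = DEFAULT_MIN_MATCH,
) -> tuple[list[GeneMatchClass], dict[int, int]]:
    """Bin every transcript by its maximal match length.

    Returns the per-gene classes with ``max_match_length >= min_length``
    (each gene appears once, at its maximum) and the per-length gene
    counts.  Counts are disjoint by construction and sum to the number of
    qualifying genes.
    """
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    records: Iterator[tuple[str, str]]
    if isinstance(transcriptome, (str, Path)):
        records = read_fasta(transcriptome)
    else:
        records = iter(transcriptome)
    scanner = ConstructScanner(construct)
    seen: set[str] = set()
    classes: list[GeneMatchClass] = []
    n_scanned = 0
    for gene_id, seq in records:
        if gene_id in seen:
            raise SequenceError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        n_scanned += 1
        cls = scanner.scan(gene_id, seq)
        if cls.max_match_length >= min_length:
            classes.append(cls)
    if n_scanned == 0:
        raise ValueError("transcriptome is empty")
    counts = dict(sorted(Counter(c.max_match_length for c in classes).items()))
    return classes, counts


def write_classes_tsv(path: str | Path, classes: list[GeneMatchClass]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmax_len\tgene_start\tconstruct_start\tstrand\n")
        for c in classes:
            w = c.witness
            fh.write(
                f"{c.gene_id}\t{c.max_match_length}\t"
                f"{w.gene_start if w else ''}\t{w.construct_start if w else ''}\t"
                f"{w.strand if w else ''}\n"
            )


def read_classes_tsv(path: str | Path) -> list[GeneMatchClass]:
    classes: list[GeneMatchClass] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "max_len"]:
            raise ValueError(f"unexpected classes header in {path}: {header}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            gene_id, max_len = parts[0], int(parts[1])
            witness = None
            if len(parts) >= 5 and parts[2] != "":
                witness = MatchHit(gene_id, max_len, int(parts[2]), int(parts[3]), parts[4])
            classes.append(GeneMatchClass(gene_id, max_len, witness))
    return classes
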