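"""DNA sequence primitives: the dsRNA construct, validation, FASTA IO.

The interfering construct is modelled as a sense strand plus its reverse
complement (the antisense strand).  A dsRNA exposes siRNAs from both strands,
so every downstream match search treats the two strands symmetrically.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Invalid nucleotide sequence (empty or non-ACGT characters)."""


def validate_dna(seq: str, *, name: str = "sequence") -> str:
    """Return *seq* upper-cased, or raise naming the first offending position.

    Ambiguity codes (N, R, Y, ...) are rejected: the match scanner defines
    contiguous identity over the concrete {A,C,G,T} alphabet only.
    """
    if not seq:
        raise SequenceError(f"{name} is empty")
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise SequenceError(
                f"{name} contains invalid character {ch!r} at position {i}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class DsRNAConstruct:
    """A double-stranded RNA construct, stored in DNA space.

    Attributes
    ----------
    id : str
        Construct identifier (e.g. ``dsAsFAR``).
    sense : str
        Sense-strand sequence, A/C/G/T only.
    antisense : str
        Reverse complement of ``sense``; derived, never supplied.
    """

    id: str
    sense: str
    antisense: str = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sense", validate_dna(self.sense, name=f"construct {self.id!r}")
        )
        object.__setattr__(self, "antisense", reverse_complement(self.sense))

    def __len__(self) -> int:
        return len(self.sense)

    @property
    def strands(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (("sense", self.sense), ("antisense", self.antisense))


def gen_dsrna(length: int, seed: int, *, construct_id: str = "dsRNA") -> DsRNAConstruct:
    """Draw a uniform-random dsRNA construct of exactly *length* nt.

    The default construct in this pipeline is 432 nt, the length of the
    dsAsFAR hairpin expressed by the transgenic cotton line under study.
    """
    if length < 1:
        raise SequenceError(f"construct length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    sense = "".join(rng.choice(list("ACGT"), size=length))
    return DsRNAConstruct(id=construct_id, sense=sense)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, validated sequence) pairs; ids must be unique."""
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        yield rec.id, validate_dna(str(rec.seq), name=rec.id)


def write_fasta(path: str | Path, records: Iterator[tuple[str, str]] | list) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_construct(path: str | Path, *, construct_id: str | None = None) -> DsRNAConstruct:
    """Read a single-record FASTA as the dsRNA construct (sense strand)."""
    records = list(read_fasta(path))
    if len(records) != 1:
        raise SequenceError(
            f"construct FASTA {path} must hold exactly one record, found {len(records)}"
        )
    name, seq = records[0]
    return DsRNAConstruct(id=construct_id or name, sense=seq)
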