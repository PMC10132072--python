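"""Sequence containers, coordinates, reverse complement and bacterial translation.

Every downstream stage (hit parsing, ORF calling, pairing, region extraction)
works on these two primitives:

* :class:`NucleotideRecord` — an uppercase DNA sequence over ``{A,C,G,T,N}``
  with a unique id, as read from FASTA.
* :class:`GenomicInterval` — 0-based half-open coordinates *always expressed on
  the forward strand*, with a strand flag.  Minus-strand features store their
  forward-strand footprint; conversion to stranded/1-based conventions happens
  only at I/O boundaries.

Translation uses the bacterial/archaeal code (NCBI table 11).  Alternative
start codons render as ``M`` when in start position, matching prokaryotic
annotation practice; any codon containing ``N`` translates to ``X`` and is
treated as neither start nor stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ksclf")

DNA_ALPHABET = frozenset("ACGTN")

#: forward/reverse base map; N is self-complementary
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: NCBI translation table 11 (bacterial, archaeal and plant plastid)
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)
#: table 11 start codons (a superset of the six used for ORF calling)
TABLE11_START_CODONS: frozenset[str] = frozenset(_TABLE11.start_codons)


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,T,N}."""


class FrameError(ValueError):
    """Raised when a coding sequence length is not divisible by 3."""


@dataclass(frozen=True)
class NucleotideRecord:
    """One nucleotide sequence (contig, genome, or accession)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: non-DNA characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on the forward strand of one record.

    ``strand`` marks which strand the feature is read from; the coordinates
    themselves are always forward-strand.
    """

    record_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.record_id!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.record_id == other.record_id
            and self.start < other.end
            and other.start < self.end
        )


def _check_dna(seq: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-DNA characters {sorted(bad)!r}")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string; ``N`` maps to ``N``."""
    _check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon under table 11; any codon containing N gives 'X'."""
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def is_stop_codon(codon: str) -> bool:
    """True for TAA/TAG/TGA; codons containing N are never stops."""
    return codon in STOP_CODONS


def translate(seq: str, start_as_met: bool = False,
              start_codons: Iterable[str] = TABLE11_START_CODONS) -> str:
    """Translate a coding DNA string under the bacterial code (table 11).

    Parameters
    ----------
    seq:
        DNA over {A,C,G,T,N}, length divisible by 3.  Stop codons render
        ``*``; codons containing N render ``X``.
    start_as_met:
        If true and the first codon is one of `start_codons`, it renders
        ``M`` regardless of its table-11 product (e.g. CTG -> M).
    """
    _check_dna(seq)
    if len(seq) % 3 != 0:
        raise FrameError(f"sequence length {len(seq)} not divisible by 3")
    aa = [translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3)]
    if start_as_met and aa and seq[:3] in set(start_codons):
        aa[0] = "M"
    return "".join(aa)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path | TextIO) -> list[NucleotideRecord]:
    """Read a multi-record FASTA file into :class:`NucleotideRecord` objects.

    Sequences are uppercased on read; duplicate ids are rejected.
    """
    records: list[NucleotideRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            NucleotideRecord(id=rec.id, seq=str(rec.seq).upper(), description=desc)
        )
    return records


def write_fasta(records: Iterable[NucleotideRecord], path: str | Path | TextIO) -> None:
    """Write records as uppercase, line-wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seq_records, path, "fasta")
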