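"""Parsing and filtering of tabular translated-homology (tblastn-style) hits.

The pipeline's entry point is a pre-computed tab-separated hit table in a
custom outfmt-6-style column order (see :data:`DEFAULT_COLUMNS`).  Hits with
e-value <= 1 (boundary inclusive) are retained; the permissive threshold is
intentional — it admits distant homologs, and spurious alignments are removed
by the downstream ORF-coverage and profile-HMM stages.

Running the external search tool itself is an optional subprocess adapter
(:func:`run_tblastn`); the core pipeline never depends on it.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .genomic import GenomicInterval

logger = logging.getLogger("ksclf")

#: default column order of the hit table.  Matches an outfmt-6 invocation with
#: "qseqid sseqid pident length evalue bitscore sstart send sframe sseq".
DEFAULT_COLUMNS: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "evalue",
    "bitscore", "sstart", "send", "sframe", "sseq",
)

_REQUIRED = set(DEFAULT_COLUMNS)


class HitParseError(ValueError):
    """Raised for malformed hit-table lines (carries the line number)."""


@dataclass(frozen=True)
class BlastHit:
    """One translated-homology hit against a nucleotide subject.

    Subject coordinates are 1-based inclusive as printed by BLAST: plus-frame
    hits have ``subject_start_1b < subject_end_1b``, minus-frame hits the
    reverse.  ``subject_protein`` is the aligned subject amino-acid string and
    may contain ``-`` gap characters.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    evalue: float
    bitscore: float
    subject_start_1b: int
    subject_end_1b: int
    frame: int
    subject_protein: str

    def __post_init__(self) -> None:
        if self.frame not in (-3, -2, -1, 1, 2, 3):
            raise ValueError(f"frame must be in ±1..3, got {self.frame}")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.frame > 0 and not self.subject_start_1b < self.subject_end_1b:
            raise ValueError(
                f"plus-frame hit must have sstart < send "
                f"({self.subject_start_1b} vs {self.subject_end_1b})"
            )
        if self.frame < 0 and not self.subject_start_1b > self.subject_end_1b:
            raise ValueError(
                f"minus-frame hit must have sstart > send "
                f"({self.subject_start_1b} vs {self.subject_end_1b})"
            )

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def span_nt(self) -> int:
        return abs(self.subject_end_1b - self.subject_start_1b) + 1


@dataclass(frozen=True)
class HitFilterConfig:
    """E-value retention rule: hits with evalue <= max_evalue pass."""

    max_evalue: float = 1.0

    def __post_init__(self) -> None:
        if not self.max_evalue > 0:
            raise ValueError("max_evalue must be > 0")


def parse_tabular_hits(
    stream: TextIO | Iterable[str],
    column_spec: Sequence[str] = DEFAULT_COLUMNS,
) -> list[BlastHit]:
    """Parse a tab-separated hit table into :class:`BlastHit` objects.

    ``column_spec`` gives the field order and must cover all BlastHit fields.
    Lines starting with ``#`` and blank lines are skipped.  No filtering is
    applied here.
    """
    missing = _REQUIRED - set(column_spec)
    if missing:
        raise ValueError(f"column_spec missing required fields: {sorted(missing)}")
    idx = {name: i for i, name in enumerate(column_spec)}
    hits: list[BlastHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(column_spec):
            raise HitParseError(
                f"line {lineno}: expected {len(column_spec)} columns, "
                f"got {len(fields)}"
            )
        try:
            hits.append(
                BlastHit(
                    query_id=fields[idx["qseqid"]],
                    subject_id=fields[idx["sseqid"]],
                    percent_identity=float(fields[idx["pident"]]),
                    align_length=int(fields[idx["length"]]),
                    evalue=float(fields[idx["evalue"]]),
                    bitscore=float(fields[idx["bitscore"]]),
                    subject_start_1b=int(fields[idx["sstart"]]),
                    subject_end_1b=int(fields[idx["send"]]),
                    frame=int(fields[idx["sframe"]]),
                    subject_protein=fields[idx["sseq"]],
                )
            )
        except (ValueError, KeyError) as exc:
            if isinstance(exc, HitParseError):
                raise
            raise HitParseError(f"line {lineno}: {exc}") from exc
    return hits


def write_tabular_hits(
    hits: Iterable[BlastHit],
    path: str | Path | TextIO,
    column_spec: Sequence[str] = DEFAULT_COLUMNS,
) -> None:
    """Write hits back out in the same TSV column convention."""
    getters = {
        "qseqid": lambda h: h.query_id,
        "sseqid": lambda h: h.subject_id,
        "pident": lambda h: f"{h.percent_identity:.3f}",
        "length": lambda h: str(h.align_length),
        "evalue": lambda h: repr(h.evalue),
        "bitscore": lambda h: f"{h.bitscore:.1f}",
        "sstart": lambda h: str(h.subject_start_1b),
        "send": lambda h: str(h.subject_end_1b),
        "sframe": lambda h: str(h.frame),
        "sseq": lambda h: h.subject_protein,
    }
    own = hasattr(path, "write")
    fh = path if own else open(path, "w")
    try:
        for h in hits:
            fh.write("\t".join(getters[c](h) for c in column_spec) + "\n")
    finally:
        if not own:
            fh.close()


def filter_hits(hits: Sequence[BlastHit], config: HitFilterConfig | None = None) -> list[BlastHit]:
    """Retain hits with evalue <= max_evalue (default 1.0, inclusive); order preserved."""
    config = config or HitFilterConfig()
    return [h for h in hits if h.evalue <= config.max_evalue]


def hit_interval(hit: BlastHit) -> GenomicInterval:
    """Normalize printed 1-based stranded coordinates to a forward-strand interval.

    Plus hits map [sstart, send] -> [sstart-1, send); minus hits (sstart > send)
    map to [send-1, sstart) with strand '-'.
    """
    if hit.frame > 0:
        start0, end0 = hit.subject_start_1b - 1, hit.subject_end_1b
    else:
        start0, end0 = hit.subject_end_1b - 1, hit.subject_start_1b
    return GenomicInterval(
        record_id=hit.subject_id, start=start0, end=end0, strand=hit.strand
    )


# ---------------------------------------------------------------------------
# optional external search adapter
# ---------------------------------------------------------------------------

def run_tblastn(
    query_fasta: str | Path,
    subject_fasta: str | Path,
    out_tsv: str | Path,
    extra_args: Sequence[str] = (),
) -> list[BlastHit]:
    """Run the external ``tblastn`` binary and parse its output.

    Thin subprocess adapter emitting the :data:`DEFAULT_COLUMNS` TSV; matrix,
    word size etc. are passed through ``extra_args`` untouched.  Requires
    ``tblastn`` on PATH; the core pipeline does not use this.
    """
    if shutil.which("tblastn") is None:
        raise RuntimeError("tblastn not found on PATH")
    outfmt = "6 " + " ".join(DEFAULT_COLUMNS)
    cmd = [
        "tblastn", "-query", str(query_fasta), "-subject", str(subject_fasta),
        "-outfmt", outfmt, "-out", str(out_tsv), *extra_args,
    ]
    logger.info("running: %s", " ".join(cmd))
    subprocess.run(cmd, check=True)
    with open(out_tsv) as fh:
        return parse_tabular_hits(fh)
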