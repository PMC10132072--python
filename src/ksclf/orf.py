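"""Hit-anchored open-reading-frame calling.

For every homology hit, the caller searches a window extending 500 nt on
either side of the hit for the longest ORF that contains it.  An ORF begins at
the first of six accepted start codons (ATG, CTG, GTG, TTG, ATT, ATC)
following a stop codon (or the window/sequence edge) and runs to the next
in-frame stop codon (or the edge).  Called ORFs must be at least 300 nt long
and cover at least 50 % of the hit with an identical translated sequence.

Only the hit's own frame and strand are scanned: the identical-translation
coverage requirement means an ORF in any other frame scores zero coverage, so
searching the remaining five frames could never change the result.

Alternative starts may place the 5' boundary upstream of the true start
codon; the definition deliberately makes the fewest assumptions and errs long.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .blast import BlastHit, hit_interval
from .genomic import (
    GenomicInterval,
    NucleotideRecord,
    is_stop_codon,
    reverse_complement,
    translate,
    translate_codon,
)

logger = logging.getLogger("ksclf")

DEFAULT_START_CODONS = frozenset({"ATG", "CTG", "GTG", "TTG", "ATT", "ATC"})
DEFAULT_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfSearchConfig:
    """Parameters of the hit-anchored ORF search.

    ``flank_nt`` — window half-width around the hit (500 nt).
    ``min_orf_nt`` — minimum ORF length including the terminal stop codon
    (300 nt, i.e. ~100 codons).
    ``min_hit_coverage`` — minimum fraction of hit residues reproduced
    identically by the ORF's translation (0.5).
    ``window_bounded`` — treat the window edge as a hard ORF boundary (the
    default); if false the scan extends past the window to the record edge.
    ``allow_edge_start`` — retain ORFs truncated at the 5' edge that lack any
    start codon, recording ``has_start_codon=False``.
    """

    flank_nt: int = 500
    start_codons: frozenset[str] = DEFAULT_START_CODONS
    stop_codons: frozenset[str] = DEFAULT_STOP_CODONS
    min_orf_nt: int = 300
    min_hit_coverage: float = 0.5
    window_bounded: bool = True
    allow_edge_start: bool = True

    def __post_init__(self) -> None:
        if self.flank_nt < 0:
            raise ValueError("flank_nt must be >= 0")
        if self.min_orf_nt < 3:
            raise ValueError("min_orf_nt must be >= 3")
        if not (0 < self.min_hit_coverage <= 1):
            raise ValueError("min_hit_coverage must be in (0, 1]")


@dataclass(frozen=True)
class OpenReadingFrame:
    """A called gene candidate.

    ``interval`` uses forward-strand 0-based half-open coordinates and
    includes the terminal stop codon when present; ``protein`` excludes the
    stop and renders an accepted start codon as Met.
    """

    interval: GenomicInterval
    start_codon: str | None
    has_start_codon: bool
    has_stop_codon: bool
    protein: str
    source_hit_index: int = -1
    hit_coverage: float = 0.0
    source_query_id: str = ""
    source_evalue: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.interval) % 3 != 0:
            raise ValueError("ORF interval length must be divisible by 3")
        expect = len(self.interval) // 3 - (1 if self.has_stop_codon else 0)
        if len(self.protein) != expect:
            raise ValueError(
                f"protein length {len(self.protein)} != expected {expect}"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def record_id(self) -> str:
        return self.interval.record_id

    @property
    def length_nt(self) -> int:
        return len(self.interval)


def _working_sequence(record: NucleotideRecord, window: GenomicInterval) -> str:
    """Window slice in reading orientation (reverse-complemented for '-')."""
    sub = record.seq[window.start : window.end]
    return reverse_complement(sub) if window.strand == "-" else sub


def _to_forward(window: GenomicInterval, a: int, b: int) -> tuple[int, int]:
    """Map working-strand [a, b) back to forward-strand coordinates."""
    if window.strand == "+":
        return window.start + a, window.start + b
    return window.end - b, window.end - a


def enumerate_orfs_in_window(
    record: NucleotideRecord,
    window: GenomicInterval,
    frame_offset: int,
    strand: str,
    config: OrfSearchConfig | None = None,
) -> list[OpenReadingFrame]:
    """Enumerate the ORFs of one frame within a window.

    Codons of the given frame on the working strand are scanned 5'->3';
    stop codons and the window edges delimit segments.  Each segment yields at
    most one ORF: from its first start codon (or, for a 5'-edge segment with
    no start codon, from the edge itself when ``allow_edge_start``) to the
    delimiting stop codon (included in the interval) or the 3' edge.
    """
    config = config or OrfSearchConfig()
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    if window.record_id != record.id:
        raise ValueError("window record_id does not match record")
    if not (0 <= window.start and window.end <= len(record)):
        raise ValueError(
            f"window [{window.start}, {window.end}) outside record "
            f"bounds [0, {len(record)})"
        )
    work = _working_sequence(record, GenomicInterval(
        record.id, window.start, window.end, strand))

    orfs: list[OpenReadingFrame] = []
    seg_first: int | None = None      # working pos of segment's first codon
    first_start: int | None = None    # working pos of first start codon in segment
    seg_at_edge = True                # 5' side of current segment is the scan edge

    def emit(seg_begin: int | None, stop_pos: int | None) -> None:
        """Close a segment; ``stop_pos`` is the delimiting stop codon or None at edge."""
        nonlocal orfs
        begin = first_start
        has_start = begin is not None
        if begin is None:
            if seg_at_edge and config.allow_edge_start and seg_begin is not None:
                begin = seg_begin
            else:
                return
        if stop_pos is not None:
            end = stop_pos + 3
            has_stop = True
        else:
            if seg_begin is None:
                return
            # 3' edge: last full codon of the frame
            end = seg_begin + ((len(work) - seg_begin) // 3) * 3
            has_stop = False
            if end <= begin:
                return
        fwd_start, fwd_end = _to_forward(window, begin, end)
        coding = work[begin : end - 3] if has_stop else work[begin:end]
        protein = translate(coding, start_as_met=True,
                            start_codons=config.start_codons) if coding else ""
        start_codon = work[begin : begin + 3] if has_start else None
        orfs.append(
            OpenReadingFrame(
                interval=GenomicInterval(record.id, fwd_start, fwd_end, strand),
                start_codon=start_codon,
                has_start_codon=has_start,
                has_stop_codon=has_stop,
                protein=protein,
            )
        )

    p = frame_offset
    while p + 3 <= len(work):
        codon = work[p : p + 3]
        if is_stop_codon(codon):
            emit(seg_first, p)
            seg_first = None
            first_start = None
            seg_at_edge = False
        else:
            if seg_first is None:
                seg_first = p
            if first_start is None and codon in config.start_codons:
                first_start = p
        p += 3
    emit(seg_first, None)
    return orfs


def hit_coverage_identity(
    orf: OpenReadingFrame, hit: BlastHit, record: NucleotideRecord
) -> float:
    """Fraction of hit residues reproduced identically by the ORF translation.

    A residue counts when its codon lies inside the ORF interval, in the ORF's
    frame and strand, and the raw table-11 translation of that genomic codon
    equals the (degapped) subject residue.  An 'X' translation never counts.
    Hits whose aligned subject protein is empty, or whose degapped length does
    not tile the hit span into codons, fall back to the in-frame
    nucleotide-overlap fraction.
    """
    if hit.subject_id != record.id or orf.record_id != record.id:
        raise ValueError("ORF, hit and record must share one record id")
    hi = hit_interval(hit)
    degapped = hit.subject_protein.replace("-", "")

    if orf.strand != hi.strand:
        return 0.0
    if hi.strand == "+":
        in_frame = (hi.start - orf.interval.start) % 3 == 0
    else:
        in_frame = (orf.interval.end - hi.end) % 3 == 0
    if not in_frame:
        return 0.0

    if not degapped or 3 * len(degapped) != hi.length:
        # positional codon mapping unavailable: in-frame nt overlap fraction
        if degapped:
            logger.warning(
                "hit %s->%s: gapped alignment does not tile span; "
                "using nucleotide-overlap coverage", hit.query_id, hit.subject_id)
        ov = min(orf.interval.end, hi.end) - max(orf.interval.start, hi.start)
        return max(0, ov) / hi.length

    matches = 0
    for i, residue in enumerate(degapped):
        if hi.strand == "+":
            cs = hi.start + 3 * i
            ce = cs + 3
        else:
            ce = hi.end - 3 * i
            cs = ce - 3
        if cs < orf.interval.start or ce > orf.interval.end:
            continue
        codon = record.seq[cs:ce]
        if hi.strand == "-":
            codon = reverse_complement(codon)
        aa = translate_codon(codon)
        if aa != "X" and aa == residue:
            matches += 1
    return matches / len(degapped)


def find_longest_containing_orf(
    record: NucleotideRecord,
    hit: BlastHit,
    config: OrfSearchConfig | None = None,
    hit_index: int = -1,
) -> OpenReadingFrame | None:
    """Return the longest qualifying ORF containing a hit, or None.

    The search window is the hit interval extended by ``flank_nt`` on both
    sides, clipped to the record; only the hit's frame and strand are scanned.
    Qualifying ORFs are >= ``min_orf_nt`` long with identical-translation hit
    coverage >= ``min_hit_coverage``.  Absence is a value, not an error.
    """
    config = config or OrfSearchConfig()
    if hit.subject_id != record.id:
        raise ValueError(
            f"hit subject {hit.subject_id!r} does not match record {record.id!r}"
        )
    hi = hit_interval(hit)
    if config.window_bounded:
        ws = max(0, hi.start - config.flank_nt)
        we = min(len(record), hi.end + config.flank_nt)
    else:
        ws, we = 0, len(record)
    window = GenomicInterval(record.id, ws, we, hi.strand)
    if hi.strand == "+":
        frame_offset = (hi.start - ws) % 3
    else:
        frame_offset = (we - hi.end) % 3

    best: OpenReadingFrame | None = None
    best_cov = 0.0
    for orf in enumerate_orfs_in_window(record, window, frame_offset, hi.strand, config):
        if orf.length_nt < config.min_orf_nt:
            continue
        cov = hit_coverage_identity(orf, hit, record)
        if cov < config.min_hit_coverage:
            continue
        if best is None or orf.length_nt > best.length_nt or (
            orf.length_nt == best.length_nt
            and orf.interval.start < best.interval.start
        ):
            best, best_cov = orf, cov
    if best is None:
        return None
    return replace(
        best,
        source_hit_index=hit_index,
        hit_coverage=best_cov,
        source_query_id=hit.query_id,
        source_evalue=hit.evalue,
    )


def dedupe_orfs(orfs: Iterable[OpenReadingFrame]) -> list[OpenReadingFrame]:
    """Merge ORFs identical in (record, interval, strand).

    Multiple query proteins typically hit the same gene; the merged ORF keeps
    the source hit with the lowest e-value.  Output is sorted by record id
    then start coordinate.
    """
    by_key: dict[tuple[str, int, int, str], OpenReadingFrame] = {}
    for orf in orfs:
        key = (orf.record_id, orf.interval.start, orf.interval.end, orf.strand)
        cur = by_key.get(key)
        if cur is None or (orf.source_evalue == orf.source_evalue
                           and orf.source_evalue < cur.source_evalue):
            by_key[key] = orf
    return sorted(by_key.values(),
                  key=lambda o: (o.record_id, o.interval.start,
                                 o.interval.end, o.strand))


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def orfs_to_frame(orfs: Sequence[OpenReadingFrame]) -> pd.DataFrame:
    """ORF table (0-based half-open coordinates) as a DataFrame."""
    return pd.DataFrame(
        [
            {
                "record_id": o.record_id,
                "start": o.interval.start,
                "end": o.interval.end,
                "strand": o.strand,
                "start_codon": o.start_codon or ".",
                "has_start": o.has_start_codon,
                "has_stop": o.has_stop_codon,
                "length_nt": o.length_nt,
                "hit_coverage": o.hit_coverage,
                "source_query_id": o.source_query_id,
                "evalue": o.source_evalue,
            }
            for o in orfs
        ],
        columns=["record_id", "start", "end", "strand", "start_codon",
                 "has_start", "has_stop", "length_nt", "hit_coverage",
                 "source_query_id", "evalue"],
    )


def orf_id(orf: OpenReadingFrame) -> str:
    return f"{orf.record_id}:{orf.interval.start}-{orf.interval.end}:{orf.strand}"


def write_orf_proteins(orfs: Sequence[OpenReadingFrame], path: str | Path | TextIO) -> None:
    """Companion protein FASTA; ids are record:start-end:strand."""
    own = hasattr(path, "write")
    fh = path if own else open(path, "w")
    try:
        for o in orfs:
            fh.write(f">{orf_id(o)}\n{o.protein}\n")
    finally:
        if not own:
            fh.close()


def write_orf_bed(orfs: Sequence[OpenReadingFrame], path: str | Path | TextIO) -> None:
    """BED6 export of ORF intervals (score column = 1000 * hit coverage)."""
    own = hasattr(path, "write")
    fh = path if own else open(path, "w")
    try:
        for o in orfs:
            fh.write(
                f"{o.record_id}\t{o.interval.start}\t{o.interval.end}\t"
                f"{orf_id(o)}\t{int(round(1000 * o.hit_coverage))}\t{o.strand}\n"
            )
    finally:
        if not own:
            fh.close()
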