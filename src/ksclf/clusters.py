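"""Proximity pairing of KS and CLF genes and cluster-region extraction.

A KS–CLF pair is two classified ORFs on the same nucleotide record separated
by at most 2 kb of intergenic sequence (overlapping genes pass the filter;
the heterodimer partners must be co-expressible), each shorter than 6 kb.
Pairing is many-to-many: a KS near two CLFs yields two discrete pairs, which
is why a dataset can hold more pairs than distinct KS or CLF genes.

Cluster regions extend 30 kb on either side of each pair's footprint, clipped
to the record; overlapping extended regions on one record are merged.
Condensation-domain co-occurrence within a region is categorized from
annotation tokens (t2ks / t2clf / t2fas) into the non-exclusive categories
KS_CLF, KS_FAS and FAS_FAS.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genomic import GenomicInterval, NucleotideRecord
from .orf import OpenReadingFrame, orf_id

logger = logging.getLogger("ksclf")

DEFAULT_REGION_FLANK_NT = 30_000


@dataclass(frozen=True)
class PairingConfig:
    """Proximity rules: gap <= max_gap_nt kept ("over 2 kb removed" is strict),
    gene length < max_gene_nt kept (exclusive bound)."""

    max_gap_nt: int = 2000
    max_gene_nt: int = 6000

    def __post_init__(self) -> None:
        if self.max_gap_nt < 0:
            raise ValueError("max_gap_nt must be >= 0")
        if self.max_gene_nt <= 0:
            raise ValueError("max_gene_nt must be > 0")


@dataclass(frozen=True)
class GenePair:
    """One KS–CLF pair on a single record."""

    ks: OpenReadingFrame
    clf: OpenReadingFrame
    intergenic_gap_nt: int

    @property
    def record_id(self) -> str:
        return self.ks.record_id

    def footprint(self) -> GenomicInterval:
        """Bounding interval of both genes (strand-agnostic, '+' by convention)."""
        return GenomicInterval(
            self.record_id,
            min(self.ks.interval.start, self.clf.interval.start),
            max(self.ks.interval.end, self.clf.interval.end),
            "+",
        )


@dataclass(frozen=True)
class ClusterRegion:
    """A merged ±flank genomic region around one or more pairs."""

    interval: GenomicInterval
    member_pairs: tuple[GenePair, ...]


class PairingCategory(Enum):
    """Condensation-domain pairings a region may hold (non-exclusive)."""

    KS_CLF = "KS_CLF"
    KS_FAS = "KS_FAS"
    FAS_FAS = "FAS_FAS"


KNOWN_LABELS = frozenset({"t2ks", "t2clf", "t2fas"})


def intergenic_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Nucleotides strictly between two intervals; 0 if they overlap or abut."""
    if a.record_id != b.record_id:
        raise ValueError(
            f"intervals on different records: {a.record_id!r} vs {b.record_id!r}"
        )
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def pair_genes(
    ks_orfs: Sequence[OpenReadingFrame],
    clf_orfs: Sequence[OpenReadingFrame],
    config: PairingConfig | None = None,
) -> list[GenePair]:
    """All (KS, CLF) combinations passing the proximity and length rules.

    Strand concordance is not required; an ORF may appear in several pairs.
    Output order is deterministic: (record, KS start, CLF start).
    """
    config = config or PairingConfig()
    pairs: list[GenePair] = []
    for ks in ks_orfs:
        if ks.length_nt >= config.max_gene_nt:
            continue
        for clf in clf_orfs:
            if clf.length_nt >= config.max_gene_nt:
                continue
            if ks.record_id != clf.record_id:
                continue
            gap = intergenic_gap(ks.interval, clf.interval)
            if gap <= config.max_gap_nt:
                pairs.append(GenePair(ks=ks, clf=clf, intergenic_gap_nt=gap))
    pairs.sort(key=lambda p: (p.record_id, p.ks.interval.start,
                              p.clf.interval.start))
    return pairs


def extract_regions(
    pairs: Sequence[GenePair],
    records: Mapping[str, NucleotideRecord] | Sequence[NucleotideRecord],
    flank_nt: int = DEFAULT_REGION_FLANK_NT,
    merge_rule: str = "extended-overlap",
) -> list[ClusterRegion]:
    """Extend each pair's footprint by ``flank_nt``, clip, and merge.

    ``merge_rule``:

    * ``extended-overlap`` (default) — merge when the ±flank extended
      intervals overlap or abut, i.e. pairs within 2×flank of each other
      combine, per the stated merge procedure;
    * ``pair-distance`` — merge only pairs whose footprints are within
      ``flank_nt`` of each other (the separate-regions-if->30-kb-apart
      bookkeeping variant).
    """
    if merge_rule not in ("extended-overlap", "pair-distance"):
        raise ValueError(f"unknown merge_rule {merge_rule!r}")
    if not isinstance(records, Mapping):
        records = {r.id: r for r in records}
    by_record: dict[str, list[GenePair]] = {}
    for p in pairs:
        if p.record_id not in records:
            raise KeyError(f"record {p.record_id!r} not provided")
        by_record.setdefault(p.record_id, []).append(p)

    regions: list[ClusterRegion] = []
    for rid in sorted(by_record):
        rlen = len(records[rid])
        items = []
        for p in by_record[rid]:
            fp = p.footprint()
            if merge_rule == "extended-overlap":
                lo = max(0, fp.start - flank_nt)
                hi = min(rlen, fp.end + flank_nt)
            else:
                lo, hi = fp.start, fp.end
            items.append((lo, hi, p))
        items.sort(key=lambda t: (t[0], t[1]))
        cur_lo, cur_hi, members = items[0][0], items[0][1], [items[0][2]]
        gap_allow = 0 if merge_rule == "extended-overlap" else flank_nt
        for lo, hi, p in items[1:]:
            if lo <= cur_hi + gap_allow:
                cur_hi = max(cur_hi, hi)
                members.append(p)
            else:
                regions.append(_make_region(rid, rlen, cur_lo, cur_hi,
                                            members, flank_nt, merge_rule))
                cur_lo, cur_hi, members = lo, hi, [p]
        regions.append(_make_region(rid, rlen, cur_lo, cur_hi,
                                    members, flank_nt, merge_rule))
    return regions


def _make_region(rid: str, rlen: int, lo: int, hi: int,
                 members: list[GenePair], flank_nt: int,
                 merge_rule: str) -> ClusterRegion:
    if merge_rule == "pair-distance":
        lo = max(0, lo - flank_nt)
        hi = min(rlen, hi + flank_nt)
    members = sorted(members, key=lambda p: (p.ks.interval.start,
                                             p.clf.interval.start))
    return ClusterRegion(
        interval=GenomicInterval(rid, lo, hi, "+"),
        member_pairs=tuple(members),
    )


def categorize_region(labels: Iterable[str]) -> set[PairingCategory]:
    """Map a region's annotation tokens to its pairing categories.

    KS_CLF needs >=1 t2ks and >=1 t2clf; KS_FAS >=1 t2ks and >=1 t2fas;
    FAS_FAS >=2 t2fas.  Unknown tokens are ignored with a warning.  The empty
    set is a valid result.
    """
    counts = Counter()
    for token in labels:
        if token in KNOWN_LABELS:
            counts[token] += 1
        else:
            logger.warning("ignoring unknown gene-function label %r", token)
    out: set[PairingCategory] = set()
    if counts["t2ks"] >= 1 and counts["t2clf"] >= 1:
        out.add(PairingCategory.KS_CLF)
    if counts["t2ks"] >= 1 and counts["t2fas"] >= 1:
        out.add(PairingCategory.KS_FAS)
    if counts["t2fas"] >= 2:
        out.add(PairingCategory.FAS_FAS)
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def pairs_to_frame(pairs: Sequence[GenePair],
                   ks_bits: Mapping[str, float] | None = None,
                   clf_bits: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Pairs TSV layout; optional bit scores keyed by ORF id."""
    rows = []
    for p in pairs:
        rows.append({
            "record_id": p.record_id,
            "ks_start": p.ks.interval.start,
            "ks_end": p.ks.interval.end,
            "ks_strand": p.ks.strand,
            "clf_start": p.clf.interval.start,
            "clf_end": p.clf.interval.end,
            "clf_strand": p.clf.strand,
            "gap_nt": p.intergenic_gap_nt,
            "ks_bits": (ks_bits or {}).get(orf_id(p.ks), float("nan")),
            "clf_bits": (clf_bits or {}).get(orf_id(p.clf), float("nan")),
        })
    return pd.DataFrame(rows, columns=[
        "record_id", "ks_start", "ks_end", "ks_strand", "clf_start",
        "clf_end", "clf_strand", "gap_nt", "ks_bits", "clf_bits"])


def region_id(region: ClusterRegion) -> str:
    iv = region.interval
    return f"{iv.record_id}:{iv.start}-{iv.end}"


def regions_to_bed(regions: Sequence[ClusterRegion]) -> str:
    """BED3 text for merged cluster regions."""
    return "".join(
        f"{r.interval.record_id}\t{r.interval.start}\t{r.interval.end}\n"
        for r in regions
    )


def region_sequences(regions: Sequence[ClusterRegion],
                     records: Mapping[str, NucleotideRecord]) -> list[tuple[str, str]]:
    """(id, sequence) FASTA slices of each region."""
    out = []
    for r in regions:
        rec = records[r.interval.record_id]
        out.append((region_id(r), rec.seq[r.interval.start : r.interval.end]))
    return out
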