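"""End-to-end orchestration: hits -> ORFs -> classification -> pairs -> regions.

The stage order matches the discovery workflow: filter homology hits by
e-value, call the longest containing ORF for each hit, deduplicate ORFs
(several query proteins hit the same gene), classify each ORF's translation
against the KS and CLF profiles, pair classified genes by proximity, and
extract merged ±30 kb cluster regions.  Per-stage input/output/dropped
counts are collected so the funnel can be audited; counts telescope (one
stage's output is the next stage's input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .blast import BlastHit, HitFilterConfig, filter_hits
from .clusters import (
    ClusterRegion,
    GenePair,
    PairingConfig,
    extract_regions,
    pair_genes,
)
from .genomic import NucleotideRecord
from .hmm import (
    BuiltinScorer,
    ClassifierConfig,
    ProfileModel,
    Scorer,
)
from .orf import (
    OpenReadingFrame,
    OrfSearchConfig,
    dedupe_orfs,
    find_longest_containing_orf,
    orf_id,
)
from .phylo import PhyloConfig

logger = logging.getLogger("ksclf")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; the defaults are the published workflow's values
    (e-value 1; ±500 nt window; six start codons; 300 nt; 50 % coverage;
    2 kb gap; <6 kb genes; ±30 kb regions; 5 % gap columns; 70 % support)."""

    hit_filter: HitFilterConfig = field(default_factory=HitFilterConfig)
    orf_search: OrfSearchConfig = field(default_factory=OrfSearchConfig)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    phylo: PhyloConfig = field(default_factory=PhyloConfig)
    region_flank_nt: int = 30_000

    def to_json(self) -> str:
        import dataclasses, json

        payload = dataclasses.asdict(self)
        for key in ("start_codons", "stop_codons"):
            payload["orf_search"][key] = sorted(payload["orf_search"][key])
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        import json

        payload = json.loads(text)
        orf = payload["orf_search"]
        orf["start_codons"] = frozenset(orf["start_codons"])
        orf["stop_codons"] = frozenset(orf["stop_codons"])
        return cls(
            hit_filter=HitFilterConfig(**payload["hit_filter"]),
            orf_search=OrfSearchConfig(**orf),
            pairing=PairingConfig(**payload["pairing"]),
            phylo=PhyloConfig(**payload["phylo"]),
            region_flank_nt=payload["region_flank_nt"],
        )


@dataclass(frozen=True)
class StageCount:
    """Audit row for one stage; reason counts sum to items_dropped."""

    stage: str
    items_in: int
    items_out: int
    items_dropped: int
    reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.reasons.values()) != self.items_dropped:
            raise ValueError(
                f"stage {self.stage}: reason counts {self.reasons} do not sum "
                f"to items_dropped={self.items_dropped}")


@dataclass
class RunResult:
    """Everything a scan produced, stage by stage."""

    filtered_hits: list[BlastHit]
    orfs: list[OpenReadingFrame]
    labels: dict[str, str]              # orf id -> KS | CLF | none
    ks_bits: dict[str, float]
    clf_bits: dict[str, float]
    ks_orfs: list[OpenReadingFrame]
    clf_orfs: list[OpenReadingFrame]
    pairs: list[GenePair]
    regions: list[ClusterRegion]
    stages: list[StageCount]


def run_scan(
    records: Sequence[NucleotideRecord] | Mapping[str, NucleotideRecord],
    hits: Sequence[BlastHit],
    ks_model: ProfileModel | Scorer,
    clf_model: ProfileModel | Scorer,
    classifier: ClassifierConfig,
    config: PipelineConfig | None = None,
) -> RunResult:
    """Run the full scan; zero pairs is a success, not an error."""
    config = config or PipelineConfig()
    if not isinstance(records, Mapping):
        records = {r.id: r for r in records}
    ks_scorer = BuiltinScorer(ks_model) if isinstance(ks_model, ProfileModel) else ks_model
    clf_scorer = BuiltinScorer(clf_model) if isinstance(clf_model, ProfileModel) else clf_model
    stages: list[StageCount] = []

    # 1. e-value filter
    kept_hits = filter_hits(list(hits), config.hit_filter)
    stages.append(StageCount(
        "hit_filter", len(hits), len(kept_hits), len(hits) - len(kept_hits),
        {"evalue_above_max": len(hits) - len(kept_hits)}))
    logger.info("[hit_filter] %d -> %d hits", len(hits), len(kept_hits))

    # 2. hit-anchored ORF calling
    called: list[OpenReadingFrame] = []
    misses = 0
    for idx, hit in enumerate(kept_hits):
        rec = records.get(hit.subject_id)
        if rec is None:
            raise KeyError(f"[orf_call] hit subject {hit.subject_id!r} not in records")
        orf = find_longest_containing_orf(rec, hit, config.orf_search, hit_index=idx)
        if orf is None:
            misses += 1
        else:
            called.append(orf)
    stages.append(StageCount(
        "orf_call", len(kept_hits), len(called), misses,
        {"no_qualifying_orf": misses}))
    logger.info("[orf_call] %d hits -> %d ORFs", len(kept_hits), len(called))

    # 3. deduplication
    unique = dedupe_orfs(called)
    dup = len(called) - len(unique)
    stages.append(StageCount(
        "dedupe", len(called), len(unique), dup, {"duplicate_interval": dup}))

    # 4. profile classification
    labels: dict[str, str] = {}
    ks_bits: dict[str, float] = {}
    clf_bits: dict[str, float] = {}
    ks_orfs: list[OpenReadingFrame] = []
    clf_orfs: list[OpenReadingFrame] = []
    rejected = 0
    for orf in unique:
        oid = orf_id(orf)
        kb = ks_scorer.score(orf.protein)
        cb = clf_scorer.score(orf.protein)
        ks_bits[oid], clf_bits[oid] = kb, cb
        ks_ok = kb >= classifier.ks_threshold
        clf_ok = cb >= classifier.clf_threshold
        if ks_ok and (not clf_ok or kb >= cb):
            labels[oid] = "KS"
            ks_orfs.append(orf)
        elif clf_ok:
            labels[oid] = "CLF"
            clf_orfs.append(orf)
        else:
            labels[oid] = "none"
            rejected += 1
    n_labelled = len(ks_orfs) + len(clf_orfs)
    stages.append(StageCount(
        "classify", len(unique), n_labelled, rejected,
        {"below_both_thresholds": rejected}))
    logger.info("[classify] %d ORFs -> %d KS, %d CLF, %d rejected",
                len(unique), len(ks_orfs), len(clf_orfs), rejected)

    # 5. proximity pairing
    pairs = pair_genes(ks_orfs, clf_orfs, config.pairing)
    paired_ids = {orf_id(p.ks) for p in pairs} | {orf_id(p.clf) for p in pairs}
    unpaired = n_labelled - len(paired_ids)
    stages.append(StageCount(
        "pair", n_labelled, len(pairs), unpaired, {"unpaired_orf": unpaired}))
    logger.info("[pair] %d labelled ORFs -> %d pairs", n_labelled, len(pairs))

    # 6. region extraction
    regions = extract_regions(pairs, records, flank_nt=config.region_flank_nt) \
        if pairs else []
    stages.append(StageCount("regions", len(pairs), len(regions), 0, {}))
    logger.info("[regions] %d pairs -> %d merged regions", len(pairs), len(regions))

    return RunResult(
        filtered_hits=kept_hits, orfs=unique, labels=labels,
        ks_bits=ks_bits, clf_bits=clf_bits, ks_orfs=ks_orfs,
        clf_orfs=clf_orfs, pairs=pairs, regions=regions, stages=stages,
    )


def stage_report(run: RunResult) -> pd.DataFrame:
    """Per-stage audit table; the reason histogram is semicolon-joined."""
    return pd.DataFrame(
        [
            {
                "stage": s.stage,
                "items_in": s.items_in,
                "items_out": s.items_out,
                "items_dropped": s.items_dropped,
                "reasons": ";".join(f"{k}={v}" for k, v in sorted(s.reasons.items())),
            }
            for s in run.stages
        ],
        columns=["stage", "items_in", "items_out", "items_dropped", "reasons"],
    )
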