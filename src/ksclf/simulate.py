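"""Synthetic bacterial contigs with planted KS/CLF-like gene pairs.

The generator emulates the genomic structure the pairing stage assumes:
contigs carrying paired condensing-enzyme genes at controlled intergenic
distances, strands and lengths, plus decoy genes from an unrelated toy
family, with a ground-truth coordinate table and a simulated homology-hit
table.  The whole pipeline is thereby testable without any database.

Planted genes are built as ``start_codon + reverse-translated body + stop``,
preceded on the coding strand by an in-frame stop codon that anchors the
5' boundary (real genes are preceded by in-frame stops; without the anchor
the first-start-after-a-stop rule may legitimately extend an ORF upstream
into random background, which would make exact truth-coordinate comparison
meaningless).  Background sequence is i.i.d. at a chosen GC fraction and may
contain incidental ORFs; the pipeline must reject those — and the decoys —
through its coverage and classification stages, not through generator
tricks.

All randomness flows from a single spec seed through named substreams, so
fixtures are bit-stable across platforms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .blast import BlastHit
from .genomic import (
    CODON_TO_AA,
    NucleotideRecord,
    reverse_complement,
    translate,
)
from .hmm import ProfileModel, build_profile, sample_sequence, AMINO_ACIDS

logger = logging.getLogger("ksclf")

#: sense codons per amino acid (table 11)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


class SpecError(ValueError):
    """Inconsistent plant specification (overlaps, out-of-bounds, ...)."""


def reverse_translate(protein: str, seed: int,
                      codon_policy: str = "uniform-synonymous") -> str:
    """DNA encoding a protein; synonymous codons drawn uniformly per seed.

    By construction the result re-translates to the input and contains no
    in-frame stop codons.
    """
    if codon_policy != "uniform-synonymous":
        raise ValueError(f"unknown codon_policy {codon_policy!r}")
    rng = np.random.default_rng(seed)
    codons = []
    for aa in protein:
        if aa not in _AA_TO_CODONS:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        options = _AA_TO_CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


@dataclass(frozen=True)
class Plant:
    """One gene to plant: the body protein (start Met is added by the start
    codon), its start codon, forward-strand start position of the gene
    interval, strand, and role (KS / CLF / decoy)."""

    protein: str
    position: int
    strand: str = "+"
    role: str = "KS"
    start_codon: str = "ATG"

    @property
    def gene_length_nt(self) -> int:
        # start codon + body + stop codon
        return 3 * len(self.protein) + 6


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one synthetic contig."""

    record_id: str
    record_length: int
    plants: tuple[Plant, ...]
    gc_fraction: float = 0.5
    seed: int = 0
    allow_overlap: bool = False

    def to_json(self) -> str:
        payload = asdict(self)
        payload["plants"] = [asdict(p) for p in self.plants]
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlantSpec":
        payload = json.loads(text)
        plants = tuple(Plant(**p) for p in payload.pop("plants"))
        return cls(plants=plants, **payload)


@dataclass(frozen=True)
class TruthRow:
    """Ground-truth coordinates of one planted gene (interval includes the
    terminal stop codon; protein is the full ORF product, start as Met)."""

    record_id: str
    start: int
    end: int
    strand: str
    role: str
    protein: str


def _plant_footprint(plant: Plant) -> tuple[int, int]:
    """Forward-strand extent including the 5' anchor stop codon."""
    s, e = plant.position, plant.position + plant.gene_length_nt
    return (s - 3, e) if plant.strand == "+" else (s, e + 3)


def generate_genome(spec: PlantSpec) -> tuple[NucleotideRecord, list[TruthRow]]:
    """Build the contig and its truth table; deterministic per seed.

    Truth/FASTA consistency (re-translation of every planted slice equals the
    recorded protein) is re-checked on every generation.
    """
    # background substream
    rng_bg = np.random.default_rng([spec.seed, 0])
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    seq = list(rng_bg.choice(bases, size=spec.record_length, p=probs))

    taken: list[tuple[int, int]] = []
    truth: list[TruthRow] = []
    for i, plant in enumerate(spec.plants):
        if plant.strand not in ("+", "-"):
            raise SpecError(f"plant {i}: bad strand {plant.strand!r}")
        lo, hi = _plant_footprint(plant)
        if lo < 0 or hi > spec.record_length:
            raise SpecError(f"plant {i}: footprint [{lo}, {hi}) outside record")
        if not spec.allow_overlap:
            for lo2, hi2 in taken:
                if lo < hi2 and lo2 < hi:
                    raise SpecError(f"plant {i}: overlaps a previous plant")
        taken.append((lo, hi))

        # per-plant codon substream derived from the spec seed
        codon_seed = int(np.random.default_rng([spec.seed, 1, i]).integers(2**31))
        body = reverse_translate(plant.protein, seed=codon_seed)
        working = "TAA" + plant.start_codon + body + "TAA"  # anchor + gene
        s = plant.position
        e = s + plant.gene_length_nt
        if plant.strand == "+":
            seq[s - 3 : e] = list(working)
        else:
            seq[s : e + 3] = list(reverse_complement(working))
        truth.append(TruthRow(
            record_id=spec.record_id, start=s, end=e, strand=plant.strand,
            role=plant.role, protein="M" + plant.protein,
        ))

    record = NucleotideRecord(id=spec.record_id, seq="".join(seq))
    for row in truth:
        sl = record.seq[row.start : row.end]
        if row.strand == "-":
            sl = reverse_complement(sl)
        got = translate(sl[:-3], start_as_met=True)
        if got != row.protein:
            raise SpecError(
                f"truth/FASTA inconsistency at {row.start}-{row.end}: "
                f"{got[:10]}... != {row.protein[:10]}...")
    return record, truth


def simulate_blast_hits(
    truth: Sequence[TruthRow],
    record: NucleotideRecord,
    coverage_fraction: float = 0.8,
    evalue: float = 1e-50,
) -> list[BlastHit]:
    """One hit per planted gene, covering its central codons.

    The hit's frame is consistent with the gene's strand and phase, and its
    aligned subject protein is the genomic translation of the covered span,
    so downstream identity coverage is exactly 1.  Decoys get hits too:
    rejecting them is classification's job, not the search stage's.
    """
    if not (0 < coverage_fraction <= 1):
        raise ValueError("coverage_fraction must be in (0, 1]")
    hits: list[BlastHit] = []
    L = len(record)
    for row in truth:
        n_codons = (row.end - row.start) // 3 - 1  # coding, stop excluded
        n_cov = max(1, int(round(coverage_fraction * n_codons)))
        offset = (n_codons - n_cov) // 2
        if row.strand == "+":
            hs = row.start + 3 * offset
            he = hs + 3 * n_cov
            sstart, send = hs + 1, he
            frame = (hs % 3) + 1
            prot = translate(record.seq[hs:he])
        else:
            he = row.end - 3 * offset
            hs = he - 3 * n_cov
            sstart, send = he, hs + 1
            frame = -(((L - he) % 3) + 1)
            prot = translate(reverse_complement(record.seq[hs:he]))
        hits.append(BlastHit(
            query_id=f"query_{row.role}",
            subject_id=row.record_id,
            percent_identity=100.0,
            align_length=n_cov,
            evalue=evalue,
            bitscore=2.0 * n_cov,
            subject_start_1b=sstart,
            subject_end_1b=send,
            frame=frame,
            subject_protein=prot,
        ))
    return hits


def truth_to_frame(truth: Sequence[TruthRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truth],
                        columns=["record_id", "start", "end", "strand",
                                 "role", "protein"])


def write_truth_bed(truth: Sequence[TruthRow], path: str | Path) -> None:
    """BED6 + role column (name = role, score = 0)."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.record_id}\t{t.start}\t{t.end}\t{t.role}\t0\t{t.strand}\n")


# ---------------------------------------------------------------------------
# toy family models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelSet:
    """Three divergent toy profiles: the two target families plus a FAS-like
    decoy family, with distant-reference cutoff proteins for the first two."""

    ks_model: ProfileModel
    clf_model: ProfileModel
    fas_model: ProfileModel
    ks_cutoff: str
    clf_cutoff: str


def _toy_consensus(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=length))


def _mutate(protein: str, fraction: float, rng: np.random.Generator) -> str:
    """Randomize a fraction of residues (to a different residue)."""
    out = list(protein)
    k = int(round(fraction * len(out)))
    for pos in rng.choice(len(out), size=k, replace=False):
        choices = [aa for aa in AMINO_ACIDS if aa != out[pos]]
        out[pos] = choices[rng.integers(19)]
    return "".join(out)


def toy_seed_alignment(consensus: str, n_seqs: int, mutation_rate: float,
                       rng: np.random.Generator) -> list[str]:
    """Ungapped seed alignment: n mutated copies of a consensus."""
    return [_mutate(consensus, mutation_rate, rng) for _ in range(n_seqs)]


def make_toy_models(
    seed: int = 97,
    length: int = 150,
    n_seed_seqs: int = 30,
    seed_mutation_rate: float = 0.10,
    cutoff_divergence: float = 0.45,
) -> ToyModelSet:
    """Deterministic toy KS / CLF / FAS profiles for fixtures and tests.

    Each family has an independent random consensus (so families are as
    divergent as unrelated proteins), a seed alignment of 30 lightly mutated
    copies, and — for KS and CLF — a distant-reference cutoff protein at 45 %
    divergence, playing the role the aurachin cluster plays for the published
    models: related enough to score well above background noise, far below a
    true family member.
    """
    models = {}
    cutoffs = {}
    for k, fam in enumerate(("KS", "CLF", "FAS")):
        rng = np.random.default_rng([seed, 10 + k])
        consensus = _toy_consensus(length, rng)
        rows = toy_seed_alignment(consensus, n_seed_seqs, seed_mutation_rate, rng)
        models[fam] = build_profile(rows, name=f"toy_{fam}")
        cutoffs[fam] = _mutate(consensus, cutoff_divergence, rng)
    return ToyModelSet(
        ks_model=models["KS"], clf_model=models["CLF"], fas_model=models["FAS"],
        ks_cutoff=cutoffs["KS"], clf_cutoff=cutoffs["CLF"],
    )


# ---------------------------------------------------------------------------
# standard scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A complete synthetic test case: contig, truth, hits, and models."""

    spec: PlantSpec
    record: NucleotideRecord
    truth: list[TruthRow]
    hits: list[BlastHit]
    models: ToyModelSet

    def eligible_truth_pairs(self, max_gap_nt: int = 2000,
                             max_gene_nt: int = 6000) -> set[tuple]:
        """Planted (KS, CLF) pairs passing the proximity/length rules, as
        ((ks_start, ks_end, ks_strand), (clf_start, clf_end, clf_strand))."""
        ks = [t for t in self.truth if t.role == "KS"]
        clf = [t for t in self.truth if t.role == "CLF"]
        out = set()
        for a in ks:
            if a.end - a.start >= max_gene_nt:
                continue
            for b in clf:
                if b.end - b.start >= max_gene_nt:
                    continue
                gap = max(0, max(a.start, b.start) - min(a.end, b.end))
                if gap <= max_gap_nt:
                    out.add(((a.start, a.end, a.strand),
                             (b.start, b.end, b.strand)))
        return out


#: strand pattern cycled over successive pairs
_PAIR_STRANDS = (("+", "+"), ("-", "-"), ("+", "-"))
_START_CODONS_CYCLE = ("ATG", "CTG", "GTG")


def default_scenario(
    seed: int,
    record_length: int = 20_000,
    n_pairs: int = 3,
    n_decoys: int = 2,
    pair_gaps: Sequence[int] = (200, 900, 1800),
    gc_fraction: float = 0.55,
    coverage_fraction: float = 0.8,
) -> Scenario:
    """The standard study condition: a 20 kb contig with three KS–CLF pairs
    (gaps 200 / 900 / 1800 nt, mixed strands and start codons) and two
    FAS-like decoy genes, all with simulated hits covering 80 % of each gene.
    """
    models = make_toy_models()
    plants: list[Plant] = []
    cursor = 400
    for i in range(n_pairs):
        ks_strand, clf_strand = _PAIR_STRANDS[i % len(_PAIR_STRANDS)]
        sc = _START_CODONS_CYCLE[i % len(_START_CODONS_CYCLE)]
        ks_prot = sample_sequence(models.ks_model, seed=(seed * 1000 + 7 * i) % 2**31)
        clf_prot = sample_sequence(models.clf_model, seed=(seed * 1000 + 7 * i + 3) % 2**31)
        ks = Plant(protein=ks_prot, position=cursor, strand=ks_strand,
                   role="KS", start_codon=sc)
        gap = pair_gaps[i % len(pair_gaps)]
        clf_pos = ks.position + ks.gene_length_nt + gap
        clf = Plant(protein=clf_prot, position=clf_pos, strand=clf_strand,
                    role="CLF", start_codon="ATG")
        plants.extend([ks, clf])
        cursor = clf_pos + clf.gene_length_nt + 2600
    for d in range(n_decoys):
        prot = sample_sequence(models.fas_model, seed=(seed * 1000 + 500 + d) % 2**31)
        plant = Plant(protein=prot, position=cursor, strand="+" if d % 2 == 0 else "-",
                      role="decoy", start_codon="ATG")
        plants.append(plant)
        cursor += plant.gene_length_nt + 900
    if cursor + 10 > record_length:
        raise SpecError(f"scenario does not fit in {record_length} nt "
                        f"(needs ~{cursor})")
    spec = PlantSpec(
        record_id=f"synthcontig_{seed}",
        record_length=record_length,
        plants=tuple(plants),
        gc_fraction=gc_fraction,
        seed=seed,
    )
    record, truth = generate_genome(spec)
    hits = simulate_blast_hits(truth, record, coverage_fraction=coverage_fraction)
    return Scenario(spec=spec, record=record, truth=truth, hits=hits, models=models)
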