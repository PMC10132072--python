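"""Hit-anchored ORF calling against construction and brute-force oracles."""

import random

import pytest

from ksclf.blast import BlastHit
from ksclf.genomic import GenomicInterval, NucleotideRecord, reverse_complement, translate
from ksclf.orf import (
    OrfSearchConfig,
    dedupe_orfs,
    enumerate_orfs_in_window,
    find_longest_containing_orf,
    hit_coverage_identity,
)
from ksclf.simulate import reverse_translate

from conftest import oracle_longest_orf, oracle_orfs


def pad(n, rng=None, seed=0):
    """Background DNA free of stop codons is not required; plain random."""
    rng = rng or random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def plus_hit(record_id, start0, end0, protein, evalue=1e-30, query="q"):
    return BlastHit(
        query_id=query, subject_id=record_id, percent_identity=100.0,
        align_length=len(protein), evalue=evalue, bitscore=100.0,
        subject_start_1b=start0 + 1, subject_end_1b=end0, frame=(start0 % 3) + 1,
        subject_protein=protein,
    )


def minus_hit(record_id, start0, end0, protein, L, evalue=1e-30):
    frame = -(((L - end0) % 3) + 1)
    return BlastHit(
        query_id="q", subject_id=record_id, percent_identity=100.0,
        align_length=len(protein), evalue=evalue, bitscore=100.0,
        subject_start_1b=end0, subject_end_1b=start0 + 1, frame=frame,
        subject_protein=protein,
    )


class TestEnumerate:
    def test_simple_window(self):
        rec = NucleotideRecord(id="r", seq="TAAATGAAATGA")
        orfs = enumerate_orfs_in_window(
            rec, GenomicInterval("r", 0, 12), frame_offset=0, strand="+")
        assert len(orfs) == 1
        (o,) = orfs
        assert (o.interval.start, o.interval.end) == (3, 12)
        assert o.has_start_codon and o.has_stop_codon
        assert o.protein == "MK"

    def test_no_start_in_internal_segment(self):
        # stop, then a segment with no start codon, then stop
        rec = NucleotideRecord(id="r", seq="TAA" + "AAA" + "CCC" + "TGA")
        orfs = enumerate_orfs_in_window(
            rec, GenomicInterval("r", 0, 12), frame_offset=0, strand="+")
        assert orfs == []

    def test_ctg_before_atg_starts_at_ctg(self):
        rec = NucleotideRecord(id="r", seq="TAA" + "CTG" + "ATG" + "AAA" + "TGA")
        (o,) = enumerate_orfs_in_window(
            rec, GenomicInterval("r", 0, 15), frame_offset=0, strand="+")
        assert o.interval.start == 3
        assert o.start_codon == "CTG"
        assert o.protein == "MMK"

    def test_edge_truncated_orf_retained_without_start(self):
        rec = NucleotideRecord(id="r", seq="AAA" + "CCC" + "TGA")
        (o,) = enumerate_orfs_in_window(
            rec, GenomicInterval("r", 0, 9), frame_offset=0, strand="+")
        assert not o.has_start_codon and o.has_stop_codon
        assert (o.interval.start, o.interval.end) == (0, 9)

    def test_edge_truncation_disabled(self):
        rec = NucleotideRecord(id="r", seq="AAA" + "CCC" + "TGA")
        cfg = OrfSearchConfig(allow_edge_start=False)
        assert enumerate_orfs_in_window(
            rec, GenomicInterval("r", 0, 9), 0, "+", cfg) == []

    def test_window_outside_record(self):
        rec = NucleotideRecord(id="r", seq="ACGTACGT")
        with pytest.raises(ValueError, match="bounds"):
            enumerate_orfs_in_window(rec, GenomicInterval("r", 0, 20), 0, "+")

    def test_n_codon_neither_start_nor_stop(self):
        # TNA is not a stop; ANG not a start: segment stays open to the edge
        rec = NucleotideRecord(id="r", seq="TAA" + "ANG" + "TNA" + "AAA")
        orfs = enumerate_orfs_in_window(
            rec, GenomicInterval("r", 0, 12), frame_offset=0, strand="+")
        assert orfs == []  # no start codon anywhere after the stop

    def test_matches_oracle_on_random_windows(self):
        rng = random.Random(42)
        for _ in range(120):
            n = rng.randrange(30, 600, 3)
            seq = pad(n, rng)
            off = rng.randint(0, 2)
            rec = NucleotideRecord(id="r", seq=seq)
            got = enumerate_orfs_in_window(
                rec, GenomicInterval("r", 0, n), off, "+")
            expect = oracle_orfs(seq, off)
            assert [(o.interval.start, o.interval.end,
                     o.has_start_codon, o.has_stop_codon) for o in got] == expect


class TestCoverage:
    def _planted(self, body_len=120, flank=200):
        """Record with one plus-strand gene and an in-frame internal hit."""
        rng = random.Random(5)
        protein = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                          for _ in range(body_len))
        gene = "ATG" + reverse_translate(protein, seed=8) + "TAA"
        seq = pad(flank - 3, rng) + "TAA" + gene + pad(flank, rng)
        rec = NucleotideRecord(id="r", seq=seq)
        gstart = flank
        return rec, protein, gstart, gstart + len(gene)

    def test_identity_full_containment(self):
        rec, protein, gs, ge = self._planted()
        # hit = codons 10..50 of the gene (offset by the start codon)
        hs = gs + 3 + 30
        he = hs + 3 * 40
        hit = plus_hit("r", hs, he, translate(rec.seq[hs:he]))
        orf = find_longest_containing_orf(rec, hit)
        assert orf is not None
        assert hit_coverage_identity(orf, hit, rec) == 1.0

    def test_half_coverage(self):
        rec, protein, gs, ge = self._planted()
        # hit straddles the stop: half its codons beyond the ORF end
        n = 40
        hs = ge - 3 * n // 2        # last 20 codons in gene (incl stop region)
        he = hs + 3 * n
        hit = plus_hit("r", hs, he, translate(rec.seq[hs:he]))
        from ksclf.orf import OpenReadingFrame

        orf = OpenReadingFrame(
            interval=GenomicInterval("r", gs, ge, "+"),
            start_codon="ATG", has_start_codon=True, has_stop_codon=True,
            protein=translate(rec.seq[gs : ge - 3], start_as_met=True))
        cov = hit_coverage_identity(orf, hit, rec)
        # 20 of 40 codons inside the ORF; the stop codon inside translates '*'
        # and the hit protein there is '*' too, so it counts iff equal & != X
        assert 0.45 <= cov <= 0.55

    def test_frame_mismatch_zero(self):
        rec, protein, gs, ge = self._planted()
        hs = gs + 3 + 1             # out of frame by 1
        he = hs + 3 * 30
        hit = plus_hit("r", hs, he, "A" * 30)
        from ksclf.orf import OpenReadingFrame

        orf = OpenReadingFrame(
            interval=GenomicInterval("r", gs, ge, "+"),
            start_codon="ATG", has_start_codon=True, has_stop_codon=True,
            protein=translate(rec.seq[gs : ge - 3], start_as_met=True))
        assert hit_coverage_identity(orf, hit, rec) == 0.0

    def test_empty_subject_protein_falls_back_to_overlap(self):
        rec, protein, gs, ge = self._planted()
        hs, he = gs + 3, gs + 3 + 90
        hit = plus_hit("r", hs, he, "")
        from ksclf.orf import OpenReadingFrame

        orf = OpenReadingFrame(
            interval=GenomicInterval("r", gs, ge, "+"),
            start_codon="ATG", has_start_codon=True, has_stop_codon=True,
            protein=translate(rec.seq[gs : ge - 3], start_as_met=True))
        assert hit_coverage_identity(orf, hit, rec) == 1.0  # fully inside


class TestFindLongest:
    def _plant(self, body_aa, flank, strand="+", start_codon="ATG", seed=5):
        rng = random.Random(seed)
        protein = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                          for _ in range(body_aa))
        gene = start_codon + reverse_translate(protein, seed=seed) + "TAA"
        working = "TAA" + gene
        if strand == "+":
            seq = pad(flank - 3, rng) + working + pad(flank, rng)
            gs = flank
        else:
            seq = pad(flank, rng) + reverse_complement(working) + pad(flank - 3, rng)
            gs = flank
        rec = NucleotideRecord(id="r", seq=seq)
        return rec, gs, gs + len(gene)

    def test_recovers_planted_gene_exactly(self):
        # 330 nt gene (108 aa body), 150 nt internal hit
        rec, gs, ge = self._plant(108, 600)
        hs = gs + 3 + 60
        he = hs + 150
        hit = plus_hit("r", hs, he, translate(rec.seq[hs:he]))
        orf = find_longest_containing_orf(rec, hit)
        assert orf is not None
        assert (orf.interval.start, orf.interval.end) == (gs, ge)
        oracle = oracle_longest_orf(rec, hit)
        assert oracle == (gs, ge)

    def test_minus_strand_recovery(self):
        rec, gs, ge = self._plant(108, 600, strand="-")
        # hit: central codons on the minus strand
        he = ge - 3 - 60            # working offset 20 codons after start
        hs = he - 150
        prot = translate(reverse_complement(rec.seq[hs:he]))
        hit = minus_hit("r", hs, he, prot, L=len(rec.seq))
        orf = find_longest_containing_orf(rec, hit)
        assert orf is not None
        assert (orf.interval.start, orf.interval.end, orf.strand) == (gs, ge, "-")

    def test_short_gene_rejected(self):
        # 297 nt gene: 97 aa body => 3 + 291 + 3 = 297 < 300
        rec, gs, ge = self._plant(97, 600)
        assert ge - gs == 297
        hs = gs + 3
        he = hs + 150
        hit = plus_hit("r", hs, he, translate(rec.seq[hs:he]))
        assert find_longest_containing_orf(rec, hit) is None

    def test_min_length_boundary_inclusive(self):
        # 300 nt gene (98 aa body) passes
        rec, gs, ge = self._plant(98, 600)
        assert ge - gs == 300
        hs = gs + 3
        he = hs + 150
        hit = plus_hit("r", hs, he, translate(rec.seq[hs:he]))
        orf = find_longest_containing_orf(rec, hit)
        assert orf is not None and orf.length_nt == 300

    def test_low_coverage_rejected(self):
        rec, gs, ge = self._plant(108, 600)
        # hit mostly beyond the gene's stop codon: < 50 % of residues inside
        n = 50
        hs = ge - 3 * 20
        he = hs + 3 * n
        hit = plus_hit("r", hs, he, translate(rec.seq[hs:he]))
        orf = find_longest_containing_orf(rec, hit)
        assert orf is None or hit_coverage_identity(orf, hit, rec) >= 0.5

    def test_strand_symmetry(self):
        rec, gs, ge = self._plant(108, 600)
        hs = gs + 3 + 60
        he = hs + 150
        hit = plus_hit("r", hs, he, translate(rec.seq[hs:he]))
        fwd = find_longest_containing_orf(rec, hit)
        # mirror the record and the hit
        L = len(rec.seq)
        mrec = NucleotideRecord(id="r", seq=reverse_complement(rec.seq))
        mhs, mhe = L - he, L - hs
        mhit = minus_hit("r", mhs, mhe, hit.subject_protein, L=L)
        rev = find_longest_containing_orf(mrec, mhit)
        assert fwd is not None and rev is not None
        assert (rev.interval.start, rev.interval.end) == (
            L - fwd.interval.end, L - fwd.interval.start)
        assert rev.protein == fwd.protein


class TestDedupe:
    def _orf(self, start=0, end=300, strand="+", evalue=1e-10, rid="r"):
        from ksclf.orf import OpenReadingFrame

        return OpenReadingFrame(
            interval=GenomicInterval(rid, start, end, strand),
            start_codon="ATG", has_start_codon=True, has_stop_codon=False,
            protein="A" * ((end - start) // 3), source_evalue=evalue)

    def test_same_gene_two_hits_merged_best_evalue(self):
        a = self._orf(evalue=1e-5)
        b = self._orf(evalue=1e-20)
        merged = dedupe_orfs([a, b])
        assert len(merged) == 1 and merged[0].source_evalue == 1e-20

    def test_opposite_strands_distinct(self):
        assert len(dedupe_orfs([self._orf(strand="+"), self._orf(strand="-")])) == 2

    def test_empty(self):
        assert dedupe_orfs([]) == []

    def test_stable_order(self):
        orfs = [self._orf(start=600, end=900), self._orf(start=0, end=300),
                self._orf(start=0, end=300, rid="q")]
        merged = dedupe_orfs(orfs)
        assert [(o.record_id, o.interval.start) for o in merged] == [
            ("q", 0), ("r", 0), ("r", 600)]
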