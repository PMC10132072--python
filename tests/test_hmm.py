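"""Profile-HMM construction, scoring (vs exhaustive path oracle), thresholds."""

import math
import random

import numpy as np
import pytest

from ksclf.hmm import (
    EXTERNAL_CLF_THRESHOLD,
    EXTERNAL_KS_THRESHOLD,
    ClassifierConfig,
    ModelDegenerateError,
    ProfileModel,
    build_profile,
    calibrate_threshold,
    classify_protein,
    read_model,
    sample_sequence,
    score_sequence,
    write_model,
)

from conftest import oracle_forward_bits, random_small_model


def single_state_model(p_match=0.9, alphabet="ACDE"):
    """L=1 model emitting 'A' with 0.9; uniform background 0.25 -> but the
    worked example uses background 0.05, so allow a 20-letter variant too."""
    K = len(alphabet)
    me = np.full((1, K), (1 - p_match) / (K - 1))
    me[0, 0] = p_match
    bg = np.full(K, 1.0 / K)
    return ProfileModel(
        name="L1", match_emissions=me, insert_emissions=bg.copy(),
        background=bg, transitions=np.full((1, 3, 3), 1.0 / 3),
        alphabet=alphabet)


class TestScore:
    def test_hand_enumerable_single_column(self):
        # 20-letter alphabet: emission 0.9 for 'A', background 1/20 = 0.05,
        # entry = exit = 1 => score("A") = log2(0.9/0.05)
        from ksclf.hmm import AMINO_ACIDS

        K = 20
        me = np.full((1, K), 0.1 / 19)
        me[0, 0] = 0.9
        bg = np.full(K, 0.05)
        m = ProfileModel(name="one", match_emissions=me,
                         insert_emissions=bg.copy(), background=bg,
                         transitions=np.full((1, 3, 3), 1.0 / 3))
        got = score_sequence(m, "A").bits
        assert got == pytest.approx(math.log2(0.9 / 0.05), abs=1e-9)
        assert got == pytest.approx(4.1699, abs=1e-3)

    def test_forward_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(12)
        alphabet = "ACDE"
        for L in (1, 2, 3):
            for _ in range(4):
                m = random_small_model(rng, L, alphabet)
                for n in (1, 2, 3, 5):
                    seq = "".join(rng.choice(list(alphabet), size=n))
                    fwd = score_sequence(m, seq, mode="forward").bits
                    vit = score_sequence(m, seq, mode="viterbi").bits
                    assert fwd == pytest.approx(
                        oracle_forward_bits(m, seq, "forward"), abs=1e-6)
                    assert vit == pytest.approx(
                        oracle_forward_bits(m, seq, "viterbi"), abs=1e-6)
                    assert fwd >= vit - 1e-9

    def test_forward_geq_viterbi_random(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            L = int(rng.integers(1, 8))
            m = random_small_model(rng, L)
            seq = "".join(rng.choice(list("ACDE"), size=int(rng.integers(1, 12))))
            f = score_sequence(m, seq, "forward").bits
            v = score_sequence(m, seq, "viterbi").bits
            assert f >= v - 1e-9

    def test_x_residue_scores_as_background(self):
        m = single_state_model()
        # 'X' aligned to the match state has odds 1 -> 0 bits; forward over a
        # single position gives exactly entry(=1) * 1
        assert score_sequence(m, "X").bits == pytest.approx(0.0, abs=1e-9)

    def test_flanking_background_residues_negligible(self, toy_models):
        # flank residues are null-emitted, so the best path is untouched:
        # viterbi is exactly invariant.  Forward additionally sums the (tiny)
        # mass of alignments that absorb the flanks, so it may move by a few
        # millibits — bounded, not zero.
        m = toy_models.ks_model
        core = sample_sequence(m, seed=4)
        flanked = "GA" + core + "LS"
        assert score_sequence(m, flanked, "viterbi").bits == pytest.approx(
            score_sequence(m, core, "viterbi").bits, abs=1e-9)
        a = score_sequence(m, core).bits
        b = score_sequence(m, flanked).bits
        assert abs(b - a) < 0.01

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            score_sequence(single_state_model(), "")


class TestBuild:
    ALN = ["ACD", "ACD", "AGD"]

    def test_width_and_determinism(self, tmp_path):
        m1 = build_profile(self.ALN, name="t")
        m2 = build_profile(self.ALN, name="t")
        assert m1.L == 3
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_model(m1, p1)
        write_model(m2, p2)
        assert p1.read_text() == p2.read_text()

    def test_gap_majority_column_excluded(self):
        # middle column 60 % gaps -> insert column, L = 2
        aln = ["A-D", "A-D", "ACD", "A-D", "ACD"]
        m = build_profile(aln)
        assert m.L == 2

    def test_exact_half_gaps_excluded(self):
        # gap fraction 0.5 is NOT < 0.5 -> not a match column
        aln = ["A-", "AC", "A-", "AC"]
        assert build_profile(aln).L == 1

    def test_degenerate_alignment_raises(self):
        with pytest.raises(ModelDegenerateError):
            build_profile(["--", "--", "AC"])

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            build_profile(["ACD"])

    def test_emission_reflects_counts(self):
        m = build_profile(self.ALN)
        # column 1: C twice, G once, +pseudocounts
        ci = m.alphabet.index("C")
        gi = m.alphabet.index("G")
        assert m.match_emissions[1, ci] > m.match_emissions[1, gi] > 0


class TestSerialization:
    def test_round_trip_probabilities(self, tmp_path, toy_models):
        m = toy_models.clf_model
        p = tmp_path / "m.json"
        write_model(m, p)
        back = read_model(p)
        assert back.name == m.name and back.alphabet == m.alphabet
        for a, b in ((back.match_emissions, m.match_emissions),
                     (back.insert_emissions, m.insert_emissions),
                     (back.background, m.background),
                     (back.transitions, m.transitions)):
            assert np.max(np.abs(a - b)) < 1e-12


class TestSample:
    def test_deterministic_per_seed(self, toy_models):
        assert sample_sequence(toy_models.ks_model, 7) == \
            sample_sequence(toy_models.ks_model, 7)
        assert sample_sequence(toy_models.ks_model, 7) != \
            sample_sequence(toy_models.ks_model, 8)

    def test_degenerate_consensus_model(self):
        # all emission mass on one residue per column, transitions all-match
        K = 4
        me = np.zeros((3, K))
        me[0, 0] = me[1, 1] = me[2, 2] = 1.0
        tr = np.zeros((3, 3, 3))
        tr[:, :, 0] = 1.0
        m = ProfileModel(name="cons", match_emissions=me,
                         insert_emissions=np.full(K, 0.25),
                         background=np.full(K, 0.25), transitions=tr,
                         alphabet="ACDE")
        assert sample_sequence(m, 1) == "ACD"

    def test_samples_outscore_shuffles(self, toy_models):
        m = toy_models.ks_model
        rng = random.Random(0)
        self_scores, shuf_scores = [], []
        for s in range(30):
            p = sample_sequence(m, s)
            self_scores.append(score_sequence(m, p).bits)
            q = list(p)
            rng.shuffle(q)
            shuf_scores.append(score_sequence(m, "".join(q)).bits)
        assert np.mean(self_scores) > np.mean(shuf_scores)


class TestThresholdsAndClassification:
    def test_cutoff_sequence_retained_under_own_threshold(self, toy_models):
        thr = calibrate_threshold(toy_models.ks_model, toy_models.ks_cutoff)
        bits = score_sequence(toy_models.ks_model, toy_models.ks_cutoff).bits
        assert bits >= thr  # boundary inclusive

    def test_below_threshold_discarded(self, toy_models):
        ks_thr = calibrate_threshold(toy_models.ks_model, toy_models.ks_cutoff)
        clf_thr = calibrate_threshold(toy_models.clf_model, toy_models.clf_cutoff)
        cfg = ClassifierConfig(ks_threshold=ks_thr, clf_threshold=clf_thr)
        decoy = sample_sequence(toy_models.fas_model, 3)
        assert classify_protein(decoy, toy_models.ks_model,
                                toy_models.clf_model, cfg) == "none"

    def test_external_mode_uses_printed_constants(self):
        cfg = ClassifierConfig.external()
        assert cfg.ks_threshold == 352.0 == EXTERNAL_KS_THRESHOLD
        assert cfg.clf_threshold == 66.0 == EXTERNAL_CLF_THRESHOLD
        assert cfg.scorer == "external"

    def test_one_sided_classification(self, toy_models):
        ks_thr = calibrate_threshold(toy_models.ks_model, toy_models.ks_cutoff)
        clf_thr = calibrate_threshold(toy_models.clf_model, toy_models.clf_cutoff)
        cfg = ClassifierConfig(ks_threshold=ks_thr, clf_threshold=clf_thr)
        ks_prot = sample_sequence(toy_models.ks_model, 21)
        clf_prot = sample_sequence(toy_models.clf_model, 22)
        assert classify_protein(ks_prot, toy_models.ks_model,
                                toy_models.clf_model, cfg) == "KS"
        assert classify_protein(clf_prot, toy_models.ks_model,
                                toy_models.clf_model, cfg) == "CLF"

    def test_exact_tie_resolves_to_ks(self):
        m = single_state_model()
        cfg = ClassifierConfig(ks_threshold=-100, clf_threshold=-100)
        # identical models => identical scores => deterministic KS label
        assert classify_protein("A", m, m, cfg) == "KS"

    def test_sampling_classification_consistency(self, toy_models):
        ks_thr = calibrate_threshold(toy_models.ks_model, toy_models.ks_cutoff)
        clf_thr = calibrate_threshold(toy_models.clf_model, toy_models.clf_cutoff)
        cfg = ClassifierConfig(ks_threshold=ks_thr, clf_threshold=clf_thr)
        ok = 0
        n = 60
        for s in range(n):
            p = sample_sequence(toy_models.ks_model, 1000 + s)
            if classify_protein(p, toy_models.ks_model,
                                toy_models.clf_model, cfg) == "KS":
                ok += 1
            p = sample_sequence(toy_models.clf_model, 2000 + s)
            if classify_protein(p, toy_models.ks_model,
                                toy_models.clf_model, cfg) == "CLF":
                ok += 1
        assert ok / (2 * n) >= 0.95
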