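"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own scanning code: the ORF
oracle re-derives segments with Biopython primitives and exhaustive position
checks, and the HMM oracle enumerates every state path recursively.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from ksclf.genomic import NucleotideRecord
from ksclf.simulate import ToyModelSet, default_scenario, make_toy_models

START_CODONS = {"ATG", "CTG", "GTG", "TTG", "ATT", "ATC"}
STOP_CODONS = {"TAA", "TAG", "TGA"}


@pytest.fixture(scope="session")
def toy_models() -> ToyModelSet:
    return make_toy_models()


@pytest.fixture(scope="session")
def scenario_seed1():
    return default_scenario(1)


# ---------------------------------------------------------------------------
# independent ORF oracle
# ---------------------------------------------------------------------------

def oracle_orfs(work: str, frame_offset: int, allow_edge_start: bool = True):
    """All ORFs of one frame in a working-strand string, as (begin, end,
    has_start, has_stop) in working coordinates.

    Independent derivation: list every in-frame codon position, mark stops,
    split into segments, and for each segment locate the first start codon by
    scanning positions — no shared code with the implementation.
    """
    positions = list(range(frame_offset, len(work) - 2, 3))
    codons = {p: work[p : p + 3] for p in positions}
    segments = []
    cur = []
    preceded_by_stop = False
    seg_edge = True
    for p in positions:
        if codons[p] in STOP_CODONS and "N" not in codons[p]:
            segments.append((cur, seg_edge, p))
            cur = []
            seg_edge = False
        else:
            cur.append(p)
    segments.append((cur, seg_edge, None))
    out = []
    for members, at_edge, stop_pos in segments:
        starts = [p for p in members
                  if codons[p] in START_CODONS and "N" not in codons[p]]
        if starts:
            begin, has_start = starts[0], True
        elif at_edge and allow_edge_start and members:
            begin, has_start = members[0], False
        else:
            continue
        if stop_pos is not None:
            out.append((begin, stop_pos + 3, has_start, True))
        else:
            if members:
                end = members[-1] + 3
                if end > begin:
                    out.append((begin, end, has_start, False))
    return out


def oracle_longest_orf(record: NucleotideRecord, hit, flank=500,
                       min_orf_nt=300, min_cov=0.5):
    """Longest qualifying ORF for a hit, derived independently.

    Coverage is computed residue-by-residue with Biopython translation of
    each hit codon, restricted to codons inside the candidate ORF.
    """
    if hit.frame > 0:
        hs, he, strand = hit.subject_start_1b - 1, hit.subject_end_1b, "+"
    else:
        hs, he, strand = hit.subject_end_1b - 1, hit.subject_start_1b, "-"
    ws = max(0, hs - flank)
    we = min(len(record.seq), he + flank)
    sub = record.seq[ws:we]
    work = str(Seq(sub).reverse_complement()) if strand == "-" else sub
    off = (hs - ws) % 3 if strand == "+" else (we - he) % 3

    degapped = hit.subject_protein.replace("-", "")
    best = None
    for a, b, _hst, _hsp in oracle_orfs(work, off):
        if strand == "+":
            fs, fe = ws + a, ws + b
        else:
            fs, fe = we - b, we - a
        if fe - fs < min_orf_nt:
            continue
        if degapped and 3 * len(degapped) == he - hs:
            m = 0
            for i, res in enumerate(degapped):
                if strand == "+":
                    cs, ce = hs + 3 * i, hs + 3 * i + 3
                    codon = record.seq[cs:ce]
                else:
                    ce = he - 3 * i
                    cs = ce - 3
                    codon = str(Seq(record.seq[cs:ce]).reverse_complement())
                if cs < fs or ce > fe:
                    continue
                aa = str(Seq(codon).translate(table=11))
                if aa != "X" and aa == res:
                    m += 1
            cov = m / len(degapped)
        else:
            cov = max(0, min(fe, he) - max(fs, hs)) / (he - hs)
        if cov < min_cov:
            continue
        if best is None or (fe - fs) > (best[1] - best[0]):
            best = (fs, fe)
    return best


# ---------------------------------------------------------------------------
# exhaustive profile-HMM path oracle
# ---------------------------------------------------------------------------

def oracle_forward_bits(model, protein: str, mode: str = "forward") -> float:
    """Bit score by explicit enumeration of every local state path.

    A path enters at any match state M_j on any residue i, moves through
    M/I/D states per the transition matrix, and exits from any match state;
    flank residues are null-emitted (odds 1).  Feasible for L <= 3 and
    sequences of length <= 5.
    """
    L = model.L
    lut = {aa: k for k, aa in enumerate(model.alphabet)}
    x = [lut.get(aa, -1) for aa in protein]
    n = len(x)
    mo = model.match_emissions / model.background
    io = model.insert_emissions / model.background
    t = model.transitions
    terms: list[float] = []

    def extend(j: int, state: int, i: int, odds: float) -> None:
        # state: 0=M, 1=I, 2=D at column j having consumed residues < i
        if state == 0:
            terms.append(odds)          # exit from this match state
        # transitions out of column j
        for tgt in range(3):
            p = t[j, state, tgt]
            if tgt == 1:                # insert: stay in column j, emit
                if i < n:
                    e = io[x[i]] if x[i] >= 0 else 1.0
                    extend(j, 1, i + 1, odds * p * e)
            else:
                nj = j + 1
                if nj >= L:
                    continue            # M/D past last column = exit (free only from M)
                if tgt == 0:            # match: emit
                    if i < n:
                        e = mo[nj, x[i]] if x[i] >= 0 else 1.0
                        extend(nj, 0, i + 1, odds * p * e)
                else:                   # delete: no emission
                    extend(nj, 2, i, odds * p)

    for i in range(n):
        for j in range(L):
            e = mo[j, x[i]] if x[i] >= 0 else 1.0
            extend(j, 0, i + 1, (1.0 / L) * e)

    if not terms:
        return float("-inf")
    if mode == "viterbi":
        return float(np.log2(max(terms)))
    return float(np.log2(sum(terms)))


def random_small_model(rng: np.random.Generator, L: int, alphabet: str = "ACDE"):
    """A valid random profile over a reduced alphabet, for oracle tests."""
    from ksclf.hmm import ProfileModel

    K = len(alphabet)
    me = rng.dirichlet(np.ones(K), size=L)
    ie = rng.dirichlet(np.ones(K))
    bg = rng.dirichlet(np.ones(K) * 5)
    tr = rng.dirichlet(np.ones(3), size=(L, 3))
    return ProfileModel(name=f"rand{L}", match_emissions=me,
                        insert_emissions=ie, background=bg,
                        transitions=tr, alphabet=alphabet)
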