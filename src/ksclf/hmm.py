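"""Profile hidden Markov models: build, score, calibrate, classify.

A profile HMM models a protein family as a chain of match columns, each with
its own emission distribution, plus insert and delete states.  Scores are
local-alignment log-odds against a background null, in bits: residues outside
the aligned core are emitted by the null and cancel, so flanking sequence is
free.  The architecture here is deliberately minimal so that an exhaustive
path-enumeration oracle can verify it:

* begin -> M_j entry, uniform 1/L over match states;
* per column j: match M_j, insert I_j, delete D_j, with transitions from each
  of {M_j, I_j, D_j} to {M_(j+1), I_j, D_(j+1)};
* exit permitted from every match state at no cost (local alignment).

Retention thresholds follow the distant-reference principle: a model's cutoff
is the score of a sequence from a cluster only distantly related to the
family (for the published KS/CLF models, the aurachin cluster: KS=352,
CLF=66 under the external HMMER scorer).  A builtin-scorer threshold is never
interchangeable with an external-scorer threshold — bit scales differ — so
builtin mode always calibrates on a cutoff protein via
:func:`calibrate_threshold`, and the printed constants apply only in
external-adapter mode.

All probability math is in log2 space with underflow-safe accumulation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Protocol, Sequence

import numpy as np

logger = logging.getLogger("ksclf")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: published retention thresholds for the external (HMMER) scorer only
EXTERNAL_KS_THRESHOLD = 352.0
EXTERNAL_CLF_THRESHOLD = 66.0

_STATE_INDEX = {"M": 0, "I": 1, "D": 2}
_NEG_INF = -np.inf


class ModelDegenerateError(ValueError):
    """Raised when a seed alignment yields zero match columns."""


@dataclass
class ProfileModel:
    """Profile HMM over a protein alphabet.

    ``transitions[j, s, t]`` is the probability of moving from state ``s`` of
    column ``j`` (0-based; s in M=0, I=1, D=2) to target ``t`` in
    (M_(j+1)=0, I_j=1, D_(j+1)=2).  The last column's M/D targets are exits.
    Every emission row and transition bundle sums to 1.
    """

    name: str
    match_emissions: np.ndarray        # (L, K)
    insert_emissions: np.ndarray       # (K,)
    background: np.ndarray             # (K,)
    transitions: np.ndarray            # (L, 3, 3)
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        L, K = self.match_emissions.shape
        if L < 1:
            raise ValueError("model must have at least one match state")
        if K != len(self.alphabet):
            raise ValueError("emission width does not match alphabet")
        for arr, what in ((self.match_emissions, "match emission"),
                          (self.transitions.reshape(-1, 3), "transition")):
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{what} rows must sum to 1 (max dev "
                                 f"{np.abs(sums - 1).max():.2e})")
        if not np.isclose(self.insert_emissions.sum(), 1.0, atol=1e-9):
            raise ValueError("insert emissions must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if self.transitions.shape != (L, 3, 3):
            raise ValueError("transitions must have shape (L, 3, 3)")

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]


@dataclass(frozen=True)
class ScoreReport:
    """One bit score (log2 odds vs the background null)."""

    sequence_id: str
    model_name: str
    bits: float
    mode: str = "forward"


def _encode(protein: str, alphabet: str) -> np.ndarray:
    """Map residues to alphabet indices; 'X' (unknown) maps to -1."""
    lut = {aa: i for i, aa in enumerate(alphabet)}
    out = np.empty(len(protein), dtype=int)
    for i, aa in enumerate(protein):
        if aa == "X":
            out[i] = -1
        elif aa in lut:
            out[i] = lut[aa]
        else:
            raise ValueError(f"residue {aa!r} not in model alphabet")
    return out


def score_sequence(
    model: ProfileModel,
    protein: str,
    mode: Literal["forward", "viterbi"] = "forward",
    sequence_id: str = "",
) -> ScoreReport:
    """Local-alignment bit score of a protein against a profile.

    Forward sums over all paths that enter at some match state, traverse
    match/insert/delete states, and exit from a match state; viterbi takes the
    single best path.  Flanking residues are emitted by the null and cancel.
    'X' residues are emitted with background probability (odds 1).
    """
    if not protein:
        raise ValueError("cannot score an empty protein")
    x = _encode(protein, model.alphabet)
    L, n = model.L, len(protein)

    with np.errstate(divide="ignore"):
        lodds_match = np.log2(model.match_emissions) - np.log2(model.background)
        lodds_ins = np.log2(model.insert_emissions) - np.log2(model.background)
        lt = np.log2(model.transitions)          # (L, 3, 3)
    entry = -np.log2(L)

    # per-residue odds rows; X -> odds 1 (0 bits)
    def em_m(i: int) -> np.ndarray:
        return lodds_match[:, x[i]] if x[i] >= 0 else np.zeros(L)

    def em_i(i: int) -> float:
        return lodds_ins[x[i]] if x[i] >= 0 else 0.0

    if mode == "forward":
        combine = np.logaddexp2
    elif mode == "viterbi":
        combine = np.maximum
    else:
        raise ValueError(f"unknown mode {mode!r}")

    def combine3(a, b, c):
        return combine(combine(a, b), c)

    neg = np.full(L, _NEG_INF)
    prev_m = prev_i = prev_d = neg
    total = _NEG_INF
    for i in range(n):
        # M_j at residue i: fresh entry, or continue from column j-1 at i-1
        shift = lambda a: np.concatenate(([_NEG_INF], a[:-1]))
        cont = combine3(shift(prev_m) + shift2(lt, 0, 0),
                        shift(prev_i) + shift2(lt, 1, 0),
                        shift(prev_d) + shift2(lt, 2, 0))
        cur_m = em_m(i) + combine(np.full(L, entry), cont)
        # I_j at residue i: from column j states at i-1
        cur_i = em_i(i) + combine3(prev_m + lt[:, 0, 1],
                                   prev_i + lt[:, 1, 1],
                                   prev_d + lt[:, 2, 1])
        # D_j at residue i: same-row scan from column j-1
        cur_d = np.full(L, _NEG_INF)
        for j in range(1, L):
            cur_d[j] = combine3(cur_m[j - 1] + lt[j - 1, 0, 2],
                                cur_i[j - 1] + lt[j - 1, 1, 2],
                                cur_d[j - 1] + lt[j - 1, 2, 2])
        prev_m, prev_i, prev_d = cur_m, cur_i, cur_d
        # exit free from every match state
        row_best = cur_m.max()
        if row_best > _NEG_INF:
            if mode == "forward":
                total = np.logaddexp2(total, row_best + np.log2(
                    np.exp2(cur_m - row_best).sum()))
            else:
                total = max(total, row_best)
    return ScoreReport(sequence_id=sequence_id, model_name=model.name,
                       bits=float(total), mode=mode)


def shift2(lt: np.ndarray, s: int, t: int) -> np.ndarray:
    """Transition log-probs from column j-1 aligned to target column j."""
    return np.concatenate(([_NEG_INF], lt[:-1, s, t]))


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_profile(
    seed_alignment: Sequence[str],
    name: str = "profile",
    match_gap_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    alphabet: str = AMINO_ACIDS,
    background: np.ndarray | None = None,
) -> ProfileModel:
    """Estimate a profile HMM from an aligned set of sequences.

    Columns whose gap fraction is below ``match_gap_threshold`` become match
    states.  Match emissions are residue counts plus background-proportional
    pseudocounts (weight 1.0 by default), normalized.  Transitions are counted
    from each row's observed local state path with +1 smoothing.  The result
    is deterministic for a fixed input.
    """
    rows = [r.upper() for r in seed_alignment]
    if len(rows) < 2:
        raise ValueError("need at least 2 aligned sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("aligned sequences must have equal length")
    K = len(alphabet)
    if background is None:
        background = np.full(K, 1.0 / K)
    background = np.asarray(background, dtype=float)
    lut = {aa: i for i, aa in enumerate(alphabet)}

    nrows = len(rows)
    gap_frac = [sum(r[c] == "-" for r in rows) / nrows for c in range(width)]
    match_cols = [c for c in range(width) if gap_frac[c] < match_gap_threshold]
    L = len(match_cols)
    if L == 0:
        raise ModelDegenerateError("no columns qualify as match states")

    counts = np.zeros((L, K))
    for j, c in enumerate(match_cols):
        for r in rows:
            aa = r[c]
            if aa in lut:
                counts[j, lut[aa]] += 1.0
    match_em = counts + pseudocount_weight * background
    match_em /= match_em.sum(axis=1, keepdims=True)

    # transition counts from local state paths (first match to last match)
    is_match = {c: j for j, c in enumerate(match_cols)}
    tcounts = np.zeros((L, 3, 3))
    for r in rows:
        path: list[tuple[str, int]] = []
        seen = 0
        for c in range(width):
            if c in is_match:
                j = is_match[c]
                path.append(("M" if r[c] != "-" else "D", j))
                seen = j
            elif r[c] != "-":
                path.append(("I", seen))
        # trim to local core: first M .. last M
        mpos = [k for k, (s, _) in enumerate(path) if s == "M"]
        if not mpos:
            continue
        core = path[mpos[0] : mpos[-1] + 1]
        for (s_a, j_a), (s_b, j_b) in zip(core, core[1:]):
            a, b = _STATE_INDEX[s_a], _STATE_INDEX[s_b]
            # target slot: M/D of next column -> 0/2; I of same column -> 1
            tcounts[j_a, a, 1 if s_b == "I" else b] += 1.0
    trans = tcounts + 1.0
    trans /= trans.sum(axis=2, keepdims=True)

    return ProfileModel(
        name=name,
        match_emissions=match_em,
        insert_emissions=background.copy(),
        background=background,
        transitions=trans,
        alphabet=alphabet,
    )


def sample_sequence(model: ProfileModel, seed: int) -> str:
    """Draw one protein from the model (deterministic per seed).

    The path enters at the first match state and walks the transition
    distributions column by column until it exits past the last column;
    delete states emit nothing, inserts emit from the insert distribution.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    j, state = 0, "M"
    K = len(model.alphabet)
    while True:
        if state == "M":
            out.append(model.alphabet[rng.choice(K, p=model.match_emissions[j])])
        elif state == "I":
            out.append(model.alphabet[rng.choice(K, p=model.insert_emissions)])
        t = rng.choice(3, p=model.transitions[j, _STATE_INDEX[state]])
        if t == 1:
            state = "I"          # stay in column j
            continue
        if j + 1 >= model.L:     # next M/D would pass the last column: exit
            break
        state = "M" if t == 0 else "D"
        j += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# thresholds and classification
# ---------------------------------------------------------------------------

class Scorer(Protocol):
    """Anything that turns a protein into a bit score for one model."""

    name: str

    def score(self, protein: str) -> float: ...


@dataclass
class BuiltinScorer:
    """Scores with the builtin forward algorithm."""

    model: ProfileModel
    mode: str = "forward"

    @property
    def name(self) -> str:
        return self.model.name

    def score(self, protein: str) -> float:
        return score_sequence(self.model, protein, mode=self.mode).bits


@dataclass(frozen=True)
class ClassifierConfig:
    """Retention thresholds and scorer mode.

    In ``external`` mode the published HMMER-scale constants (KS 352, CLF 66)
    are meaningful defaults; in ``builtin`` mode thresholds must come from
    :func:`calibrate_threshold` on cutoff proteins — the two bit scales are
    not interchangeable.
    """

    ks_threshold: float
    clf_threshold: float
    scorer: Literal["builtin", "external"] = "builtin"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ks_threshold) and np.isfinite(self.clf_threshold)):
            raise ValueError("thresholds must be finite")

    @classmethod
    def external(cls) -> "ClassifierConfig":
        return cls(ks_threshold=EXTERNAL_KS_THRESHOLD,
                   clf_threshold=EXTERNAL_CLF_THRESHOLD, scorer="external")


def calibrate_threshold(
    model: ProfileModel | Scorer, cutoff_protein: str, mode: str = "forward"
) -> float:
    """Score of the distant-reference cutoff protein; retention uses >= (inclusive),
    so the cutoff sequence itself is always retained under its own threshold."""
    if isinstance(model, ProfileModel):
        return score_sequence(model, cutoff_protein, mode=mode).bits
    return model.score(cutoff_protein)


def classify_protein(
    protein: str,
    ks_model: ProfileModel | Scorer,
    clf_model: ProfileModel | Scorer,
    config: ClassifierConfig,
) -> str:
    """Label a protein KS, CLF or none by thresholded profile scores.

    Both models are scored; a model whose threshold is met (>=) is a
    candidate.  No candidate -> "none"; one -> its label; both -> the higher
    bit score wins, with an exact tie resolved to "KS" (deterministic).
    """
    ks_scorer = BuiltinScorer(ks_model) if isinstance(ks_model, ProfileModel) else ks_model
    clf_scorer = BuiltinScorer(clf_model) if isinstance(clf_model, ProfileModel) else clf_model
    ks_bits = ks_scorer.score(protein)
    clf_bits = clf_scorer.score(protein)
    ks_ok = ks_bits >= config.ks_threshold
    clf_ok = clf_bits >= config.clf_threshold
    if ks_ok and clf_ok:
        if ks_bits == clf_bits:
            logger.debug("exact KS/CLF score tie (%.3f bits); labelling KS", ks_bits)
            return "KS"
        return "KS" if ks_bits > clf_bits else "CLF"
    if ks_ok:
        return "KS"
    if clf_ok:
        return "CLF"
    return "none"


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_model(model: ProfileModel, path: str | Path) -> None:
    """Serialize a model to a plain-text JSON schema (full float precision)."""
    payload = {
        "name": model.name,
        "L": model.L,
        "alphabet": model.alphabet,
        "background": model.background.tolist(),
        "insert_emissions": model.insert_emissions.tolist(),
        "match_emissions": model.match_emissions.tolist(),
        "transitions": model.transitions.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path: str | Path) -> ProfileModel:
    payload = json.loads(Path(path).read_text())
    return ProfileModel(
        name=payload["name"],
        match_emissions=np.array(payload["match_emissions"]),
        insert_emissions=np.array(payload["insert_emissions"]),
        background=np.array(payload["background"]),
        transitions=np.array(payload["transitions"]),
        alphabet=payload["alphabet"],
    )


# ---------------------------------------------------------------------------
# optional external HMMER adapter
# ---------------------------------------------------------------------------

class PyhmmerScorer:
    """External scorer backed by pyhmmer; bit scores on the HMMER scale.

    Use with the published thresholds (KS 352 / CLF 66).  Optional: the core
    pipeline runs entirely on the builtin scorer.
    """

    def __init__(self, hmm_path: str | Path):
        import pyhmmer  # deferred; optional dependency

        self._pyhmmer = pyhmmer
        with pyhmmer.plan7.HMMFile(str(hmm_path)) as fh:
            self.hmm = fh.read()
        self.name = self.hmm.name.decode()
        self._bg = pyhmmer.plan7.Background(self.hmm.alphabet)
        self._pipeline = pyhmmer.plan7.Pipeline(
            self.hmm.alphabet, background=self._bg, bias_filter=False,
            F1=1.0, F2=1.0, F3=1.0, E=1e9,
        )

    def score(self, protein: str) -> float:
        seq = self._pyhmmer.easel.TextSequence(name=b"q", sequence=protein)
        hits = self._pipeline.search_hmm(
            self.hmm, [seq.digitize(self.hmm.alphabet)])
        self._pipeline.clear()
        if len(hits) == 0:
            return float("-inf")
        return float(hits[0].score)
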