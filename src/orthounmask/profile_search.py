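"""Position-specific search models and the iterative unmasking loop.

Two model families drive remote-ortholog detection:

* :class:`PSSM` — a position-specific scoring matrix searched by local
  Smith–Waterman alignment with affine gaps (the PSI-BLAST-style engine);
* :class:`ProfileHMM` — a match/insert/delete profile HMM scored by local
  forward or Viterbi log-odds (the HMMER-style engine).

Because no external database statistics are available, statistical
significance is self-contained: a model is calibrated against shuffled or
synthetic decoys, an extreme-value (Gumbel) distribution is fitted to the
decoy score maxima, and E-values follow from its tail times the database
size (:func:`calibrate_evalues`).

:func:`iterative_search` implements the stepping-stone strategy: hits below
the inclusion E-value are realigned to the model and folded back into the
profile, so a moderately diverged intermediate admitted early can bridge
detection to orthologs too distant for the seed profile alone. Admission is
sticky (a sequence once admitted is never dropped), which makes the loop
monotone and guarantees convergence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._matrices import blosum62_tables
from .domain_features import henikoff_weights
from .seqio import AA_INDEX, AMINO_ACIDS, GAP, Alignment, SequenceRecord

AMINO_ACID_BY_INDEX = AMINO_ACIDS

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)
NEG = -1e30


def _encode(residues: str) -> np.ndarray:
    """Residue string -> indices; 'X' -> 20 (neutral)."""
    return np.array([AA_INDEX.get(ch, 20) for ch in residues], dtype=np.int64)


def _mixed_frequencies(f: np.ndarray, alpha: float, pseudocount_weight: float
                       ) -> np.ndarray:
    """Mix observed frequencies with BLOSUM62-conditional pseudocounts.

    g_a = sum_b P(a|b) f_b; result = (alpha f + w g) / (alpha + w).
    alpha is the effective observation count minus one, so a single
    sequence yields the pure conditional (BLAST-like) profile.
    """
    _, _, cond = blosum62_tables()
    g = cond @ f
    return (alpha * f + pseudocount_weight * g) / (alpha + pseudocount_weight)


def _column_frequencies(col: str, weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted residue frequencies of one column (gaps and X excluded);
    returns (frequencies over 20 aa, number of distinct residues)."""
    bg, _, _ = blosum62_tables()
    f = np.zeros(20)
    seen = set()
    for i, ch in enumerate(col):
        if ch == GAP or ch == "X":
            continue
        f[AA_INDEX[ch]] += weights[i]
        seen.add(ch)
    if f.sum() == 0:
        return bg.copy(), 1.0
    return f / f.sum(), float(len(seen))


# ===========================================================================
# PSSM
# ===========================================================================

@dataclass
class PSSM:
    """Per-position log-odds scores in bits over the 20 amino acids.

    ``source_columns`` maps profile positions back to the columns of the
    alignment the profile was built from. Gap penalties are in the BLAST
    half-bit convention (applied to doubled scores during search).
    """

    scores: np.ndarray              # (length, 20) bits
    background: np.ndarray          # (20,)
    pseudocount_weight: float
    gap_open: float = 11.0
    gap_extend: float = 1.0
    source_columns: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def score_of(self, pos: int, residue: str) -> float:
        if residue == "X":
            return 0.0
        return float(self.scores[pos, AA_INDEX[residue]])


def build_pssm(alignment: Alignment, weights: np.ndarray | None = None,
               pseudocount_weight: float = 5.0,
               max_gap_fraction: float = 0.5,
               gap_open: float = 11.0, gap_extend: float = 1.0) -> PSSM:
    """Build a PSSM from a seed alignment.

    Per column: weighted observed frequencies are mixed with BLOSUM62
    conditional pseudocounts (weight ``pseudocount_weight``, observed weight
    = mean distinct-residue count minus one) and converted to log2 odds
    against the BLOSUM62 background. Columns with gap fraction above
    ``max_gap_fraction`` are excluded from the profile (logged).
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    bg, _, _ = blosum62_tables()
    if weights is None:
        weights = henikoff_weights(alignment)
    n = alignment.n_rows
    cols, excluded = [], []
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        if col.count(GAP) / n > max_gap_fraction:
            excluded.append(j)
        else:
            cols.append(j)
    if excluded:
        logger.info("PSSM: excluded %d gappy columns: %s", len(excluded), excluded)
    if not cols:
        raise ValueError("no columns below the gap-fraction threshold")
    scores = np.zeros((len(cols), 20))
    for k, j in enumerate(cols):
        col = alignment.column(j)
        f, distinct = _column_frequencies(col, weights)
        alpha = max(distinct - 1.0, 0.0)
        mixed = _mixed_frequencies(f, alpha, pseudocount_weight)
        scores[k] = np.log2(mixed / bg)
    return PSSM(scores, bg.copy(), pseudocount_weight, gap_open, gap_extend,
                source_columns=cols)


def pssm_from_sequence(seq: SequenceRecord,
                       pseudocount_weight: float = 5.0,
                       gap_open: float = 11.0, gap_extend: float = 1.0) -> PSSM:
    """Single-sequence profile: pure BLOSUM62-conditional log-odds."""
    bg, _, cond = blosum62_tables()
    L = len(seq.residues)
    scores = np.zeros((L, 20))
    for k, ch in enumerate(seq.residues):
        if ch == "X":
            continue
        scores[k] = np.log2(cond[:, AA_INDEX[ch]] / bg)
    return PSSM(scores, bg.copy(), pseudocount_weight, gap_open, gap_extend,
                source_columns=list(range(L)))


# ---------------------------------------------------------------------------
# Local Smith-Waterman search with position-specific scores
# ---------------------------------------------------------------------------

@dataclass
class SearchHit:
    """A scored local match of a model on one target sequence.

    ``envelope`` is 0-based half-open on the target; ``model_span`` likewise
    on the model positions. ``evalue`` is None until a calibration is
    attached.
    """

    target_id: str
    envelope: tuple[int, int]
    score_bits: float
    evalue: float | None = None
    alignment: tuple[str, str] | None = None
    model_span: tuple[int, int] | None = None
    iteration_found: int = 0


def _substitution_grid(S2: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """(L, n) position-specific scores; 'X' target residues score 0."""
    sub = S2[:, np.minimum(enc, 19)]
    sub[:, enc == 20] = 0.0
    return sub


def _sw_traceback(M, Ix, Iy, sub, open_, ext, i, j):
    """Recover one local alignment ending at M[i, j]; ties prefer the
    diagonal, then the up (profile-consuming) move, then the left move."""
    tol = 1e-9
    prof_aln, targ_aln = [], []
    state = "M"
    end_i, end_j = i, j
    while True:
        if state == "M":
            prof_aln.append(i - 1)
            targ_aln.append(j - 1)
            rest = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if abs(rest) <= tol and not (
                    abs(rest - M[i, j]) <= tol or abs(rest - Ix[i, j]) <= tol
                    or abs(rest - Iy[i, j]) <= tol):
                break
            if abs(rest - M[i, j]) <= tol:
                state = "M"
            elif abs(rest - Ix[i, j]) <= tol:
                state = "Ix"
            elif abs(rest - Iy[i, j]) <= tol:
                state = "Iy"
            else:  # local start
                break
            if i == 0 or j == 0:
                break
        elif state == "Ix":
            prof_aln.append(i - 1)
            targ_aln.append(None)
            val = Ix[i, j]
            i = i - 1
            if abs(val - (M[i, j] - open_)) <= tol:
                state = "M"
            else:
                state = "Ix"
        else:  # Iy
            prof_aln.append(None)
            targ_aln.append(j - 1)
            val = Iy[i, j]
            j = j - 1
            if abs(val - (M[i, j] - open_)) <= tol:
                state = "M"
            else:
                state = "Iy"
    prof_aln.reverse()
    targ_aln.reverse()
    return prof_aln, targ_aln, (i, end_i), (j, end_j)


def search_pssm(pssm: PSSM, target: SequenceRecord, min_score_bits: float = 0.0,
                max_hits: int = 10) -> list[SearchHit]:
    """Local alignment search of a PSSM against one target.

    Returns non-overlapping hits with score above ``min_score_bits``,
    best-first; each round masks the previous hit's target envelope and
    realigns. E-values are not attached here (see
    :func:`calibrate_evalues`).
    """
    enc = _encode(target.residues)
    S2 = 2.0 * pssm.scores  # half-bit units to match the 11/1 gap costs
    open_, ext = pssm.gap_open, pssm.gap_extend
    base_sub = _substitution_grid(S2, enc)
    hits: list[SearchHit] = []
    masked = np.zeros(len(enc), dtype=bool)
    for _ in range(max_hits):
        sub = base_sub.copy()
        sub[:, masked] = NEG
        M, Ix, Iy, sub = _sw_matrices_from_sub(sub, open_, ext)
        best = float(M[1:, 1:].max(initial=NEG))
        if best / 2.0 <= min_score_bits:
            break
        i, j = np.unravel_index(int(np.argmax(M[1:, 1:])), M[1:, 1:].shape)
        i, j = i + 1, j + 1
        prof_aln, targ_aln, (pi0, pi1), (tj0, tj1) = _sw_traceback(
            M, Ix, Iy, sub, open_, ext, i, j)
        # profile side rendered as the per-position consensus residue
        consensus = "".join(AMINO_ACID_BY_INDEX[int(np.argmax(pssm.scores[p]))]
                            for p in range(pssm.length))
        pair = (
            "".join(GAP if p is None else consensus[p] for p in prof_aln),
            "".join(GAP if t is None else target.residues[t] for t in targ_aln),
        )
        hits.append(SearchHit(target.id, (tj0, tj1), best / 2.0,
                              alignment=pair, model_span=(pi0, pi1)))
        masked[tj0:tj1] = True
    hits.sort(key=lambda h: -h.score_bits)
    return hits


def _sw_matrices_from_sub(sub: np.ndarray, open_: float, ext: float):
    """DP fill from a precomputed (possibly masked) substitution grid."""
    L, n = sub.shape
    M = np.full((L + 1, n + 1), NEG)
    Ix = np.full((L + 1, n + 1), NEG)
    Iy = np.full((L + 1, n + 1), NEG)
    for i in range(1, L + 1):
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]),
                               np.maximum(Iy[i - 1, :-1], 0.0))
        M[i, 1:] = sub[i - 1] + prev_best
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - open_, Ix[i - 1, 1:] - ext)
        idx = np.arange(n + 1, dtype=float)
        run = np.maximum.accumulate(M[i, :-1] + idx[:-1] * ext)
        Iy[i, 1:] = run - open_ - (idx[1:] - 1.0) * ext
    return M, Ix, Iy, sub


# ===========================================================================
# Profile HMM
# ===========================================================================

@dataclass
class ProfileHMM:
    """Match/insert/delete profile HMM with local entry/exit.

    Entry is uniform over match states; every match state carries an
    explicit exit probability, so all outgoing-transition sets sum to 1.
    Insert states emit the background (zero log-odds). ``match_columns``
    maps match states to columns of the source alignment.
    """

    match_emissions: np.ndarray     # (L, 20)
    insert_emission: np.ndarray     # (20,) background
    mm: np.ndarray                  # M_k -> M_{k+1}
    mi: np.ndarray                  # M_k -> I_k
    md: np.ndarray                  # M_k -> D_{k+1}
    me: np.ndarray                  # M_k -> E
    im: np.ndarray                  # I_k -> M_{k+1} (last: -> E)
    ii: np.ndarray                  # I_k -> I_k
    dm: np.ndarray                  # D_k -> M_{k+1} (last: -> E)
    dd: np.ndarray                  # D_k -> D_{k+1}
    background: np.ndarray
    match_columns: list = field(default_factory=list)
    weighting: str = "henikoff"
    gap_fraction_threshold: float = 0.5

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        L = self.n_match
        assert np.all(np.abs(self.match_emissions.sum(axis=1) - 1) < 1e-9)
        out_m = self.mm + self.mi + self.md + self.me
        assert np.all(np.abs(out_m - 1) < 1e-9)
        assert np.all(np.abs(self.im + self.ii - 1) < 1e-9)
        assert np.all(np.abs(self.dm + self.dd - 1) < 1e-9)
        assert L >= 1


DEFAULT_EXIT_PROB = 0.05
TRANSITION_PSEUDOCOUNT = 0.5


def build_profile_hmm(alignment: Alignment,
                      gap_fraction_threshold: float = 0.5,
                      weights: np.ndarray | None = None,
                      pseudocount_weight: float = 5.0,
                      exit_prob: float = DEFAULT_EXIT_PROB) -> ProfileHMM:
    """Build a profile HMM from a seed alignment.

    Columns with gap fraction <= ``gap_fraction_threshold`` become match
    states; the rest feed insert states. Match emissions are weighted counts
    mixed with BLOSUM62-conditional pseudocounts; transitions come from
    weighted state-path counts with additive smoothing.
    """
    bg, _, _ = blosum62_tables()
    if weights is None:
        weights = henikoff_weights(alignment)
    n = alignment.n_rows
    match_cols = [j for j in range(alignment.n_columns)
                  if alignment.column(j).count(GAP) / n <= gap_fraction_threshold]
    if not match_cols:
        raise ValueError(
            "no column qualifies as a match state; raise gap_fraction_threshold")
    L = len(match_cols)
    match_set = set(match_cols)
    col_to_state = {j: k for k, j in enumerate(match_cols)}

    emissions = np.zeros((L, 20))
    for k, j in enumerate(match_cols):
        f, distinct = _column_frequencies(alignment.column(j), weights)
        emissions[k] = _mixed_frequencies(f, max(distinct - 1.0, 0.0),
                                          pseudocount_weight)
        emissions[k] /= emissions[k].sum()

    # weighted state-path transition counts (counts on the scale of n rows)
    a = TRANSITION_PSEUDOCOUNT
    cMM = np.full(L, a); cMI = np.full(L, a); cMD = np.full(L, a)
    cIM = np.full(L, a); cII = np.full(L, a)
    cDM = np.full(L, a); cDD = np.full(L, a)
    for i, (_, row) in enumerate(alignment.rows):
        w = weights[i] * n
        prev = None  # (kind, state index)
        for j, ch in enumerate(row):
            if j in match_set:
                here = ("M" if ch != GAP else "D", col_to_state[j])
            elif ch != GAP:
                # insert residue attaches to the preceding match-state slot
                k = col_to_state.get(max((c for c in match_cols if c < j),
                                         default=-1), -1)
                here = ("I", k)
            else:
                continue
            if prev is not None:
                pk, ps = prev
                hk, _ = here
                if pk == "M":
                    (cMM if hk == "M" else cMI if hk == "I" else cMD)[ps] += w
                elif pk == "I":
                    (cIM if hk == "M" else cII)[ps if ps >= 0 else 0] += w
                else:
                    (cDM if hk == "M" else cDD)[ps] += w
            if here[0] == "I" and here[1] < 0:
                prev = None  # insert before the first match state: flank
            else:
                prev = here
    totM = cMM + cMI + cMD
    mm = (1 - exit_prob) * cMM / totM
    mi = (1 - exit_prob) * cMI / totM
    md = (1 - exit_prob) * cMD / totM
    me = np.full(L, exit_prob)
    # last match state transitions only to its insert or to E
    mi[L - 1] = (1 - exit_prob) * cMI[L - 1] / (cMI[L - 1] + cMM[L - 1] + cMD[L - 1])
    mm[L - 1] = 0.0
    md[L - 1] = 0.0
    me[L - 1] = 1.0 - mi[L - 1]
    totI = cIM + cII
    im = cIM / totI
    ii = cII / totI
    totD = cDM + cDD
    dm = cDM / totD
    dd = cDD / totD
    dm[L - 1] = 1.0  # terminal delete exits
    dd[L - 1] = 0.0
    hmm = ProfileHMM(emissions, bg.copy(), mm, mi, md, me, im, ii, dm, dd,
                     bg.copy(), match_columns=match_cols,
                     gap_fraction_threshold=gap_fraction_threshold)
    hmm.validate()
    return hmm


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(x > 0, np.log(np.maximum(x, 1e-300)), NEG)


def _hmm_arrays(hmm: ProfileHMM, residues: str):
    """Shared precomputation: per-position emission log-odds (natural log)."""
    enc = _encode(residues)
    emo = _log(hmm.match_emissions / hmm.background[None, :])  # (L, 20)
    em = np.where(enc[None, :] == 20, 0.0,
                  emo[:, np.minimum(enc, 19)])
    em[:, enc == 20] = 0.0
    return em  # (L, n)


def hmm_score(hmm: ProfileHMM, seq: SequenceRecord, mode: str = "forward") -> float:
    """Local log2-odds score of a sequence against the profile HMM.

    Unmatched flanking residues are emitted at background (zero log-odds).
    ``forward`` sums over all local paths; ``viterbi`` takes the best.
    """
    if mode == "viterbi":
        return viterbi_align(hmm, seq).score_bits
    L = hmm.n_match
    n = len(seq.residues)
    em = _hmm_arrays(hmm, seq.residues)
    lmm, lmi, lmd = _log(hmm.mm), _log(hmm.mi), _log(hmm.md)
    lme, lim, lii = _log(hmm.me), _log(hmm.im), _log(hmm.ii)
    ldm, ldd = _log(hmm.dm), _log(hmm.dd)
    lentry = -math.log(L)
    fM = np.full(L, NEG)
    fI = np.full(L, NEG)
    fD = np.full(L, NEG)
    total = NEG
    # prefix sums of D->D: cdd[k] = sum(ldd[:k]); cddp[j] = sum(ldd[:j+1]),
    # so a chain M_j -> D_{j+1} -> ... -> D_k costs lmd[j] + cdd[k] - cddp[j]
    cdd = np.concatenate(([0.0], np.cumsum(ldd[:-1])))
    cddp = np.cumsum(ldd)
    for t in range(n):
        pM, pI, pD = fM, fI, fD
        # match: entry, M->M, I->M, D->M (all from position t-1)
        stay = np.full(L, NEG)
        stay[1:] = np.logaddexp(
            np.logaddexp(pM[:-1] + lmm[:-1], pI[:-1] + lim[:-1]),
            pD[:-1] + ldm[:-1])
        fM = em[:, t] + np.logaddexp(stay, lentry)
        # insert: M->I, I->I (background emission, zero log-odds)
        fI = np.logaddexp(pM + lmi, pI + lii)
        # delete chain within the same time slice, vectorized via prefix sums
        u = fM + lmd - cddp
        acc = np.logaddexp.accumulate(u)
        fD = np.full(L, NEG)
        fD[1:] = cdd[1:] + acc[:-1]
        total = np.logaddexp(total, float(
            np.logaddexp.reduce(fM + lme)))
    return total / LN2


@dataclass
class ViterbiAlignment:
    """Best local path of a sequence through the model."""

    score_bits: float
    target_span: tuple[int, int]        # 0-based half-open on the sequence
    model_span: tuple[int, int]         # 0-based half-open on match states
    match_row: str                      # length n_match; '-' for unvisited/deleted
    pairs: list                         # (match_state or None, seq_pos or None)


def viterbi_align(hmm: ProfileHMM, seq: SequenceRecord) -> ViterbiAlignment:
    """Viterbi local alignment with full traceback.

    ``match_row`` places the aligned residues into model match-state
    coordinates (insert-state residues are dropped), which is what the
    iterative search uses to grow its profile alignment.
    """
    L = hmm.n_match
    n = len(seq.residues)
    em = _hmm_arrays(hmm, seq.residues)
    lmm, lmi, lmd = _log(hmm.mm), _log(hmm.mi), _log(hmm.md)
    lme, lim, lii = _log(hmm.me), _log(hmm.im), _log(hmm.ii)
    ldm, ldd = _log(hmm.dm), _log(hmm.dd)
    lentry = -math.log(L)
    vM = np.full((L, n), NEG)
    vI = np.full((L, n), NEG)
    vD = np.full((L, n), NEG)
    cdd = np.concatenate(([0.0], np.cumsum(ldd[:-1])))
    cddp = np.cumsum(ldd)
    for t in range(n):
        pM = vM[:, t - 1] if t else np.full(L, NEG)
        pI = vI[:, t - 1] if t else np.full(L, NEG)
        pD = vD[:, t - 1] if t else np.full(L, NEG)
        stay = np.full(L, NEG)
        if L > 1:
            stay[1:] = np.maximum(np.maximum(pM[:-1] + lmm[:-1],
                                             pI[:-1] + lim[:-1]),
                                  pD[:-1] + ldm[:-1])
        vM[:, t] = em[:, t] + np.maximum(stay, lentry)
        vI[:, t] = np.maximum(pM + lmi, pI + lii)
        u = vM[:, t] + lmd - cddp
        run = np.maximum.accumulate(u)
        vD[1:, t] = cdd[1:] + run[:-1]
    ends = vM + lme[:, None]
    k, t = np.unravel_index(int(np.argmax(ends)), ends.shape)
    score = float(ends[k, t])
    # traceback
    pairs = []
    state = "M"
    tol = 1e-9
    kk, tt = k, t
    while True:
        if state == "M":
            pairs.append((kk, tt))
            rest = vM[kk, tt] - em[kk, tt]
            if abs(rest - (-math.log(L))) <= tol and (kk == 0 or tt == 0):
                break
            prev_t = tt - 1
            if kk > 0 and prev_t >= 0:
                if abs(rest - (vM[kk - 1, prev_t] + lmm[kk - 1])) <= tol:
                    kk, tt, state = kk - 1, prev_t, "M"; continue
                if abs(rest - (vI[kk - 1, prev_t] + lim[kk - 1])) <= tol:
                    kk, tt, state = kk - 1, prev_t, "I"; continue
                if abs(rest - (vD[kk - 1, prev_t] + ldm[kk - 1])) <= tol:
                    kk, tt, state = kk - 1, prev_t, "D"; continue
            break  # local entry
        elif state == "I":
            pairs.append((None, tt))
            val = vI[kk, tt]
            prev_t = tt - 1
            if prev_t < 0:
                break
            if abs(val - (vM[kk, prev_t] + lmi[kk])) <= tol:
                tt, state = prev_t, "M"
            else:
                tt, state = prev_t, "I"
        else:  # D
            pairs.append((kk, None))
            val = vD[kk, tt]
            if abs(val - (vM[kk - 1, tt] + lmd[kk - 1])) <= tol:
                kk, state = kk - 1, "M"
            else:
                kk, state = kk - 1, "D"
    pairs.reverse()
    match_row = [GAP] * L
    t_positions = [p[1] for p in pairs if p[1] is not None]
    k_positions = [p[0] for p in pairs if p[0] is not None]
    for mk, tp in pairs:
        if mk is not None and tp is not None:
            match_row[mk] = seq.residues[tp]
    return ViterbiAlignment(
        score_bits=score / LN2,
        target_span=(min(t_positions), max(t_positions) + 1) if t_positions else (0, 0),
        model_span=(min(k_positions), max(k_positions) + 1) if k_positions else (0, 0),
        match_row="".join(match_row),
        pairs=pairs,
    )


# ===========================================================================
# Empirical E-value calibration
# ===========================================================================

@dataclass
class CalibrationCurve:
    """Gumbel tail fitted to decoy score maxima; turns bits into E-values."""

    mu: float
    lam: float
    n_decoys: int
    seed: int
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.n_decoys < 50:
            raise ValueError("at least 50 decoys required")

    def pvalue(self, score_bits: float) -> float:
        z = -self.lam * (score_bits - self.mu)
        # P(S >= s) under Gumbel = 1 - exp(-exp(z))
        return float(-np.expm1(-np.exp(np.clip(z, -700, 700))))

    def evalue(self, score_bits: float, db_size: int) -> float:
        return db_size * self.pvalue(score_bits)


def _model_score(model, seq: SequenceRecord) -> float:
    if isinstance(model, ProfileHMM):
        return viterbi_align(model, seq).score_bits
    hits = search_pssm(model, seq, min_score_bits=-1e9, max_hits=1)
    return hits[0].score_bits if hits else 0.0


def make_shuffled_decoys(targets: list, n_decoys: int, rng) -> list:
    """Length- and composition-matched decoys by residue shuffling."""
    decoys = []
    for d in range(n_decoys):
        src = targets[int(rng.integers(len(targets)))]
        letters = list(src.residues)
        rng.shuffle(letters)
        decoys.append(SequenceRecord(f"decoy_{d}", "".join(letters), "protein"))
    return decoys


def fit_gumbel(scores: np.ndarray, fix_lambda: float | None = None
               ) -> tuple[float, float]:
    """Gumbel (mu, lambda) from decoy scores.

    Full MLE by default; with ``fix_lambda``, only the location is
    estimated (closed form). Fixing lambda at ln 2 for Viterbi log2-odds
    scores is the conservative, HMMER-style choice — the fitted slope on a
    small decoy sample is noisy, and overestimating it deflates tail
    E-values, which is the expensive error in an admission loop.
    """
    scores = np.asarray(scores, dtype=float)
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate decoy scores (zero variance)")
    if fix_lambda is None:
        loc, scale = stats.gumbel_r.fit(scores)
        return float(loc), float(1.0 / scale)
    beta = 1.0 / fix_lambda
    mu = -beta * math.log(float(np.mean(np.exp(-scores / beta))))
    return float(mu), float(fix_lambda)


#: conservative slope for Viterbi bit scores (scores are log2-odds)
VITERBI_LAMBDA = math.log(2.0)


def calibrate_evalues(model, targets: list, n_decoys: int = 200,
                      seed: int = 0, decoys: list | None = None,
                      fix_lambda: float | None = None,
                      model_id: str = "") -> CalibrationCurve:
    """Fit a Gumbel null to the model's scores on shuffled decoys.

    E(score, db_size) = db_size * (1 - exp(-exp(-lambda (score - mu)))),
    monotone decreasing in score and linear in database size.
    """
    if n_decoys < 50:
        raise ValueError("n_decoys must be >= 50")
    rng = np.random.default_rng(seed)
    if decoys is None:
        decoys = make_shuffled_decoys(targets, n_decoys, rng)
    scores = np.array([_model_score(model, d) for d in decoys])
    mu, lam = fit_gumbel(scores, fix_lambda)
    return CalibrationCurve(mu=mu, lam=lam,
                            n_decoys=len(decoys), seed=seed, model_id=model_id)


# ===========================================================================
# Iterative stepping-stone search
# ===========================================================================

@dataclass
class IterativeSearchResult:
    model: ProfileHMM
    hits: list                       # SearchHit, one per reported target
    admitted: dict                   # id -> iteration admitted
    n_iterations: int
    converged: bool
    profile_rows: list               # (id, match-row string) of the final profile


def iterative_search(seed_alignment: Alignment, proteomes: list,
                     inclusion_evalue: float = 0.5,
                     report_evalue: float = 5.0,
                     max_iterations: int = 10,
                     exclusion_list: set | None = None,
                     seed: int = 0,
                     n_decoys: int = 200) -> IterativeSearchResult:
    """Iterative profile-HMM search with sticky admission.

    Each round builds a model from the current profile alignment, calibrates
    it on shuffled decoys, scores every proteome sequence, and admits hits
    with E-value at or below ``inclusion_evalue`` (unless excluded by id).
    Admitted sequences are realigned to the model by Viterbi and their
    match-state rows are appended to the profile; admission is sticky, so
    the profile grows monotonically and the loop converges. Deterministic
    given ``seed``.
    """
    exclusion_list = exclusion_list or set()
    targets: list[SequenceRecord] = []
    for prot in proteomes:
        targets.extend(prot)
    if not targets:
        raise ValueError("empty proteome list")
    db_size = len(targets)
    seed_ids = set(seed_alignment.ids)

    hmm = build_profile_hmm(seed_alignment)
    profile_rows = [(rid, "".join(row[j] for j in hmm.match_columns))
                    for rid, row in seed_alignment.rows]
    admitted: dict[str, int] = {}
    best_hits: dict[str, SearchHit] = {}
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        calib = calibrate_evalues(hmm, targets, n_decoys=n_decoys,
                                  seed=seed * 1000 + it,
                                  fix_lambda=VITERBI_LAMBDA,
                                  model_id=f"iter{it}")
        new_rows = []
        for tgt in targets:
            if tgt.id in seed_ids:
                continue
            aln = viterbi_align(hmm, tgt)
            ev = calib.evalue(aln.score_bits, db_size)
            if ev <= report_evalue:
                prev = best_hits.get(tgt.id)
                if prev is None:
                    best_hits[tgt.id] = SearchHit(
                        tgt.id, aln.target_span, aln.score_bits, ev,
                        model_span=aln.model_span, iteration_found=it)
                elif ev < (prev.evalue if prev.evalue is not None else np.inf):
                    best_hits[tgt.id] = SearchHit(
                        tgt.id, aln.target_span, aln.score_bits, ev,
                        model_span=aln.model_span,
                        iteration_found=prev.iteration_found)
            if (ev <= inclusion_evalue and tgt.id not in admitted
                    and tgt.id not in exclusion_list):
                admitted[tgt.id] = it
                new_rows.append((tgt.id, aln.match_row))
        if not new_rows:
            converged = True
            break
        kept = [(rid, row) for rid, row in new_rows if set(row) != {GAP}]
        profile_rows = profile_rows + kept
        new_aln = Alignment(profile_rows)
        hmm = build_profile_hmm(new_aln)
        # re-express rows in the (possibly smaller) new match-column space
        profile_rows = [(rid, "".join(row[j] for j in hmm.match_columns))
                        for rid, row in new_aln.rows]
    hits = sorted(best_hits.values(), key=lambda h: h.evalue)
    return IterativeSearchResult(hmm, hits, admitted, it, converged,
                                 profile_rows)


# ===========================================================================
# Reciprocal validation
# ===========================================================================

def reciprocal_check(candidate: SequenceRecord, reference_orthologs: list,
                     background_proteome: list, seed: int = 0,
                     inclusion_evalue: float = 0.5,
                     n_decoys: int = 200) -> tuple[bool, str | None]:
    """Reciprocal-search sanity test for a candidate ortholog.

    Builds a single-sequence profile from the candidate and searches the
    references together with a background proteome; passes iff the best
    E-value hit is a reference ortholog below the inclusion threshold.
    """
    ref_ids = {r.id for r in reference_orthologs}
    if not ref_ids:
        raise ValueError("reference set is empty")
    if ref_ids & {b.id for b in background_proteome}:
        raise ValueError("reference and background ids overlap")
    pssm = pssm_from_sequence(candidate)
    background = [b for b in background_proteome if b.id != candidate.id]
    targets = list(reference_orthologs) + background
    calib = calibrate_evalues(pssm, targets, n_decoys=n_decoys, seed=seed,
                              fix_lambda=VITERBI_LAMBDA,
                              model_id=f"reciprocal:{candidate.id}")
    best_id, best_ev = None, np.inf
    for tgt in targets:
        sc = _model_score(pssm, tgt)
        ev = calib.evalue(sc, len(targets))
        if ev < best_ev:
            best_id, best_ev = tgt.id, ev
    ok = best_id in ref_ids and best_ev <= inclusion_evalue
    return ok, best_id
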