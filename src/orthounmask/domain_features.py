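"""Conservation statistics, alignment trimming and scm3-style domain scoring.

The scm3 domain — the short CENPA-chaperone module shared by HJURP, Scm3
and CAL1 — carries three sequence signatures that survive even when overall
identity collapses below 10%: a near-invariant KY dipeptide anchor,
hydrophobic residues spaced 2–4 apart across the ~25-residue recognition
helix, and an alternating acidic (E/D) / short-hydrophobic (I/L/V) pattern
over the ~10-residue β-strand downstream of the anchor.
:func:`score_scm3_features` turns those signatures into an explicit,
decomposable score; it is this package's stand-in for profile–profile
(HHpred-style) confirmation, and all three components are reported
separately so thresholds can be tuned per clade.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import AA_INDEX, AMINO_ACIDS, GAP, Alignment, SequenceRecord

logger = logging.getLogger(__name__)

#: hydrophobic set for the helix periodicity signal. Y is deliberately
#: excluded: the anchor tyrosine is scored by the anchor component.
HYDROPHOBIC = set("AVLIMFWC")
ACIDIC = set("ED")
SHORT_HYDROPHOBIC = set("ILV")

HELIX_WINDOW = 25   # ~25 aa recognition helix
STRAND_WINDOW = 10  # ~10 aa beta-strand downstream of the anchor

MAX_INFO = math.log2(20.0)


# ---------------------------------------------------------------------------
# Sequence weighting and trimming
# ---------------------------------------------------------------------------

def henikoff_weights(alignment: Alignment) -> np.ndarray:
    """Henikoff & Henikoff position-based row weights, normalized to sum 1.

    Each column contributes 1/(r*s) to every row, where r is the number of
    distinct symbols in the column and s the multiplicity of the row's
    symbol. Gaps are treated as a symbol type of their own.
    """
    n = alignment.n_rows
    weights = np.zeros(n)
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        for i, ch in enumerate(col):
            weights[i] += 1.0 / (r * counts[ch])
    total = weights.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return weights / total


def trim_alignment(alignment: Alignment, max_gap_fraction: float = 0.5
                   ) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    Automated stand-in for manual removal of species-specific insertions
    before logo plotting and profile building. Returns the trimmed alignment
    and the removed column indices (0-based, in the input coordinates).
    """
    if not 0 < max_gap_fraction < 1:
        raise ValueError("max_gap_fraction must be in (0, 1)")
    n = alignment.n_rows
    removed = [
        j for j in range(alignment.n_columns)
        if alignment.column(j).count(GAP) / n > max_gap_fraction
    ]
    if len(removed) == alignment.n_columns:
        raise ValueError("trimming removed every column")
    if not removed:
        return alignment, []
    keep = [j for j in range(alignment.n_columns) if j not in set(removed)]
    rows = [(rid, "".join(res[j] for j in keep)) for rid, res in alignment.rows]
    return Alignment(rows, molecule=alignment.molecule), removed


# ---------------------------------------------------------------------------
# Logo / information content
# ---------------------------------------------------------------------------

@dataclass
class LogoMatrix:
    """Per-column weighted residue frequencies and information content."""

    frequencies: np.ndarray          # (n_columns, 20), each row sums to 1
    information: np.ndarray          # bits per column
    weighting: str = "uniform"
    small_sample_corrected: bool = False

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]

    def to_tsv(self, path) -> None:
        header = "column\tinformation\t" + "\t".join(AMINO_ACIDS)
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for j in range(self.n_columns):
                freqs = "\t".join(f"{f:.6g}" for f in self.frequencies[j])
                fh.write(f"{j + 1}\t{self.information[j]:.6g}\t{freqs}\n")


def column_information(alignment: Alignment,
                       weights: np.ndarray | None = None,
                       small_sample_correction: bool = False) -> LogoMatrix:
    """Weighted per-column frequencies and information content in bits.

    info(col) = log2(20) - H(col); gaps and 'X' are excluded from the
    frequency mass (renormalized). The optional small-sample correction
    subtracts (20-1)/(2 ln2 n) with n the number of non-gap symbols.
    """
    n = alignment.n_rows
    if weights is None:
        weights = np.full(n, 1.0 / n)
        tag = "uniform"
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
        tag = "custom"
    ncol = alignment.n_columns
    freqs = np.zeros((ncol, 20))
    info = np.zeros(ncol)
    for j in range(ncol):
        col = alignment.column(j)
        f = np.zeros(20)
        n_obs = 0
        for i, ch in enumerate(col):
            if ch == GAP or ch == "X":
                continue
            f[AA_INDEX[ch]] += weights[i]
            n_obs += 1
        if f.sum() == 0:  # column of only X residues: uninformative
            freqs[j] = np.full(20, 1.0 / 20)
            info[j] = 0.0
            continue
        f /= f.sum()
        nz = f[f > 0]
        h = -float(np.sum(nz * np.log2(nz)))
        ic = MAX_INFO - h
        if small_sample_correction and n_obs > 0:
            ic -= (20 - 1) / (2.0 * math.log(2.0) * n_obs)
        freqs[j] = f
        info[j] = ic
    return LogoMatrix(freqs, info, weighting=tag,
                      small_sample_corrected=small_sample_correction)


# ---------------------------------------------------------------------------
# scm3 feature scoring
# ---------------------------------------------------------------------------

@dataclass
class DomainFeatureScore:
    """Decomposed scm3-domain evidence for one sequence window.

    ``composite = w_anchor * anchor_indicator + w_period * periodicity
    + w_altern * alternation``; anchor_indicator is 1 for a KY anchor,
    ``r_anchor_value`` (default 0.5) for the conservative RY substitution,
    0 when absent.
    """

    anchor_position: int | None      # 0-based index of the K/R, or None
    anchor_residues: str             # "KY", "RY" or ""
    penalty_applied: bool
    periodicity_score: float
    alternation_score: float
    composite: float
    window: tuple[int, int]          # [start, end) searched
    weights: dict = field(default_factory=dict)


DEFAULT_FEATURE_WEIGHTS = {"anchor": 1.0, "periodicity": 0.05, "alternation": 0.1}
R_ANCHOR_VALUE = 0.5


def _periodicity(seq: str, anchor: int) -> float:
    """Count hydrophobic residue pairs at spacings 2-4 in the helix window
    (the ``HELIX_WINDOW`` residues ending at, and including, the anchor)."""
    start = max(0, anchor - HELIX_WINDOW + 1)
    window = seq[start:anchor + 1]
    hydro = [i for i, ch in enumerate(window) if ch in HYDROPHOBIC]
    count = 0
    for a in range(len(hydro)):
        for b in range(a + 1, len(hydro)):
            if 2 <= hydro[b] - hydro[a] <= 4:
                count += 1
    return float(count)


def _alternation(seq: str, anchor: int) -> float:
    """Longest alternating acidic/short-hydrophobic run in the strand window
    (the ``STRAND_WINDOW`` residues after the anchor dipeptide)."""
    start = anchor + 2
    window = seq[start:start + STRAND_WINDOW]

    def cls(ch: str) -> int:
        if ch in ACIDIC:
            return 0
        if ch in SHORT_HYDROPHOBIC:
            return 1
        return -1

    best = run = 0
    prev = -1
    for ch in window:
        c = cls(ch)
        if c == -1:
            run = 0
        elif run == 0 or c == prev:
            run = 1
        else:
            run += 1
        prev = c
        best = max(best, run)
    return float(best)


def score_scm3_features(seq: SequenceRecord | str,
                        search_region: tuple[int, int] | None = None,
                        weights: dict | None = None) -> DomainFeatureScore:
    """Score a protein for the three scm3-domain sequence signatures.

    Every [KR]Y dipeptide in the search region is evaluated as a candidate
    anchor and the highest-composite placement is reported; an R anchor is
    accepted at reduced value (the only substitution seen at the lysine is
    conservative). Sequences shorter than 12 residues report an absent
    anchor and zero scores.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    w = dict(DEFAULT_FEATURE_WEIGHTS)
    if weights:
        w.update(weights)
    lo, hi = (0, len(residues)) if search_region is None else search_region
    empty = DomainFeatureScore(None, "", False, 0.0, 0.0, 0.0, (lo, hi), w)
    if len(residues) < 12:
        return empty
    best: DomainFeatureScore | None = None
    for i in range(lo, min(hi, len(residues)) - 1):
        first, second = residues[i], residues[i + 1]
        if second != "Y" or first not in "KR":
            continue
        penalty = first == "R"
        anchor_val = R_ANCHOR_VALUE if penalty else 1.0
        per = _periodicity(residues, i)
        alt = _alternation(residues, i)
        comp = (w["anchor"] * anchor_val + w["periodicity"] * per
                + w["alternation"] * alt)
        cand = DomainFeatureScore(i, first + "Y", penalty, per, alt, comp,
                                  (lo, hi), w)
        if best is None or cand.composite > best.composite:
            best = cand
    return best if best is not None else empty
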