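"""Goldman–Yang codon substitution machinery (standard genetic code).

Shared by the dN/dS estimators and the codon-family simulator: the 61
sense-codon state space, the GY94 rate matrix Q(kappa, omega, pi), and
transition probabilities via eigendecomposition of the reversible
symmetrization. Q is scaled to one expected substitution per codon site per
unit branch length.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"
STOP_CODONS = set(_TABLE.stop_codons)
SENSE_CODONS = [
    "".join(c) for c in product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_PURINES = {"A", "G"}


def is_transition(n1: str, n2: str) -> bool:
    return (n1 in _PURINES) == (n2 in _PURINES) and n1 != n2


def codon_diff(c1: str, c2: str) -> list[int]:
    return [k for k in range(3) if c1[k] != c2[k]]


def is_synonymous(c1: str, c2: str) -> bool:
    return CODON_AA[c1] == CODON_AA[c2]


def f3x4_frequencies(codon_rows: list[str], floor: float = 1e-4) -> np.ndarray:
    """F3x4 equilibrium codon frequencies from observed per-position
    nucleotide frequencies (gaps skipped), floored and renormalized."""
    counts = np.zeros((3, 4))
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for row in codon_rows:
        for start in range(0, len(row), 3):
            codon = row[start:start + 3]
            if "-" in codon or any(n not in nt_index for n in codon):
                continue
            for k in range(3):
                counts[k, nt_index[codon[k]]] += 1
    counts += 1.0  # additive smoothing against absent nucleotides
    pos = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        pos[0, nt_index[c[0]]] * pos[1, nt_index[c[1]]] * pos[2, nt_index[c[2]]]
        for c in SENSE_CODONS
    ])
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 instantaneous rate matrix over sense codons.

    Single-nucleotide changes only: rate ∝ pi_j, times kappa for
    transitions, times omega for nonsynonymous changes. Scaled so the
    expected substitution rate at equilibrium is 1 per codon site.
    """
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = codon_diff(ci, cj)
            if len(diff) != 1:
                continue
            k = diff[0]
            rate = pi[j]
            if is_transition(ci[k], cj[k]):
                rate *= kappa
            if not is_synonymous(ci, cj):
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    return Q / scale


def substitution_proportions(kappa: float, omega: float, pi: np.ndarray
                             ) -> tuple[float, float]:
    """Equilibrium proportions (rho_S, rho_N) of synonymous and
    nonsynonymous substitutions under Q(kappa, omega, pi)."""
    Q = gy94_rate_matrix(kappa, omega, pi)
    rho_s = rho_n = 0.0
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j or Q[i, j] == 0:
                continue
            flux = pi[i] * Q[i, j]
            if is_synonymous(ci, cj):
                rho_s += flux
            else:
                rho_n += flux
    total = rho_s + rho_n
    return rho_s / total, rho_n / total


@dataclass
class CodonRates:
    """Eigendecomposed reversible Q for fast transition probabilities."""

    Q: np.ndarray
    pi: np.ndarray
    eigvals: np.ndarray
    left: np.ndarray    # diag(1/sqrt(pi)) U
    right: np.ndarray   # U^T diag(sqrt(pi))

    @classmethod
    def from_parameters(cls, kappa: float, omega: float, pi: np.ndarray
                        ) -> "CodonRates":
        Q = gy94_rate_matrix(kappa, omega, pi)
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = (B + B.T) / 2.0  # symmetric for reversible Q; average off rounding
        w, U = np.linalg.eigh(B)
        return cls(Q, pi, w, U / sq[:, None], (U * sq[:, None]).T)

    def transition_matrix(self, t: float) -> np.ndarray:
        P = self.left @ (np.exp(self.eigvals * t)[:, None] * self.right)
        return np.maximum(P, 0.0)
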