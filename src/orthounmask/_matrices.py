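"""BLOSUM62-derived background frequencies and conditional probabilities.

The PSSM/HMM pseudocount machinery needs the residue-pair joint
distribution implied by BLOSUM62 rather than the integer half-bit scores.
The joint is reconstructed as ``q_ab ∝ p_a p_b 2^(s_ab/2)`` with ``p`` the
Robinson–Robinson background (the frequencies BLAST pairs with BLOSUM62),
then balanced by symmetric Sinkhorn scaling so its marginals equal the
background exactly.  That exactness matters: a column whose observed
frequencies equal the background then receives exactly zero log-odds after
pseudocount mixing.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AMINO_ACIDS

# Robinson & Robinson amino-acid frequencies (BLAST's protein background),
# reordered to this package's alphabetical residue order.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


@lru_cache(maxsize=1)
def blosum62_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (background p[20], joint q[20,20], conditional q(a|b)[a,b]).

    Guarantees: q is symmetric, q.sum() == 1, q.sum(axis=0) == p, and
    therefore (cond @ p) == p to numerical precision.
    """
    mat = substitution_matrices.load("BLOSUM62")
    n = len(AMINO_ACIDS)
    s = np.empty((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            s[i, j] = mat[a][b]
    p = np.array([_ROBINSON[a] for a in AMINO_ACIDS])
    p = p / p.sum()
    q = np.outer(p, p) * np.power(2.0, s / 2.0)  # scores are half-bit log-odds
    q /= q.sum()
    # symmetric Sinkhorn: scale q so both marginals equal p exactly
    d = np.ones(n)
    for _ in range(500):
        marg = (q * np.outer(d, d)).sum(axis=1)
        d_new = d * np.sqrt(p / marg)
        if np.max(np.abs(d_new - d)) < 1e-15:
            d = d_new
            break
        d = d_new
    q = q * np.outer(d, d)
    q /= q.sum()
    cond = q / q.sum(axis=0, keepdims=True)  # cond[a, b] = P(a | b)
    return p, q, cond


def background_frequencies() -> np.ndarray:
    return blosum62_tables()[0].copy()
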