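"""Structural validation of candidate chaperone domains.

A candidate that looks scm3-like in sequence space is checked against a
reference fold: least-squares backbone superposition (Kabsch),
region-restricted RMSD, inter-chain contact listing, and per-residue
confidence (pLDDT) filtering. The package's operational definition of a
"successful scm3-like structure" is an RMSD of the candidate domain to the
reference fold at or below a configurable cutoff (default 2.0 Å over CA)
together with mean pLDDT of the domain at or above 70; both numbers are
configuration defaults, not claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .seqio import StructureModel

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3x3, proper orthonormal
    translation: np.ndarray    # 3-vector, Å
    rmsd: float                # Å
    n_pairs: int
    pairing: list              # (index_A, index_B) pairs used


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray,
                     pairing: list | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of paired coordinate sets.

    Finds the proper rotation R and translation t minimizing
    ``|| (A - centroid_A) R - (B - centroid_B) ||`` by SVD; reflections are
    excluded by sign correction of the smallest singular vector. Needs at
    least 3 non-collinear pairs.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError("at least 3 paired atoms required")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise ValueError("coordinates are collinear; superposition is degenerate")
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    if pairing is None:
        pairing = [(i, i) for i in range(n)]
    return SuperpositionResult(R, t, rmsd, n, pairing)


def region_rmsd(model_a: StructureModel, model_b: StructureModel,
                residues_a: list | None = None, residues_b: list | None = None,
                atoms: tuple = ("CA",)) -> SuperpositionResult:
    """RMSD of a paired region after optimal superposition.

    ``residues_a``/``residues_b`` are matched lists of residue numbers (file
    numbering); by default, residues are paired by shared number. Only atoms
    named in ``atoms`` and present in both paired residues are used.
    """
    by_a, by_b = model_a.by_number(), model_b.by_number()
    if residues_a is None or residues_b is None:
        common = sorted(set(by_a) & set(by_b))
        residues_a = residues_b = common
    if len(residues_a) != len(residues_b):
        raise ValueError("paired residue lists differ in length")
    missing = [(ra, rb) for ra, rb in zip(residues_a, residues_b)
               if ra not in by_a or rb not in by_b]
    if missing:
        raise ValueError(f"unmatched residue numbers: {missing}")
    pa, pb, pairing = [], [], []
    for ra, rb in zip(residues_a, residues_b):
        for atom in atoms:
            if atom in by_a[ra].atoms and atom in by_b[rb].atoms:
                pa.append(by_a[ra].atoms[atom])
                pb.append(by_b[rb].atoms[atom])
                pairing.append((ra, rb))
    if len(pa) < 3:
        raise ValueError("fewer than 3 paired atoms in the selected region")
    res = kabsch_superpose(np.array(pa), np.array(pb))
    return SuperpositionResult(res.rotation, res.translation, res.rmsd,
                               res.n_pairs, pairing)


def residue_contacts(chain_a: StructureModel, chain_b: StructureModel,
                     cutoff: float = 4.5) -> list:
    """Residue pairs whose minimum backbone-atom distance is <= cutoff (Å).

    Side chains are not represented in :class:`StructureModel`, so this is
    a backbone-distance approximation of all-atom contact determination.
    Returns (residue_number_a, residue_number_b, min_distance) sorted.
    """
    if not len(chain_a) or not len(chain_b):
        raise ValueError("both chains must be non-empty")
    contacts = []
    coords_b = []
    index_b = []
    for rb in chain_b.residues:
        for atom in BACKBONE_ATOMS:
            if atom in rb.atoms:
                coords_b.append(rb.atoms[atom])
                index_b.append(rb.number)
    coords_b = np.array(coords_b)
    index_b = np.array(index_b)
    for ra in chain_a.residues:
        coords_a = np.array([ra.atoms[a] for a in BACKBONE_ATOMS if a in ra.atoms])
        d = cdist(coords_a, coords_b)
        for num_b in np.unique(index_b):
            dmin = float(d[:, index_b == num_b].min())
            if dmin <= cutoff:
                contacts.append((ra.number, int(num_b), dmin))
    contacts.sort(key=lambda c: (c[0], c[1]))
    return contacts


@dataclass
class ConfidenceSummary:
    mask: np.ndarray           # True where confidence >= threshold
    mean: float
    fraction_passing: float


def confidence_filter(model: StructureModel, min_confidence: float = 70.0
                      ) -> ConfidenceSummary:
    """Per-residue pLDDT mask and summary statistics."""
    conf = model.confidences()
    mask = conf >= min_confidence
    return ConfidenceSummary(mask, float(conf.mean()),
                             float(mask.mean()))
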