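"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration or a different
library route, deliberately sharing no code path with the implementation
it checks.
"""

from __future__ import annotations

import math
from itertools import permutations, product

import numpy as np
from Bio.Data import CodonTable

from orthounmask.seqio import AA_INDEX, GAP


# ---------------------------------------------------------------------------
# Profile HMM: exhaustive path-sum forward probability
# ---------------------------------------------------------------------------

def hmm_forward_bruteforce(hmm, residues: str) -> float:
    """Sum log2-odds over every legal local state path by enumeration.

    Paths start at any match state (entry 1/L), end at any match state
    (exit me[k]); flanking residues are free. Mirrors the model's
    conventions: inserts emit at background (odds 1), deletes emit nothing,
    trailing inserts cannot reach the exit.
    """
    L = hmm.n_match
    n = len(residues)
    bg = hmm.background

    def em_odds(k, t):
        ch = residues[t]
        if ch == "X":
            return 1.0
        idx = AA_INDEX[ch]
        return hmm.match_emissions[k, idx] / bg[idx]

    total = 0.0

    def walk(kind, k, t, weight):
        """State (kind, k) has just been consumed; t = next residue index."""
        nonlocal total
        if kind == "M":
            total += weight * hmm.me[k]
        if kind == "M":
            if k + 1 < L and t < n:
                walk("M", k + 1, t + 1, weight * hmm.mm[k] * em_odds(k + 1, t))
            if t < n and not (k == L - 1):
                walk("I", k, t + 1, weight * hmm.mi[k])
            if k + 1 < L:
                walk("D", k + 1, t, weight * hmm.md[k])
        elif kind == "I":
            if k + 1 < L and t < n:
                walk("M", k + 1, t + 1, weight * hmm.im[k] * em_odds(k + 1, t))
            if t < n:
                walk("I", k, t + 1, weight * hmm.ii[k])
        else:  # D
            if k + 1 < L and t < n:
                walk("M", k + 1, t + 1, weight * hmm.dm[k] * em_odds(k + 1, t))
            if k + 1 < L:
                walk("D", k + 1, t, weight * hmm.dd[k])

    for k0 in range(L):
        for t0 in range(n):
            walk("M", k0, t0 + 1, (1.0 / L) * em_odds(k0, t0))
    return math.log2(total) if total > 0 else -math.inf


# ---------------------------------------------------------------------------
# PSSM local alignment: exhaustive enumeration
# ---------------------------------------------------------------------------

def sw_bruteforce(scores_halfbits: np.ndarray, target: str, gap_open: float,
                  gap_extend: float) -> float:
    """Best local alignment score by recursive enumeration of all paths.

    Affine gaps opening only from a match; alignments must start and end
    with a match. Exponential — use only on tiny instances.
    """
    L, n = scores_halfbits.shape[0], len(target)

    def sub(i, j):
        ch = target[j]
        if ch == "X":
            return 0.0
        return scores_halfbits[i, AA_INDEX[ch]]

    best = -math.inf

    def extend(i, j, state, score):
        """(i, j) = last consumed profile/target indices."""
        nonlocal best
        if state == "M":
            best = max(best, score)
        # diagonal
        if i + 1 < L and j + 1 < n:
            extend(i + 1, j + 1, "M", score + sub(i + 1, j + 1))
        # gap in target (consume profile)
        if state in ("M", "X") and i + 1 < L:
            extend(i + 1, j, "X", score - gap_open)
        elif state == "X" and i + 1 < L:
            extend(i + 1, j, "X", score - gap_extend)
        # gap in profile (consume target)
        if state in ("M", "Y") and j + 1 < n:
            cost = gap_open if state == "M" else gap_extend
            extend(i, j + 1, "Y", score - cost)

    for i0 in range(L):
        for j0 in range(n):
            extend(i0, j0, "M", sub(i0, j0))
    return best


# ---------------------------------------------------------------------------
# NG86: independent counting implementation
# ---------------------------------------------------------------------------

_CODE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODE.stop_codons)


def _aa(codon):
    return _CODE.forward_table[codon]


def ng86_counts_bruteforce(seq_a: str, seq_b: str):
    """(S_sites, N_sites, Sd, Nd) by direct enumeration, written
    independently of the package implementation."""
    S = N = Sd = Nd = 0.0
    for s in range(0, len(seq_a), 3):
        c1, c2 = seq_a[s:s + 3], seq_b[s:s + 3]
        if "-" in c1 or "-" in c2:
            continue
        for codon in (c1, c2):
            syn_sites = 0.0
            for pos in range(3):
                muts = [codon[:pos] + nt + codon[pos + 1:]
                        for nt in "ACGT" if nt != codon[pos]]
                valid = [m for m in muts if m not in _STOPS]
                if valid:
                    syn = sum(1 for m in valid if _aa(m) == _aa(codon))
                    syn_sites += syn / len(valid)
            S += syn_sites / 2.0
            N += (3.0 - syn_sites) / 2.0
        positions = [k for k in range(3) if c1[k] != c2[k]]
        if not positions:
            continue
        path_s, path_n = [], []
        for order in permutations(positions):
            cur = c1
            s_cnt = n_cnt = 0
            blocked = False
            for k in order:
                nxt = cur[:k] + c2[k] + cur[k + 1:]
                if nxt in _STOPS:
                    blocked = True
                    break
                if _aa(nxt) == _aa(cur):
                    s_cnt += 1
                else:
                    n_cnt += 1
                cur = nxt
            if not blocked:
                path_s.append(s_cnt)
                path_n.append(n_cnt)
        if path_s:
            Sd += sum(path_s) / len(path_s)
            Nd += sum(path_n) / len(path_n)
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# Codon likelihood: brute-force sum over ancestral states
# ---------------------------------------------------------------------------

def codon_likelihood_bruteforce(tree, states, row_index, rates, scale):
    """Per-site likelihood by explicit summation over all internal-node
    codon assignments (tiny trees only)."""
    dtree = tree.dendropy_tree
    internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in dtree.leaf_node_iter()]
    P = {}
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None:
            P[nd] = rates.transition_matrix((nd.edge.length or 0.0) * scale)
    n_sites = states.shape[1]
    out = np.zeros(n_sites)
    for site in range(n_sites):
        total = 0.0
        for assignment in product(range(61), repeat=len(internals)):
            amap = {nd: a for nd, a in zip(internals, assignment)}
            prob = rates.pi[amap[dtree.seed_node]]
            for nd in dtree.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                parent_state = amap[nd.parent_node]
                child_state = (states[row_index[nd.taxon.label], site]
                               if nd.is_leaf() else amap[nd])
                prob *= P[nd][parent_state, child_state]
            total += prob
        out[site] = total
    return out


# ---------------------------------------------------------------------------
# Pairwise identity, contacts, trimming
# ---------------------------------------------------------------------------

def identity_bruteforce(rows, columns=None):
    vals = []
    ncol = len(rows[0])
    cols = range(ncol) if columns is None else columns
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            num = den = 0
            for j in cols:
                x, y = rows[a][j], rows[b][j]
                if x == GAP and y == GAP:
                    continue
                den += 1
                if x == y and x not in (GAP, "X"):
                    num += 1
            if den:
                vals.append(100.0 * num / den)
    return float(np.mean(vals))


def contacts_bruteforce(chain_a, chain_b, cutoff):
    out = set()
    for ra in chain_a.residues:
        for rb in chain_b.residues:
            dmin = min(
                float(np.linalg.norm(xa - xb))
                for xa in ra.atoms.values() for xb in rb.atoms.values())
            if dmin <= cutoff:
                out.add((ra.number, rb.number))
    return out
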