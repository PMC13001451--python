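"""Phylogenetics and molecular-evolution analyses for unmasked ortholog sets.

Covers the comparative questions asked of a newly unmasked ortholog family:
is the domain tree congruent with the species tree (neighbor joining +
Robinson–Foulds distance), how fast is the gene evolving (pairwise NG86 and
whole-gene M0 maximum likelihood dN/dS), and is any site under diversifying
selection (two-class vs three-class site-model likelihood-ratio test with
naive empirical-Bayes per-site posteriors — NEB, not BEB, and labelled as
such in the output).

Tree inference here is deliberately lightweight: distance-based NJ is the
built-in, and externally inferred Newick trees are accepted wherever a
topology is needed.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._codon import (CODON_AA, CODON_INDEX, SENSE_CODONS, STOP_CODONS,
                     CodonRates, codon_diff, f3x4_frequencies, gy94_rate_matrix,
                     is_synonymous, substitution_proportions)
from .seqio import GAP, Alignment

logger = logging.getLogger(__name__)


# ===========================================================================
# Trees
# ===========================================================================

class Tree:
    """Thin wrapper over a dendropy tree: unique leaf names, branch lengths
    in expected substitutions per site, Newick round-trip."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        names = self.leaf_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(dtree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip()

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def terminal_branch_lengths(self) -> dict:
        return {lf.taxon.label: (lf.edge.length or 0.0)
                for lf in self._tree.leaf_node_iter()}

    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self._tree.preorder_edge_iter())

    def bipartitions(self) -> set:
        """Non-trivial bipartitions as frozensets of the smaller leaf side."""
        all_leaves = frozenset(self.leaf_names)
        splits = set()
        for node in self._tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(side) < len(all_leaves) - 1:
                other = all_leaves - side
                splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits

    def prune_to(self, keep: list) -> "Tree":
        dtree = self._tree.clone(depth=1)
        dtree.retain_taxa_with_labels(keep)
        return Tree(dtree)


def _pairwise_distance(a: str, b: str, correction: str) -> float:
    diff = countable = 0
    for ca, cb in zip(a, b):
        if ca == GAP or cb == GAP:
            continue
        countable += 1
        if ca != cb:
            diff += 1
    p = diff / countable if countable else 0.0
    if correction == "poisson":
        if p >= 1.0:
            logger.info("saturated Poisson correction; falling back to p-distance")
            return p
        return -math.log(1.0 - p)
    return p


def nj_tree(alignment: Alignment, distance: str = "p") -> Tree:
    """Neighbor-joining tree from p- or Poisson-corrected distances.

    Negative branch-length estimates are clamped to zero (logged). NJ is
    exact on additive distances, so 4-taxon additive inputs are recovered
    with their branch lengths.
    """
    if distance not in ("p", "poisson"):
        raise ValueError("distance must be 'p' or 'poisson'")
    if alignment.n_rows < 4:
        raise ValueError("NJ needs at least 4 rows")
    ids = alignment.ids
    n = len(ids)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        D[i, j] = D[j, i] = _pairwise_distance(
            alignment.rows[i][1], alignment.rows[j][1], distance)
    buf = io.StringIO()
    buf.write("," + ",".join(ids) + "\n")
    for i in range(n):
        buf.write(ids[i] + "," + ",".join(f"{D[i, j]:.10f}" for j in range(n)) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    dtree = pdm.nj_tree()
    clamped = 0
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            clamped += 1
    if clamped:
        logger.info("clamped %d negative NJ branch estimates to 0", clamped)
    return Tree(dtree)


def rf_distance(tree1: Tree, tree2: Tree) -> int:
    """Robinson–Foulds distance: bipartitions present in exactly one tree."""
    s1, s2 = set(tree1.leaf_names), set(tree2.leaf_names)
    if s1 != s2:
        raise ValueError(f"leaf sets differ: {sorted(s1 ^ s2)}")
    b1, b2 = tree1.bipartitions(), tree2.bipartitions()
    return len(b1 ^ b2)


# ===========================================================================
# Codon alignments
# ===========================================================================

class CodonAlignment:
    """In-frame codon-aligned nucleotide rows (standard genetic code).

    Row lengths must be divisible by 3, gaps must come in whole-codon
    units, and internal stop codons are rejected with their position.
    """

    def __init__(self, rows: list):
        if len(rows) < 2:
            raise ValueError("codon alignment needs at least 2 rows")
        lengths = {len(seq) for _, seq in rows}
        if len(lengths) != 1:
            raise ValueError("ragged codon alignment")
        length = lengths.pop()
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} not divisible by 3")
        for rid, seq in rows:
            seq = seq.upper()
            for start in range(0, length, 3):
                codon = seq[start:start + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(
                        f"partial-codon gap at codon {start // 3 + 1} in {rid!r}")
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"internal stop codon {codon} at codon "
                        f"{start // 3 + 1} in {rid!r}")
        self.rows = [(rid, seq.upper()) for rid, seq in rows]

    @property
    def ids(self) -> list:
        return [rid for rid, _ in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_codons(self) -> int:
        return len(self.rows[0][1]) // 3

    def codon(self, rid_index: int, j: int) -> str:
        return self.rows[rid_index][1][3 * j:3 * j + 3]

    def codon_columns(self) -> np.ndarray:
        """(n_rows, n_codons) array of sense-codon indices; -1 = gap/other."""
        out = np.full((self.n_rows, self.n_codons), -1, dtype=np.int64)
        for i in range(self.n_rows):
            for j in range(self.n_codons):
                out[i, j] = CODON_INDEX.get(self.codon(i, j), -1)
        return out

    def subset(self, keep_ids: list) -> "CodonAlignment":
        keep = set(keep_ids)
        return CodonAlignment([(rid, seq) for rid, seq in self.rows
                               if rid in keep])


# ===========================================================================
# NG86 pairwise dN/dS
# ===========================================================================

@dataclass
class OmegaEstimate:
    method: str                  # "NG86" | "M0"
    omega: float | None          # None when dS == 0 (undefined)
    dN: float
    dS: float
    N_sites: float
    S_sites: float
    kappa: float | None = None
    logL: float | None = None
    converged: bool = True
    corrected: bool = True       # Jukes-Cantor correction applied (NG86)
    label: str = ""

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


def _codon_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one codon.

    Per position, the synonymous fraction is computed over the non-stop
    single-nucleotide changes, so S + N = 3 exactly per codon (stop-bound
    changes redistribute their weight within the position).
    """
    s_total = 0.0
    for k in range(3):
        syn = non_stop = 0
        for nt in "ACGT":
            if nt == codon[k]:
                continue
            mut = codon[:k] + nt + codon[k + 1:]
            if mut in STOP_CODONS:
                continue
            non_stop += 1
            if CODON_AA[mut] == CODON_AA[codon]:
                syn += 1
        if non_stop:
            s_total += syn / non_stop
    return s_total, 3.0 - s_total


def _pair_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """Average synonymous/nonsynonymous difference counts over all mutational
    orderings between two codons that avoid stop intermediates."""
    diff = codon_diff(c1, c2)
    if not diff:
        return 0.0, 0.0
    syn_counts, nonsyn_counts = [], []
    for order in permutations(diff):
        cur = c1
        s = n = 0
        ok = True
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_AA[cur] == CODON_AA[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            syn_counts.append(s)
            nonsyn_counts.append(n)
    if not syn_counts:
        return None
    return float(np.mean(syn_counts)), float(np.mean(nonsyn_counts))


def _jc_correct(p: float) -> float | None:
    if p < 3.0 / 4.0:
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return None


def ng86_dnds(seq_a: str, seq_b: str, label: str = "") -> OmegaEstimate:
    """Nei–Gojobori (1986) pairwise dN/dS with Jukes–Cantor correction.

    Gapped codon columns are skipped (pairwise deletion); multi-hit codons
    are resolved by equal-weight averaging over all mutational orderings
    through non-stop intermediates. When the correction domain fails
    (p >= 3/4), uncorrected proportions are returned with
    ``corrected=False``.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("length not divisible by 3")
    S = N = Sd = Nd = 0.0
    for start in range(0, len(seq_a), 3):
        c1, c2 = seq_a[start:start + 3], seq_b[start:start + 3]
        if "-" in c1 or "-" in c2:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError(f"stop codon at codon {start // 3 + 1}")
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        d = _pair_differences(c1, c2)
        if d is None:
            logger.info("codon pair %s/%s has no stop-free path; skipped", c1, c2)
            continue
        Sd += d[0]
        Nd += d[1]
    if S == 0 or N == 0:
        raise ValueError("no countable codon sites")
    pS, pN = Sd / S, Nd / N
    dS, dN = _jc_correct(pS), _jc_correct(pN)
    corrected = dS is not None and dN is not None
    if not corrected:
        # keep both on the same (uncorrected) scale for a comparable ratio
        logger.info("Jukes-Cantor correction domain failure; returning proportions")
        dS, dN = pS, pN
    omega = dN / dS if dS > 0 else None
    return OmegaEstimate("NG86", omega, dN, dS, N, S, corrected=corrected,
                         label=label)


# ===========================================================================
# Likelihood machinery (shared by M0 and the sites test)
# ===========================================================================

def _tree_edges(tree: Tree):
    """Postorder (node, parent, length) list and leaf-name mapping."""
    dtree = tree.dendropy_tree
    edges = []
    for node in dtree.postorder_node_iter():
        if node.parent_node is not None:
            edges.append((node, node.parent_node, node.edge.length or 0.0))
    return edges


def _site_likelihoods(tree: Tree, states: np.ndarray, row_index: dict,
                      rates: CodonRates, branch_scale: float) -> np.ndarray:
    """Felsenstein pruning: per-site likelihoods over a fixed topology.

    ``states`` is (n_rows, n_sites) of sense-codon indices (-1 = missing,
    treated as fully ambiguous). Vectorized over sites: each node carries a
    (61, n_sites) conditional-likelihood array.
    """
    n_states, n_sites = 61, states.shape[1]
    partial = {}
    dtree = tree.dendropy_tree
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            row = row_index[node.taxon.label]
            arr = np.zeros((n_states, n_sites))
            idx = states[row]
            ambiguous = idx < 0
            arr[:, ambiguous] = 1.0
            ok = ~ambiguous
            arr[idx[ok], np.nonzero(ok)[0]] = 1.0
            node._cl = arr
        else:
            arr = np.ones((n_states, n_sites))
            for child in node.child_nodes():
                P = rates.transition_matrix((child.edge.length or 0.0)
                                            * branch_scale)
                arr *= P @ child._cl
            node._cl = arr
    root = dtree.seed_node
    site_l = rates.pi @ root._cl
    return np.maximum(site_l, 1e-300)


def _prepare_ml_inputs(codon_alignment: CodonAlignment, tree: Tree):
    leaf_names = set(tree.leaf_names)
    if set(codon_alignment.ids) != leaf_names:
        raise ValueError("tree leaves and alignment rows differ")
    states = codon_alignment.codon_columns()
    # column-wise complete deletion: drop sites with any gap/non-sense codon
    keep = ~np.any(states < 0, axis=0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("complete deletion removed %d codon columns", dropped)
    states = states[:, keep]
    if states.shape[1] == 0:
        raise ValueError("no complete codon columns")
    row_index = {rid: i for i, rid in enumerate(codon_alignment.ids)}
    pi = f3x4_frequencies([seq for _, seq in codon_alignment.rows])
    return states, row_index, pi


OMEGA_BOUNDS = (1e-4, 20.0)
KAPPA_BOUNDS = (0.1, 50.0)
SCALE_BOUNDS = (1e-3, 100.0)


def m0_fit(codon_alignment: CodonAlignment, tree: Tree,
           optimize_scale: bool = True) -> OmegaEstimate:
    """Whole-gene dN/dS by maximum likelihood under the one-ratio (M0)
    Goldman–Yang codon model with F3x4 frequencies.

    Optimizes omega, kappa and a global branch-length scale by bounded
    quasi-Newton; non-convergence is flagged on the result, never silent.
    dN and dS are derived from the fitted rate matrix so that dN/dS equals
    omega exactly; site counts are mutational-opportunity proportions from
    the omega=1 matrix (times 3 per codon).
    """
    states, row_index, pi = _prepare_ml_inputs(codon_alignment, tree)

    def nll(x):
        lo, lk, ls = x
        rates = CodonRates.from_parameters(math.exp(lk), math.exp(lo), pi)
        scale = math.exp(ls) if optimize_scale else 1.0
        sl = _site_likelihoods(tree, states, row_index, rates, scale)
        return -float(np.log(sl).sum())

    x0 = np.log([0.3, 2.0, 1.0])
    bounds = [tuple(np.log(OMEGA_BOUNDS)), tuple(np.log(KAPPA_BOUNDS)),
              tuple(np.log(SCALE_BOUNDS))]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    if not res.success:
        res2 = optimize.minimize(nll, np.log([1.0, 5.0, 0.5]),
                                 method="L-BFGS-B", bounds=bounds)
        if res2.fun < res.fun:
            res = res2
    omega, kappa, scale = np.exp(res.x)
    # model-based dN/dS bookkeeping
    rho_s1, rho_n1 = substitution_proportions(kappa, 1.0, pi)
    rho_s, rho_n = substitution_proportions(kappa, omega, pi)
    T = tree.total_length() * (scale if optimize_scale else 1.0)
    S_sites, N_sites = 3.0 * rho_s1, 3.0 * rho_n1
    dS = T * rho_s / rho_s1
    dN = T * rho_n / rho_n1
    n_cod = states.shape[1]
    return OmegaEstimate("M0", float(omega) if dS > 0 else None,
                         float(dN), float(dS),
                         N_sites * n_cod, S_sites * n_cod,
                         kappa=float(kappa), logL=-float(res.fun),
                         converged=bool(res.success), label="M0")


# ---------------------------------------------------------------------------
# Site-class selection test (two classes vs three classes)
# ---------------------------------------------------------------------------

@dataclass
class SitesTestResult:
    lnL_null: float
    lnL_alt: float
    LRT_stat: float
    df: int
    p_value: float
    per_site_posterior: np.ndarray   # P(site in the omega>1 class), NEB
    flagged_sites: list              # 0-based indices with posterior > 0.9
    null_params: dict = field(default_factory=dict)
    alt_params: dict = field(default_factory=dict)
    posterior_method: str = "NEB"    # naive empirical Bayes at the MLEs
    converged: bool = True


def _mixture_nll(tree, states, row_index, pi, omegas, props, kappa, scale):
    per_class = []
    for w in omegas:
        rates = CodonRates.from_parameters(kappa, w, pi)
        per_class.append(_site_likelihoods(tree, states, row_index, rates, scale))
    L = np.stack(per_class)                      # (k, n_sites)
    mix = np.maximum(props @ L, 1e-300)
    return -float(np.log(mix).sum()), L


def sites_test(codon_alignment: CodonAlignment, tree: Tree,
               flag_threshold: float = 0.9) -> SitesTestResult:
    """Positive-selection likelihood-ratio test with per-site posteriors.

    Null: two site classes, omega0 in [0, 1] (estimated) and omega = 1.
    Alternative: adds a third class with omega > 1. 2*delta-lnL is compared
    to chi-square with 2 df (conservative at the boundary). Per-site
    posteriors for the positive class use naive empirical Bayes at the
    MLEs; sites above ``flag_threshold`` are flagged.
    """
    states, row_index, pi = _prepare_ml_inputs(codon_alignment, tree)

    def null_nll(x):
        lw0, a0, lk, ls = x
        p0 = 1.0 / (1.0 + math.exp(-a0))
        nll, _ = _mixture_nll(tree, states, row_index, pi,
                              [math.exp(lw0), 1.0],
                              np.array([p0, 1.0 - p0]),
                              math.exp(lk), math.exp(ls))
        return nll

    def alt_nll(x):
        lw0, lw2, a0, a1, lk, ls = x
        e0, e1 = math.exp(a0), math.exp(a1)
        z = 1.0 + e0 + e1
        props = np.array([e0 / z, e1 / z, 1.0 / z])
        nll, _ = _mixture_nll(tree, states, row_index, pi,
                              [math.exp(lw0), 1.0, 1.0 + math.exp(lw2)],
                              props, math.exp(lk), math.exp(ls))
        return nll

    nb = [(math.log(1e-4), 0.0), (-6, 6), tuple(np.log(KAPPA_BOUNDS)),
          tuple(np.log(SCALE_BOUNDS))]
    rn = optimize.minimize(null_nll, [math.log(0.2), 0.0, math.log(2.0), 0.0],
                           method="L-BFGS-B", bounds=nb)
    ab = [(math.log(1e-4), 0.0), (math.log(1e-3), math.log(19.0)),
          (-6, 6), (-6, 6), tuple(np.log(KAPPA_BOUNDS)),
          tuple(np.log(SCALE_BOUNDS))]
    starts = [
        [rn.x[0], math.log(1.0), rn.x[1], -1.0, rn.x[2], rn.x[3]],
        [rn.x[0], math.log(3.0), rn.x[1], -2.5, rn.x[2], rn.x[3]],
    ]
    ra = None
    for s0 in starts:
        cand = optimize.minimize(alt_nll, s0, method="L-BFGS-B", bounds=ab)
        if ra is None or cand.fun < ra.fun:
            ra = cand
    converged = bool(rn.success and ra.success)
    lnl0, lnl1 = -rn.fun, -ra.fun
    if lnl1 < lnl0 - 1e-4:
        # alternative must nest the null; restart from the null optimum
        cand = optimize.minimize(
            alt_nll, [rn.x[0], math.log(1e-3), rn.x[1], -6.0, rn.x[2], rn.x[3]],
            method="L-BFGS-B", bounds=ab)
        if cand.fun < ra.fun:
            ra = cand
            lnl1 = -ra.fun
        converged = converged and lnl1 >= lnl0 - 1e-4
    lrt = max(2.0 * (lnl1 - lnl0), 0.0)
    p = float(stats.chi2.sf(lrt, df=2))
    # NEB posteriors at the alternative MLEs
    lw0, lw2, a0, a1, lk, ls = ra.x
    e0, e1 = math.exp(a0), math.exp(a1)
    z = 1.0 + e0 + e1
    props = np.array([e0 / z, e1 / z, 1.0 / z])
    omegas = [math.exp(lw0), 1.0, 1.0 + math.exp(lw2)]
    _, L = _mixture_nll(tree, states, row_index, pi, omegas, props,
                        math.exp(lk), math.exp(ls))
    weighted = props[:, None] * L
    post = weighted[2] / np.maximum(weighted.sum(axis=0), 1e-300)
    flagged = [int(i) for i in np.nonzero(post > flag_threshold)[0]]
    return SitesTestResult(
        lnL_null=lnl0, lnL_alt=lnl1, LRT_stat=lrt, df=2, p_value=p,
        per_site_posterior=post, flagged_sites=flagged,
        null_params={"omega0": math.exp(rn.x[0]),
                     "p0": 1.0 / (1.0 + math.exp(-rn.x[1])),
                     "kappa": math.exp(rn.x[2])},
        alt_params={"omega0": omegas[0], "omega2": omegas[2],
                    "props": props.tolist(), "kappa": math.exp(lk)},
        converged=converged)


# ===========================================================================
# Dataset filtering and omega contrasts
# ===========================================================================

@dataclass
class FilterReport:
    accepted: bool
    reason: str
    dropped_long_branch: list
    dropped_large_insertion: list
    kept_ids: list


def filter_for_selection_analysis(codon_alignment: CodonAlignment, tree: Tree,
                                  min_taxa: int = 8, branch_factor: float = 3.0,
                                  insertion_factor: float = 1.5
                                  ) -> tuple[CodonAlignment | None, Tree | None,
                                             FilterReport]:
    """Quality gate before selection analyses.

    Rejects datasets with fewer than ``min_taxa`` rows, drops leaves whose
    terminal branch exceeds ``branch_factor`` times the median terminal
    branch, and drops rows whose ungapped length exceeds
    ``insertion_factor`` times the median (large-insertion proxy). If
    filtering leaves fewer than ``min_taxa`` rows the dataset is rejected;
    every exclusion is itemized in the report.
    """
    ids = codon_alignment.ids
    if len(ids) < min_taxa:
        report = FilterReport(False, f"only {len(ids)} sequences "
                              f"(minimum {min_taxa})", [], [], [])
        return None, None, report
    term = tree.terminal_branch_lengths()
    med_branch = float(np.median([term[i] for i in ids]))
    long_branch = [i for i in ids
                   if med_branch > 0 and term[i] > branch_factor * med_branch]
    lengths = {rid: len(seq.replace(GAP, "")) for rid, seq in codon_alignment.rows}
    med_len = float(np.median(list(lengths.values())))
    large_ins = [i for i in ids if lengths[i] > insertion_factor * med_len]
    drop = set(long_branch) | set(large_ins)
    kept = [i for i in ids if i not in drop]
    if len(kept) < min_taxa:
        report = FilterReport(False,
                              f"{len(kept)} sequences remain after exclusions "
                              f"(minimum {min_taxa})",
                              long_branch, large_ins, kept)
        return None, None, report
    report = FilterReport(True, "", long_branch, large_ins, kept)
    if not drop:
        return codon_alignment, tree, report
    return (codon_alignment.subset(kept), tree.prune_to(kept), report)


def omega_contrast(gene_sets: dict) -> pd.DataFrame:
    """Summarize dN/dS across named gene sets and their pairwise ratios.

    ``gene_sets`` maps a set name to a list of :class:`OmegaEstimate`.
    Undefined omegas (dS = 0) are excluded from means but counted. No
    significance statistic is attached — the output is descriptive.
    """
    rows = []
    means = {}
    for name, estimates in gene_sets.items():
        if not estimates:
            raise ValueError(f"gene set {name!r} is empty")
        defined = [e.omega for e in estimates if e.omega_defined]
        if not defined:
            raise ValueError(f"gene set {name!r} has no defined omega values")
        means[name] = float(np.mean(defined))
        rows.append({"set": name, "n": len(estimates),
                     "n_defined": len(defined),
                     "mean_omega": means[name],
                     "median_omega": float(np.median(defined))})
    table = pd.DataFrame(rows).set_index("set")
    for a in means:
        for b in means:
            if a != b:
                table.loc[a, f"ratio_vs_{b}"] = means[a] / means[b]
    return table
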