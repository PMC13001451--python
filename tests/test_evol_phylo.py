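import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from orthounmask._codon import (SENSE_CODONS, CodonRates, f3x4_frequencies,
                                gy94_rate_matrix)
from orthounmask.evol_phylo import (CodonAlignment, Tree,
                                    _prepare_ml_inputs, _site_likelihoods,
                                    filter_for_selection_analysis, m0_fit,
                                    ng86_dnds, nj_tree, omega_contrast,
                                    rf_distance, sites_test)
from orthounmask.seqio import Alignment
from orthounmask.synthetic_data import SimulationConfig, simulate_codon_family

from .oracles import codon_likelihood_bruteforce, ng86_counts_bruteforce


def random_tree(rng, n_taxa, mean_branch=0.3):
    """Deterministic random topology by sequential joining."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{t}:{rng.uniform(0.05, mean_branch):.4f}" for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = (f"({nodes[i]},{nodes[j]}):"
                  f"{rng.uniform(0.05, mean_branch):.4f}")
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return Tree.from_newick("(" + ",".join(nodes) + ");")


class TestNJTree:
    def test_recovers_additive_four_taxon_tree(self):
        # distances from ((a:1,b:2):2,(c:2,d:4):2) are additive
        aln_rows = None
        import io
        buf = io.StringIO(",a,b,c,d\na,0,3,7,9\nb,3,0,8,10\nc,7,8,0,6\nd,9,10,6,0\n")
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
        dtree = pdm.nj_tree()
        t = Tree(dtree)
        assert t.bipartitions() == {frozenset({"a", "b"})}

    def test_identical_sequences_zero_cherry(self):
        aln = Alignment([("a", "KYEIDVKYEI"), ("b", "KYEIDVKYEI"),
                         ("c", "LWCHGFLWCH"), ("d", "LWMHGFLWMH")])
        tree = nj_tree(aln, distance="p")
        term = tree.terminal_branch_lengths()
        assert term["a"] == pytest.approx(0.0, abs=1e-12)
        assert term["b"] == pytest.approx(0.0, abs=1e-12)

    def test_topology_matches_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        from orthounmask.seqio import AMINO_ACIDS
        rows = []
        base = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, 60))
        for name, n_mut in (("a", 3), ("b", 5), ("c", 20), ("d", 22)):
            seq = list(base)
            for pos in rng.choice(60, n_mut, replace=False):
                seq[pos] = AMINO_ACIDS[int(rng.integers(0, 20))]
            rows.append((name, "".join(seq)))
        aln = Alignment(rows)
        tree = nj_tree(aln, distance="p")
        # oracle: least-squares fit of all 3 unrooted 4-taxon topologies
        def pdist(x, y):
            return sum(a != b for a, b in zip(x, y)) / len(x)
        d = {(i, j): pdist(rows[i][1], rows[j][1])
             for i, j in itertools.combinations(range(4), 2)}
        names = [r[0] for r in rows]
        best, best_err = None, np.inf
        for split in ((0, 1), (0, 2), (0, 3)):
            pair = set(split)
            other = [k for k in range(4) if k not in pair]
            # path matrix for 5 branch lengths (4 terminal + 1 internal)
            A, y = [], []
            for (i, j), dist in d.items():
                row = [0.0] * 5
                row[i] = row[j] = 1.0
                same_side = ({i, j} == pair) or ({i, j} == set(other))
                if not same_side:
                    row[4] = 1.0
                A.append(row)
                y.append(dist)
            sol, res, *_ = np.linalg.lstsq(np.array(A), np.array(y),
                                           rcond=None)
            err = float(np.sum((np.array(A) @ sol - np.array(y)) ** 2))
            if err < best_err:
                best, best_err = pair, err
        expected_split = frozenset(names[k] for k in best)
        got = tree.bipartitions()
        assert got == {expected_split} or got == {
            frozenset(names) - expected_split}

    def test_too_few_rows(self):
        aln = Alignment([("a", "KY"), ("b", "KY"), ("c", "LW")])
        with pytest.raises(ValueError):
            nj_tree(aln)


class TestRFDistance:
    def test_identical_topologies_zero(self):
        t1 = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = Tree.from_newick("((a:2,b:2):2,(c:2,d:2):2);")
        assert rf_distance(t1, t2) == 0

    def test_four_taxon_swap_is_two(self):
        t1 = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = Tree.from_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_leaf_mismatch_reported(self):
        t1 = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = Tree.from_newick("((a:1,b:1):1,(c:1,e:1):1);")
        with pytest.raises(ValueError, match="d.*e|e.*d"):
            rf_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dendropy_bipartition_route(self, seed):
        rng = np.random.default_rng(seed)
        t1 = random_tree(rng, 8)
        t2 = random_tree(rng, 8)
        got = rf_distance(t1, t2)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = treecompare.symmetric_difference(d1, d2)
        assert got == expected

    def test_metric_properties_spot_check(self):
        rng = np.random.default_rng(99)
        trees = [random_tree(rng, 6) for _ in range(3)]
        for a, b in itertools.permutations(range(3), 2):
            assert rf_distance(trees[a], trees[b]) == \
                rf_distance(trees[b], trees[a])
        d01 = rf_distance(trees[0], trees[1])
        d12 = rf_distance(trees[1], trees[2])
        d02 = rf_distance(trees[0], trees[2])
        assert d02 <= d01 + d12


class TestNG86:
    def test_identical_sequences_undefined_omega(self):
        est = ng86_dnds("ATGAAA", "ATGAAA")
        assert est.dN == 0 and est.dS == 0 and est.omega is None

    def test_toy_pair_two_syn_one_nonsyn(self):
        """Hand-constructed 10-codon pair: GAA->GAG and CTG->CTA are
        synonymous, AAA->AGA is nonsynonymous, all at fourfold/simple
        sites."""
        a = "ATGGAACTGAAAGGCTTTCCAACGTGGCAT"
        b = "ATGGAGCTAAGAGGCTTTCCAACGTGGCAT"
        est = ng86_dnds(a, b)
        Sx, Nx, Sdx, Ndx = ng86_counts_bruteforce(a, b)
        assert (Sdx, Ndx) == (2.0, 1.0)
        assert est.S_sites == pytest.approx(Sx, abs=1e-9)
        assert est.N_sites == pytest.approx(Nx, abs=1e-9)
        pS = 0.75 * (1 - np.exp(-4.0 * est.dS / 3.0))
        pN = 0.75 * (1 - np.exp(-4.0 * est.dN / 3.0))
        assert pS * Sx == pytest.approx(Sdx, abs=1e-9)
        assert pN * Nx == pytest.approx(Ndx, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_path_enumeration_oracle(self, seed):
        """Moderately diverged pairs (so the distance correction applies)
        agree with an independent enumeration of sites and multi-hit
        pathways."""
        rng = np.random.default_rng(seed)
        a_codons = list(rng.choice(SENSE_CODONS, 12))
        b_codons = list(a_codons)
        for pos in rng.choice(12, 4, replace=False):
            b_codons[pos] = str(rng.choice(SENSE_CODONS))
        a, b = "".join(a_codons), "".join(b_codons)
        Sx, Nx, Sdx, Ndx = ng86_counts_bruteforce(a, b)
        est = ng86_dnds(a, b)
        assert est.S_sites == pytest.approx(Sx, abs=1e-9)
        assert est.N_sites == pytest.approx(Nx, abs=1e-9)
        if est.corrected:
            pS = 0.75 * (1 - np.exp(-4.0 * est.dS / 3.0))
            pN = 0.75 * (1 - np.exp(-4.0 * est.dN / 3.0))
        else:
            pS, pN = est.dS, est.dN
        assert pS * Sx == pytest.approx(Sdx, abs=1e-9)
        assert pN * Nx == pytest.approx(Ndx, abs=1e-9)

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(SENSE_CODONS, 12))
        b = "".join(rng.choice(SENSE_CODONS, 12))
        e1, e2 = ng86_dnds(a, b), ng86_dnds(b, a)
        assert e1.dN == pytest.approx(e2.dN)
        assert e1.dS == pytest.approx(e2.dS)

    def test_site_counts_sum_to_three_per_codon(self):
        from orthounmask.evol_phylo import _codon_sites
        for codon in SENSE_CODONS:
            s, n = _codon_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng86_dnds("ATGAAA", "ATG")


class TestCodonLikelihood:
    @pytest.mark.parametrize("seed", range(3))
    def test_pruning_equals_bruteforce_ancestral_sum(self, seed):
        tree = Tree.from_newick("((a:0.2,b:0.3):0.15,(c:0.25,d:0.1):0.05);")
        cfg = SimulationConfig(tree=tree, seed=seed, model="codon", n_sites=5,
                               omega_classes=((1.0, 0.4),))
        caln, _ = simulate_codon_family(cfg)
        states, row_index, pi = _prepare_ml_inputs(caln, tree)
        rates = CodonRates.from_parameters(2.0, 0.4, pi)
        fast = _site_likelihoods(tree, states, row_index, rates, 1.0)
        slow = codon_likelihood_bruteforce(tree, states, row_index, rates, 1.0)
        np.testing.assert_allclose(fast, slow, rtol=1e-8)


class TestM0Fit:
    def test_logl_at_mle_beats_probes(self):
        tree = Tree.from_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1,"
                                "(e:0.2,f:0.2):0.1);")
        cfg = SimulationConfig(tree=tree, seed=7, model="codon", n_sites=150,
                               omega_classes=((1.0, 0.5),))
        caln, _ = simulate_codon_family(cfg)
        est = m0_fit(caln, tree)
        states, row_index, pi = _prepare_ml_inputs(caln, tree)
        for omega, kappa in ((0.1, 2.0), (2.0, 2.0), (0.5, 10.0)):
            rates = CodonRates.from_parameters(kappa, omega, pi)
            probe = float(np.log(_site_likelihoods(
                tree, states, row_index, rates, 1.0)).sum())
            assert est.logL >= probe - 1e-6

    def test_omega_recovery_and_bookkeeping(self):
        tree = Tree.from_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1,"
                                "(e:0.2,f:0.2):0.1);")
        cfg = SimulationConfig(tree=tree, seed=7, model="codon", n_sites=300,
                               omega_classes=((1.0, 0.5),))
        caln, _ = simulate_codon_family(cfg)
        est = m0_fit(caln, tree)
        assert est.converged
        assert est.omega == pytest.approx(0.5, abs=0.15)
        # dN/dS equals omega by construction, sites sum to 3 per codon
        assert est.dN / est.dS == pytest.approx(est.omega, rel=1e-6)
        n_cod = caln.n_codons
        assert est.N_sites + est.S_sites == pytest.approx(3 * n_cod, rel=1e-9)


class TestSitesTest:
    def test_flagged_sites_match_posterior_threshold(self):
        tree = Tree.from_newick("((a:0.4,b:0.4):0.2,(c:0.4,d:0.4):0.2,"
                                "(e:0.4,f:0.4):0.2);")
        cfg = SimulationConfig(tree=tree, seed=1, model="codon", n_sites=80,
                               omega_classes=((0.7, 0.2), (0.3, 3.0)))
        caln, _ = simulate_codon_family(cfg)
        res = sites_test(caln, tree)
        assert res.flagged_sites == [
            int(i) for i in np.nonzero(res.per_site_posterior > 0.9)[0]]
        assert res.LRT_stat >= 0
        assert np.all((res.per_site_posterior >= 0)
                      & (res.per_site_posterior <= 1))


class TestSelectionFilter:
    def _tree(self, n, long_leaf=None):
        parts = []
        for i in range(n):
            bl = 2.0 if f"t{i}" == long_leaf else 0.2
            parts.append(f"t{i}:{bl}")
        return Tree.from_newick("(" + ",".join(parts) + ");")

    def _aln(self, n, long_row=None):
        rows = []
        for i in range(n):
            seq = "ATGAAACCCGGG" * 5
            if f"t{i}" == long_row:
                seq = seq + "GCT" * 40
            rows.append((f"t{i}", seq))
        width = max(len(s) for _, s in rows)
        rows = [(rid, s + "-" * (width - len(s))) for rid, s in rows]
        return CodonAlignment(rows)

    def test_small_dataset_rejected(self):
        caln, tree = self._aln(7), self._tree(7)
        out_aln, out_tree, report = filter_for_selection_analysis(caln, tree)
        assert out_aln is None and not report.accepted
        assert "7" in report.reason

    def test_long_branch_dropped(self):
        caln, tree = self._aln(10), self._tree(10, long_leaf="t3")
        out_aln, out_tree, report = filter_for_selection_analysis(caln, tree)
        assert report.accepted and report.dropped_long_branch == ["t3"]
        assert "t3" not in out_aln.ids and "t3" not in out_tree.leaf_names

    def test_large_insertion_dropped(self):
        caln, tree = self._aln(10, long_row="t5"), self._tree(10)
        out_aln, out_tree, report = filter_for_selection_analysis(caln, tree)
        assert report.dropped_large_insertion == ["t5"]
        assert "t5" not in out_aln.ids

    def test_clean_eight_taxon_dataset_unchanged(self):
        caln, tree = self._aln(8), self._tree(8)
        out_aln, out_tree, report = filter_for_selection_analysis(caln, tree)
        assert report.accepted and out_aln is caln and out_tree is tree


class TestOmegaContrast:
    def _est(self, omega):
        from orthounmask.evol_phylo import OmegaEstimate
        return OmegaEstimate("M0", omega, omega * 0.1, 0.1, 100, 50)

    def test_ratio_of_means(self):
        table = omega_contrast({"fast": [self._est(0.5)],
                                "slow": [self._est(0.05)]})
        assert table.loc["fast", "ratio_vs_slow"] == pytest.approx(10.0)

    def test_undefined_excluded_but_counted(self):
        from orthounmask.evol_phylo import OmegaEstimate
        undef = OmegaEstimate("NG86", None, 0.0, 0.0, 100, 50)
        table = omega_contrast({"g": [self._est(0.4), undef]})
        assert table.loc["g", "n"] == 2 and table.loc["g", "n_defined"] == 1
        assert table.loc["g", "mean_omega"] == pytest.approx(0.4)

    def test_label_permutation_only_reorders(self):
        sets = {"a": [self._est(0.2)], "b": [self._est(0.6)]}
        t1 = omega_contrast(sets)
        t2 = omega_contrast(dict(reversed(list(sets.items()))))
        assert t1.loc["a", "mean_omega"] == t2.loc["a", "mean_omega"]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            omega_contrast({"empty": []})
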