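import math

import numpy as np
import pytest
from scipy import stats

from orthounmask._matrices import blosum62_tables
from orthounmask.profile_search import (CalibrationCurve, build_profile_hmm,
                                        build_pssm, calibrate_evalues,
                                        fit_gumbel, hmm_score,
                                        iterative_search, pssm_from_sequence,
                                        reciprocal_check, search_pssm,
                                        viterbi_align)
from orthounmask.seqio import AA_INDEX, AMINO_ACIDS, Alignment, SequenceRecord
from orthounmask.synthetic_data import make_decoy_proteome

from .oracles import hmm_forward_bruteforce, sw_bruteforce


def random_alignment(rng, n_rows, n_cols, gap_p=0.0):
    rows = []
    for i in range(n_rows):
        chars = [AMINO_ACIDS[k] if rng.random() >= gap_p else "-"
                 for k in rng.integers(0, 20, n_cols)]
        rows.append((f"r{i}", "".join(chars)))
    rows[0] = ("r0", rows[0][1].replace("-", "A"))
    return Alignment(rows)


class TestPSSM:
    def test_conserved_column_sign(self):
        aln = Alignment([("a", "L"), ("b", "L"), ("c", "L")])
        pssm = build_pssm(aln, pseudocount_weight=100.0)
        assert pssm.score_of(0, "L") > 0 > pssm.score_of(0, "D")

    def test_background_column_is_neutral(self):
        # a column whose frequencies equal the background scores ~0 bits
        from orthounmask.profile_search import _mixed_frequencies
        bg, _, _ = blosum62_tables()
        mixed = _mixed_frequencies(bg.copy(), 3.0, 5.0)
        assert np.abs(np.log2(mixed / bg)).max() < 1e-9

    def test_matches_hand_mixing_formula(self):
        """Recompute the pseudocount mixing for a 3-column toy by hand."""
        aln = Alignment([("a", "KLD"), ("b", "KLE"), ("c", "KID")])
        from orthounmask.domain_features import henikoff_weights
        w = henikoff_weights(aln)
        pssm = build_pssm(aln, pseudocount_weight=5.0)
        bg, _, cond = blosum62_tables()
        for j in range(3):
            col = [row[j] for _, row in aln.rows]
            f = np.zeros(20)
            for wi, ch in zip(w, col):
                f[AA_INDEX[ch]] += wi
            f /= f.sum()
            alpha = len(set(col)) - 1.0
            mixed = (alpha * f + 5.0 * (cond @ f)) / (alpha + 5.0)
            np.testing.assert_allclose(pssm.scores[j], np.log2(mixed / bg),
                                       atol=1e-12)

    def test_gappy_columns_excluded(self):
        aln = Alignment([("a", "K-D"), ("b", "K-E"), ("c", "KID"),
                         ("d", "K-D")])
        pssm = build_pssm(aln)
        assert pssm.length == 2 and pssm.source_columns == [0, 2]

    def test_invalid_pseudocount_weight(self, motif_alignment):
        with pytest.raises(ValueError):
            build_pssm(motif_alignment, pseudocount_weight=0.0)


class TestSearchPSSM:
    def test_self_match_envelope(self, motif_alignment):
        pssm = build_pssm(motif_alignment)
        target = SequenceRecord("t", "GGGG" + "KYEIDV" + "GGGG")
        hits = search_pssm(pssm, target)
        assert hits[0].envelope == (4, 10)
        assert hits[0].score_bits == max(h.score_bits for h in hits)

    def test_no_hit_on_poly_proline(self, motif_alignment):
        pssm = build_pssm(motif_alignment)
        assert search_pssm(pssm, SequenceRecord("p", "P" * 20)) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_optimum_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        L, n = 4, 7
        scores = rng.normal(0, 2.5, (L, 20))
        from orthounmask.profile_search import PSSM
        bg, _, _ = blosum62_tables()
        model = PSSM(scores, bg, 1.0, gap_open=4.0, gap_extend=1.0)
        target = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, n))
        hits = search_pssm(model, SequenceRecord("t", target),
                           min_score_bits=-1e8, max_hits=1)
        expected = sw_bruteforce(2.0 * scores, target, 4.0, 1.0)
        assert hits[0].score_bits * 2.0 == pytest.approx(expected, abs=1e-9)


class TestProfileHMM:
    def test_ungapped_columns_become_match_states(self):
        aln = Alignment([("a", "KYEI"), ("b", "KYEI"), ("c", "KYEL")])
        assert build_profile_hmm(aln).n_match == 4

    def test_gappy_column_becomes_insert(self):
        aln = Alignment([("a", "K-YEI"), ("b", "KCYEI"), ("c", "K-YEL"),
                         ("d", "K-YEI"), ("e", "KAYEL")])
        hmm = build_profile_hmm(aln, gap_fraction_threshold=0.5)
        assert hmm.n_match == 4 and hmm.match_columns == [0, 2, 3, 4]

    def test_probability_normalization(self, motif_alignment):
        hmm = build_profile_hmm(motif_alignment)
        hmm.validate()  # asserts all emission/transition sums == 1

    def test_all_gap_threshold_error(self):
        aln = Alignment([("a", "A-"), ("b", "-C")])
        with pytest.raises(ValueError, match="threshold"):
            build_profile_hmm(aln, gap_fraction_threshold=0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_forward_at_least_viterbi(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 4, 6)
        hmm = build_profile_hmm(aln)
        seq = SequenceRecord(
            "s", "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, 15)))
        assert hmm_score(hmm, seq, "forward") >= \
            hmm_score(hmm, seq, "viterbi") - 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_forward_equals_path_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        aln = random_alignment(rng, 3, 3)
        hmm = build_profile_hmm(aln)
        assert hmm.n_match <= 3
        seq = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, 4))
        got = hmm_score(hmm, SequenceRecord("s", seq), "forward")
        expected = hmm_forward_bruteforce(hmm, seq)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_deterministic_emission_hand_score(self):
        """A hand-built two-match-state model emitting K then Y with
        certainty, scored on "KY", reproduces the closed-form sum of
        emission log-odds plus transition terms."""
        from orthounmask.profile_search import ProfileHMM
        bg, _, _ = blosum62_tables()
        em = np.zeros((2, 20))
        em[0, AA_INDEX["K"]] = 1.0
        em[1, AA_INDEX["Y"]] = 1.0
        hmm = ProfileHMM(
            match_emissions=em, insert_emission=bg.copy(),
            mm=np.array([0.9, 0.0]), mi=np.array([0.05, 0.1]),
            md=np.array([0.0, 0.0]), me=np.array([0.05, 0.9]),
            im=np.array([0.6, 0.6]), ii=np.array([0.4, 0.4]),
            dm=np.array([1.0, 1.0]), dd=np.array([0.0, 0.0]),
            background=bg.copy())
        hmm.validate()
        got = hmm_score(hmm, SequenceRecord("s", "KY"), "viterbi")
        expected = (math.log2(1.0 / bg[AA_INDEX["K"]])
                    + math.log2(1.0 / bg[AA_INDEX["Y"]])
                    + math.log2(1.0 / 2.0)              # entry at M1
                    + math.log2(0.9)                    # M1 -> M2
                    + math.log2(0.9))                   # M2 -> E exit
        assert got == pytest.approx(expected, rel=1e-9)
        # the Viterbi path is the full two-state match
        va = viterbi_align(hmm, SequenceRecord("s", "KY"))
        assert va.target_span == (0, 2) and va.match_row == "KY"


class TestCalibration:
    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(1)
        samples = stats.gumbel_r.rvs(loc=5.0, scale=1.0 / 0.7, size=500,
                                     random_state=rng)
        mu, lam = fit_gumbel(samples)
        assert mu == pytest.approx(5.0, rel=0.10)
        assert lam == pytest.approx(0.7, rel=0.10)

    def test_evalue_linear_in_db_size(self):
        curve = CalibrationCurve(mu=2.0, lam=0.7, n_decoys=100, seed=0)
        assert curve.evalue(5.0, 200) == pytest.approx(
            2.0 * curve.evalue(5.0, 100))

    def test_evalue_decreasing_in_score(self):
        curve = CalibrationCurve(mu=2.0, lam=0.7, n_decoys=100, seed=0)
        scores = np.linspace(-5, 15, 50)
        evals = [curve.evalue(s, 100) for s in scores]
        # non-increasing everywhere (the tail saturates at db_size far
        # below mu), strictly decreasing once the tail resolves
        assert all(a >= b for a, b in zip(evals, evals[1:]))
        above = [curve.evalue(s, 100) for s in np.linspace(2, 15, 30)]
        assert all(a > b for a, b in zip(above, above[1:]))

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gumbel(np.full(100, 3.0))

    def test_minimum_decoy_count_enforced(self, motif_alignment):
        hmm = build_profile_hmm(motif_alignment)
        with pytest.raises(ValueError):
            calibrate_evalues(hmm, [], n_decoys=10)


class TestIterativeSearch:
    def test_exact_copy_admitted_and_converges(self, motif_alignment):
        copy = SequenceRecord("copy", "GGGGKYEIDVGGGG")
        decoys = make_decoy_proteome(60, (14, 2), seed=5)
        res = iterative_search(motif_alignment, [decoys + [copy]],
                               seed=1, n_decoys=60)
        assert "copy" in res.admitted and res.admitted["copy"] == 1
        assert res.converged

    def test_deterministic_under_seed(self, motif_alignment):
        copy = SequenceRecord("copy", "GGGGKYEIDVGGGG")
        decoys = make_decoy_proteome(60, (14, 2), seed=5)
        r1 = iterative_search(motif_alignment, [decoys + [copy]],
                              seed=9, n_decoys=60)
        r2 = iterative_search(motif_alignment, [decoys + [copy]],
                              seed=9, n_decoys=60)
        t1 = [(h.target_id, h.envelope, h.score_bits, h.evalue) for h in r1.hits]
        t2 = [(h.target_id, h.envelope, h.score_bits, h.evalue) for h in r2.hits]
        assert t1 == t2 and r1.admitted == r2.admitted

    def test_excluded_id_reported_but_never_admitted(self, motif_alignment):
        copy = SequenceRecord("esterase_like", "GGGGKYEIDVGGGG")
        decoys = make_decoy_proteome(60, (14, 2), seed=5)
        res = iterative_search(motif_alignment, [decoys + [copy]],
                               exclusion_list={"esterase_like"},
                               seed=1, n_decoys=60)
        assert "esterase_like" not in res.admitted
        reported = {h.target_id for h in res.hits}
        assert "esterase_like" in reported

    def test_stepping_stone_requires_intermediate(self, stepping_stone):
        """The central property: the remote ortholog is admitted only when
        the intermediate clade is searchable."""
        ds = stepping_stone
        seed_aln = ds.seed_domain_alignment()
        with_c = iterative_search(
            seed_aln, [ds.decoys + [ds.intermediate, ds.remote]],
            seed=11, n_decoys=100)
        assert "C" in with_c.admitted and with_c.admitted["C"] == 1
        assert "B" in with_c.admitted and with_c.admitted["B"] > 1
        without_c = iterative_search(
            seed_aln, [ds.decoys + [ds.remote]], seed=11, n_decoys=100)
        assert "B" not in without_c.admitted

    def test_admission_monotone_under_sticky_rule(self, stepping_stone):
        ds = stepping_stone
        res = iterative_search(ds.seed_domain_alignment(),
                               [ds.decoys + [ds.intermediate, ds.remote]],
                               seed=11, n_decoys=100)
        # every admitted id stays in the final profile rows
        profile_ids = {rid for rid, _ in res.profile_rows}
        assert set(res.admitted) <= profile_ids

    def test_decoy_only_fdr(self):
        """On decoy-only proteomes the E-values are honest: the count of
        hits at E <= t stays within a small multiple of t."""
        aln = Alignment([(f"s{i}", "KYEIDVLKYEIDVL") for i in range(4)])
        counts_01, counts_1 = [], []
        for seed in (1, 2, 3):
            decoys = make_decoy_proteome(150, (120, 20), seed=seed)
            res = iterative_search(aln, [decoys], seed=seed, n_decoys=100,
                                   max_iterations=1)
            evs = [h.evalue for h in res.hits]
            counts_01.append(sum(e <= 0.1 for e in evs))
            counts_1.append(sum(e <= 1.0 for e in evs))
        assert np.mean(counts_01) <= 0.5    # c = 5 at t = 0.1
        assert np.mean(counts_1) <= 5.0     # c = 5 at t = 1


class TestReciprocal:
    def test_identical_candidate_passes(self):
        refs = [SequenceRecord(f"ref{i}", "MKVLYEIDVKYEIDVLLQ") for i in range(3)]
        background = make_decoy_proteome(80, (18, 3), seed=2)
        cand = SequenceRecord("cand", refs[0].residues)
        ok, best = reciprocal_check(cand, refs, background, seed=3, n_decoys=80)
        assert ok and best in {r.id for r in refs}

    def test_shuffled_candidate_fails(self):
        rng = np.random.default_rng(0)
        refs = [SequenceRecord(f"ref{i}", "MKVLYEIDVKYEIDVLLQ") for i in range(3)]
        background = make_decoy_proteome(80, (18, 3), seed=2)
        letters = list("MNQPSTGRHWCFAAEEDDKK")
        rng.shuffle(letters)
        cand = SequenceRecord("cand", "".join(letters))
        ok, _ = reciprocal_check(cand, refs, background, seed=3, n_decoys=80)
        assert not ok

    def test_diverged_ortholog_vs_decoy(self, stepping_stone):
        ds = stepping_stone
        background = ds.decoys
        ok_true, _ = reciprocal_check(ds.intermediate, ds.seed_records,
                                      background, seed=3, n_decoys=100)
        ok_decoy, _ = reciprocal_check(background[0], ds.seed_records,
                                       background, seed=3, n_decoys=100)
        assert ok_true and not ok_decoy
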