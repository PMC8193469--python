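import itertools
import math

import numpy as np
import pytest

from modclogic.motifs import (
    MarkovBackground,
    MotifError,
    build_interaction_matrix,
    decode_sequence,
    encode_sequence,
    hypergeometric_tail,
    pfm_to_pssm,
    randomization_test,
    reverse_complement,
    scan_sequences,
    score_pvalue_table,
    score_site,
    SiteHit,
)
from modclogic.synthetic import default_promoter_background


@pytest.fixture(scope="module")
def bg():
    return default_promoter_background()


@pytest.fixture(scope="module")
def toy_pssm(bg):
    counts = np.array(
        [[8.0, 1.0, 2.0], [3.0, 5.0, 1.0], [2.0, 9.0, 4.0], [1.0, 2.0, 6.0]]
    )
    return pfm_to_pssm(counts, 1.0, bg, "toy")


class TestBackground:
    def test_row_sums_and_positivity_enforced(self):
        with pytest.raises(MotifError):
            MarkovBackground(np.array([0.5, 0.5, 0.0, 0.0]), np.full((4, 4), 0.25))
        bad = np.full((4, 4), 0.25)
        bad[0, 0] = 0.3
        with pytest.raises(MotifError):
            MarkovBackground(np.full(4, 0.25), bad)

    def test_estimation_from_sequences(self):
        bg = MarkovBackground.from_sequences(["ACGTACGTACGT" * 10], pseudocount=0.1)
        assert np.allclose(bg.transition.sum(axis=1), 1.0)
        assert bg.transition[0, 1] > bg.transition[0, 0]  # A->C dominates A->A

    def test_stationary_is_invariant(self, bg):
        pi = bg.stationary()
        assert np.allclose(pi @ bg.transition, pi)


class TestPSSM:
    def test_uniform_counts_uniform_background_zero_weights(self):
        pssm = pfm_to_pssm(np.full((4, 3), 5.0), 1.0, MarkovBackground.uniform())
        assert np.allclose(pssm.weights, 0.0)

    def test_hand_computed_log_odds(self):
        pssm = pfm_to_pssm(
            np.array([[3.0], [1.0], [0.0], [0.0]]), 1.0, MarkovBackground.uniform()
        )
        assert math.isclose(pssm.weights[0, 0], math.log(((3 + 0.25) / 5) / 0.25))
        assert math.isclose(pssm.weights[0, 2], math.log(((0 + 0.25) / 5) / 0.25))

    def test_weights_shift_with_background(self):
        counts = np.array([[6.0], [2.0], [1.0], [1.0]])
        t = np.full((4, 4), 0.25)
        skewed = MarkovBackground(np.array([0.4, 0.2, 0.2, 0.2]), t)
        # stationary of a uniform transition matrix stays uniform, so skew the
        # transitions towards A instead
        t2 = np.array([[0.55, 0.15, 0.15, 0.15]] * 4)
        skewed = MarkovBackground(np.array([0.55, 0.15, 0.15, 0.15]), t2)
        w_uniform = pfm_to_pssm(counts, 1.0, MarkovBackground.uniform()).weights
        w_skewed = pfm_to_pssm(counts, 1.0, skewed).weights
        assert w_skewed[0, 0] < w_uniform[0, 0]  # common base scores lower

    def test_invalid_matrices_rejected(self, bg):
        with pytest.raises(MotifError):
            pfm_to_pssm(np.empty((4, 0)), 1.0, bg)
        with pytest.raises(MotifError):
            pfm_to_pssm(np.zeros((4, 2)), 1.0, bg)
        with pytest.raises(MotifError):
            pfm_to_pssm(np.full((4, 2), 2.0), 0.0, bg)


class TestScoreSite:
    def test_matches_direct_log_likelihood_ratio(self, bg, toy_pssm):
        for word in ("ACG", "TTT", "GCA"):
            arr = encode_sequence(word)
            motif_ll = sum(toy_pssm.log_freq[i, arr[i]] for i in range(3))
            bg_ll = (
                math.log(bg.initial[arr[0]])
                + math.log(bg.transition[arr[0], arr[1]])
                + math.log(bg.transition[arr[1], arr[2]])
            )
            assert math.isclose(score_site(word, toy_pssm, bg), motif_ll - bg_ll)

    def test_previous_base_conditioning(self, bg, toy_pssm):
        s_init = score_site("ACG", toy_pssm, bg)
        s_prev = score_site("ACG", toy_pssm, bg, previous_base="C")
        delta = math.log(bg.initial[0]) - math.log(bg.transition[1, 0])
        assert math.isclose(s_prev - s_init, delta)

    def test_additivity_over_concatenated_matrices(self, bg):
        c1 = np.array([[5.0], [2.0], [2.0], [1.0]])
        c2 = np.array([[1.0], [6.0], [2.0], [1.0]])
        p1 = pfm_to_pssm(c1, 1.0, bg)
        p2 = pfm_to_pssm(c2, 1.0, bg)
        p12 = pfm_to_pssm(np.hstack([c1, c2]), 1.0, bg)
        s = score_site("AC", p12, bg)
        expected = score_site("A", p1, bg) + score_site("C", p2, bg, previous_base="A")
        assert math.isclose(s, expected)

    def test_ambiguous_base_rejected(self, bg, toy_pssm):
        with pytest.raises(MotifError):
            score_site("ANG", toy_pssm, bg)


class TestScoreDistribution:
    def test_dp_equals_exhaustive_word_enumeration(self, bg, toy_pssm):
        """The DP tail equals summing Markov-1 probabilities of all 64 words."""
        dist = score_pvalue_table(toy_pssm, bg, bin_width=0.001)
        pi = bg.stationary()
        scores, probs = [], []
        for prev in range(4):
            for word in itertools.product(range(4), repeat=3):
                w = np.array(word)
                scores.append(score_site(w, toy_pssm, bg, previous_base=prev))
                probs.append(
                    pi[prev]
                    * bg.transition[prev, w[0]]
                    * bg.transition[w[0], w[1]]
                    * bg.transition[w[1], w[2]]
                )
        scores, probs = np.array(scores), np.array(probs)
        assert math.isclose(probs.sum(), 1.0)
        for q in (-3.0, -1.0, 0.0, 1.0, 2.0):
            exact = probs[scores >= q - 1e-9].sum()
            assert math.isclose(dist.pvalue(q), exact, rel_tol=1e-9, abs_tol=1e-12)

    def test_minimal_score_has_pvalue_one(self, bg, toy_pssm):
        dist = score_pvalue_table(toy_pssm, bg)
        assert dist.pvalue(dist.scores[0]) == 1.0
        assert dist.pvalue(-1e9) == 1.0

    def test_monotone_non_increasing(self, bg, toy_pssm):
        dist = score_pvalue_table(toy_pssm, bg)
        qs = np.linspace(dist.scores[0], dist.scores[-1], 50)
        ps = dist.pvalue(qs)
        assert np.all(np.diff(ps) <= 1e-15)

    def test_bin_halving_changes_pvalues_by_less_than_one_bin(self, bg, toy_pssm):
        coarse = score_pvalue_table(toy_pssm, bg, bin_width=0.02)
        fine = score_pvalue_table(toy_pssm, bg, bin_width=0.01)
        max_bin_mass = coarse.pmf.max()
        for q in (-1.0, 0.0, 1.0):
            assert abs(coarse.pvalue(q) - fine.pvalue(q)) <= 2 * max_bin_mass


class TestScanner:
    def _naive(self, seq, pssm, bg, dist, p_thr, s_thr):
        arr = encode_sequence(seq)
        w = pssm.width
        out = []
        for pos in range(len(seq) - w + 1):
            for strand in "+-":
                if strand == "+":
                    word = arr[pos : pos + w]
                    prev = int(arr[pos - 1]) if pos > 0 else None
                else:
                    word = reverse_complement(arr[pos : pos + w])
                    prev = 3 - int(arr[pos + w]) if pos + w < len(arr) else None
                if np.any(word < 0) or (prev is not None and prev > 3) or (
                    strand == "+" and pos > 0 and arr[pos - 1] < 0
                ):
                    continue
                score = score_site(word, pssm, bg, previous_base=prev)
                pv = dist.pvalue(score)
                if score >= s_thr and pv <= p_thr:
                    out.append((pos, strand, round(score, 9)))
        return sorted(out)

    def test_equals_naive_oracle(self, bg, toy_pssm):
        rng = np.random.default_rng(0)
        seq = decode_sequence(rng.integers(0, 4, 400))
        dist = score_pvalue_table(toy_pssm, bg, bin_width=0.001)
        hits = scan_sequences(
            [("s", seq)], toy_pssm, bg, p_threshold=0.05, score_threshold=0.3,
            distribution=dist,
        )
        got = sorted((h.start, h.strand, round(h.score, 9)) for h in hits)
        assert got == self._naive(seq, toy_pssm, bg, dist, 0.05, 0.3)

    def test_sequence_shorter_than_motif_has_no_hits(self, bg, toy_pssm):
        assert scan_sequences([("s", "AC")], toy_pssm, bg) == []

    def test_empty_sequence_set_rejected(self, bg, toy_pssm):
        with pytest.raises(MotifError):
            scan_sequences([], toy_pssm, bg)

    def test_raising_score_threshold_never_adds_hits(self, bg, toy_pssm):
        rng = np.random.default_rng(1)
        seq = decode_sequence(rng.integers(0, 4, 500))
        loose = scan_sequences([("s", seq)], toy_pssm, bg, 0.1, 0.0)
        tight = scan_sequences([("s", seq)], toy_pssm, bg, 0.1, 1.0)
        loose_keys = {(h.start, h.strand) for h in loose}
        assert {(h.start, h.strand) for h in tight} <= loose_keys

    def test_strand_symmetry_under_rc_symmetric_background(self, toy_pssm):
        """Scanning the reverse complement mirrors the hit set."""
        # an RC-symmetric background: uniform transitions
        bg = MarkovBackground.uniform()
        pssm = pfm_to_pssm(toy_pssm.counts, 1.0, bg, "toy")
        rng = np.random.default_rng(2)
        arr = rng.integers(0, 4, 300)
        seq = decode_sequence(arr)
        rc_seq = decode_sequence(reverse_complement(arr))
        fwd = scan_sequences([("s", seq)], pssm, bg, 0.05, 0.0)
        rev = scan_sequences([("s", rc_seq)], pssm, bg, 0.05, 0.0)
        n = len(seq)
        mirrored = sorted(
            (n - h.end, "-" if h.strand == "+" else "+", round(h.score, 6)) for h in rev
        )
        assert mirrored == sorted((h.start, h.strand, round(h.score, 6)) for h in fwd)

    def test_ambiguous_windows_skipped(self, bg, toy_pssm):
        hits = scan_sequences([("s", "ANNNA" * 20)], toy_pssm, bg, 1.0, -100.0)
        assert all("N" not in h.word for h in hits)


class TestInteractionMatrix:
    def _hit(self, seq_id):
        return SiteHit(seq_id, 0, 3, "+", "ACG", 5.0, 1e-6)

    def test_no_hits_gives_zero_matrix(self):
        mat, rows, cols = build_interaction_matrix(
            {}, {"r1": "g1"}, ["TF1"], ["g1"]
        )
        assert mat.values.sum() == 0

    def test_single_hit_single_cell(self):
        mat, rows, cols = build_interaction_matrix(
            {"TF1": [self._hit("r1")]}, {"r1": "g1", "r2": "g2"}, ["TF1", "TF2"],
            ["g1", "g2"],
        )
        assert mat.loc["TF1", "g1"] == 1
        assert mat.values.sum() == 1
        assert rows["TF1"] == 1 and cols["g1"] == 1

    def test_unmapped_gene_warns(self):
        with pytest.warns(UserWarning, match="no mapped region"):
            mat, _, _ = build_interaction_matrix(
                {"TF1": [self._hit("r1")]}, {"r1": "g1"}, ["TF1"], ["g1", "orphan"]
            )
        assert mat["orphan"].sum() == 0


class TestHypergeometricTail:
    def test_exact_value_against_subset_enumeration(self):
        """N=10, K=5, n=4, k=4: every 4-subset of a 10-universe enumerated."""
        universe = list(range(10))
        marked = set(range(5))
        total = hits = 0
        for subset in itertools.combinations(universe, 4):
            total += 1
            if sum(x in marked for x in subset) >= 4:
                hits += 1
        assert math.isclose(hypergeometric_tail(4, 5, 4, 10), hits / total)
        assert math.isclose(hypergeometric_tail(4, 5, 4, 10), 5 / 210)

    def test_all_marked_gives_one(self):
        for k in range(0, 4):
            assert hypergeometric_tail(k, 10, 3, 10) == 1.0

    def test_zero_draws_tail_is_one(self):
        assert hypergeometric_tail(0, 5, 4, 10) == 1.0

    def test_margin_errors(self):
        with pytest.raises(MotifError):
            hypergeometric_tail(3, 11, 4, 10)
        with pytest.raises(MotifError):
            hypergeometric_tail(5, 5, 4, 10)


class TestRandomization:
    def test_null_pvalues_roughly_uniform(self):
        """Observed sets drawn from the same null show no enrichment."""
        rng = np.random.default_rng(0)
        marked = set(rng.choice(500, size=100, replace=False))

        def count_targets(genes):
            return {"TF": sum(g in marked for g in genes)}

        universe = list(range(500))
        pvals = []
        for trial in range(40):
            obs = list(rng.choice(universe, size=20, replace=False))
            df = randomization_test(count_targets, universe, obs,
                                    group_size=20, n_groups=25, seed=trial)
            pvals.append(df.pvalue.iloc[0])
        frac_small = np.mean(np.array(pvals) < 0.05)
        # binomial 3-sigma band around 0.05 with 40 trials
        assert frac_small <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 40)

    def test_enriched_set_detected(self):
        marked = set(range(100))  # genes 0..99 carry sites

        def count_targets(genes):
            return {"TF": sum(g in marked for g in genes)}

        universe = list(range(100, 600))  # background universe without sites
        obs = list(range(0, 20))
        df = randomization_test(count_targets, universe, obs,
                                group_size=20, n_groups=50, seed=1)
        assert df.pvalue.iloc[0] < 1e-3

    def test_zero_groups_rejected(self):
        with pytest.raises(MotifError):
            randomization_test(lambda g: {}, list(range(100)), [1], n_groups=0)
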