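import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regcircuit.io_formats import SequenceRecord, reverse_complement
from regcircuit.motif import (MarkovBackground, PWM, SiteHit, align_pwms,
                              build_pwm_from_sites, discover_motifs_zoops,
                              filter_overlaps, information_content, log_odds,
                              sample_background_sequence, scan_sequences,
                              score_pvalue_table, train_markov_background)
from regcircuit.synthetic_data import consensus_pwm, plant_sites

from conftest import random_pwm


class TestBuildPwm:
    def test_unanimous_counts(self):
        pwm = build_pwm_from_sites(["AC", "AC"], alpha=0.0)
        assert pwm.matrix[0, 0] == 1.0 and pwm.matrix[1, 1] == 1.0

    def test_even_split(self):
        pwm = build_pwm_from_sites(["A", "C"], alpha=0.0)
        assert pwm.matrix[0, 0] == 0.5 and pwm.matrix[0, 1] == 0.5

    def test_pseudocount_formula(self):
        pwm = build_pwm_from_sites(["A"], alpha=1.0)
        assert pwm.matrix[0, 0] == pytest.approx(0.625)
        assert pwm.matrix[0, 1] == pytest.approx(0.125)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_pwm_from_sites(["AC", "A"])

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            build_pwm_from_sites([])

    def test_reproduces_empirical_frequencies_of_planted_sites(self, rng,
                                                               uniform_bg):
        truth = consensus_pwm("TGACGTCATTGA", p=0.9)
        seqs = [SequenceRecord(f"s{i}",
                               sample_background_sequence(uniform_bg, 60, rng))
                for i in range(40)]
        planted, sites = plant_sites(seqs, truth, 1.0, rng)
        by_id = {r.id: r.sequence for r in planted}
        letters = []
        for sid, start, strand in sites:
            s = by_id[sid][start - 1:start + 11]
            letters.append(s if strand == "+" else reverse_complement(s))
        pwm = build_pwm_from_sites(letters, alpha=0.0)
        counts = np.zeros((12, 4))
        for word in letters:
            for j, ch in enumerate(word):
                counts[j, "ACGT".index(ch)] += 1
        assert np.allclose(pwm.matrix, counts / len(letters))


class TestInformationContent:
    def test_small_sample_closed_form(self):
        pwm = PWM("m", np.array([[1.0, 0, 0, 0]]), nsites=4)
        e4 = 3.0 / (8.0 * math.log(2.0))
        assert information_content(pwm)[0] == pytest.approx(2.0 - e4, abs=1e-9)
        assert e4 == pytest.approx(0.5410, abs=1e-4)

    def test_limits(self):
        certain = PWM("m", np.array([[1.0, 0, 0, 0]]), nsites=10 ** 9)
        assert information_content(certain)[0] == pytest.approx(2.0, abs=1e-6)
        uniform = PWM("m", np.full((1, 4), 0.25), nsites=10 ** 9)
        assert information_content(uniform)[0] == pytest.approx(0.0, abs=1e-6)

    def test_requires_sites(self):
        pwm = PWM("m", np.full((1, 4), 0.25), nsites=0)
        with pytest.raises(ValueError):
            information_content(pwm)


class TestMarkovBackground:
    def test_order0_add_one_smoothing(self):
        bg = train_markov_background(["AACC"], order=0)
        assert np.allclose(bg.marginal, [3 / 8, 3 / 8, 1 / 8, 1 / 8])

    def test_order1_hand_count(self):
        # "AAAAAAA": six A->A transitions; add-one gives P(A|A) = 7/10
        bg = train_markov_background(["AAAAAAA"], order=1)
        assert bg.probs["A"][0] == pytest.approx(7 / 10)
        assert bg.probs["A"][1] == pytest.approx(1 / 10)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            train_markov_background(["ACG"], order=4)

    def test_order_bounds(self):
        with pytest.raises(ValueError):
            train_markov_background(["ACGT" * 100], order=5)

    def test_n_windows_skipped(self):
        bg = train_markov_background(["AANCC"], order=0)
        # counts A2 C2 (N skipped), smoothed as in the 4-letter case
        assert np.allclose(bg.marginal, [3 / 8, 3 / 8, 1 / 8, 1 / 8])


class TestSampling:
    def test_uniform_law_of_large_numbers(self, uniform_bg):
        seq = sample_background_sequence(uniform_bg, 10 ** 5, seed=1)
        for base in "ACGT":
            assert 0.24 <= seq.count(base) / 1e5 <= 0.26

    def test_absorbing_order1_chain(self):
        probs = {"": np.array([1.0, 0, 0, 0])}
        for ctx in "ACGT":
            probs[ctx] = np.array([1.0, 0, 0, 0])
        bg = MarkovBackground(order=1, probs=probs)
        assert sample_background_sequence(bg, 10, seed=3) == "A" * 10

    def test_same_seed_same_sequence(self, uniform_bg):
        a = sample_background_sequence(uniform_bg, 500, seed=11)
        b = sample_background_sequence(uniform_bg, 500, seed=11)
        assert a == b

    def test_length_below_order_rejected(self):
        bg = MarkovBackground.uniform(2)
        with pytest.raises(ValueError):
            sample_background_sequence(bg, 1, seed=0)


class TestLogOdds:
    def test_unanimous_column_two_bits(self, uniform_bg):
        pwm = build_pwm_from_sites(["A", "A"], alpha=0.0)
        lo = log_odds(pwm, uniform_bg)
        assert lo[0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_background_pwm_scores_zero(self, uniform_bg):
        pwm = PWM("m", np.full((3, 4), 0.25))
        assert np.allclose(log_odds(pwm, uniform_bg), 0.0)

    def test_monotone_in_probability(self, uniform_bg):
        pwm = PWM("m", np.array([[0.1, 0.2, 0.3, 0.4]]))
        lo = log_odds(pwm, uniform_bg)[0]
        assert np.all(np.diff(lo) > 0)


class TestPvalueTable:
    def test_width1_max_score_quarter(self, uniform_bg):
        pwm = PWM("m", np.array([[0.7, 0.1, 0.1, 0.1]]))
        table = score_pvalue_table(pwm, uniform_bg)
        max_int = int(table.int_matrix.max())
        assert table.pvalue_int(max_int) == pytest.approx(0.25)

    def test_min_score_has_p_one(self, rng, uniform_bg):
        pwm = random_pwm(rng, 6)
        table = score_pvalue_table(pwm, uniform_bg)
        assert table.pvalue_int(int(table.int_matrix.min(axis=1).sum())) == 1.0

    def test_dp_matches_enumeration_small_width(self, rng, uniform_bg):
        eps = 1e-3
        for _ in range(5):
            w = int(rng.integers(2, 7))
            pwm = random_pwm(rng, w)
            table = score_pvalue_table(pwm, uniform_bg, eps)
            lo = log_odds(pwm, uniform_bg)
            words = np.array(list(itertools.product(range(4), repeat=w)))
            real = lo[np.arange(w), words].sum(axis=1)
            prob = np.full(len(words), 0.25 ** w)
            ints = table.int_matrix[np.arange(w), words].sum(axis=1)
            for wi in range(len(words)):
                p_dp = table.pvalue_int(int(ints[wi]))
                band = w * eps + 1e-12
                p_hi = prob[real >= real[wi] - band].sum()
                p_lo = prob[real >= real[wi] + band].sum()
                assert p_lo - 1e-12 <= p_dp <= p_hi + 1e-12

    def test_rejects_zero_probabilities(self, uniform_bg):
        pwm = build_pwm_from_sites(["A", "A"], alpha=0.0)
        with pytest.raises(ValueError):
            score_pvalue_table(pwm, uniform_bg)


class TestScan:
    def test_planted_consensus_found_at_offset(self, rng, uniform_bg):
        pwm = consensus_pwm("TGCACCATTGGT", p=0.94)
        seq = sample_background_sequence(uniform_bg, 200, rng)
        site = "TGCACCATTGGT"
        seq = seq[:80] + site + seq[92:]
        hits = scan_sequences(pwm, [("s", seq)], uniform_bg, p_max=1e-4)
        assert any(h.start == 81 and h.strand == "+" and h.pvalue < 1e-4
                   for h in hits)

    def test_strand_symmetry(self, rng, uniform_bg):
        pwm = consensus_pwm("TGCACCATTGGT", p=0.94)
        seq = sample_background_sequence(uniform_bg, 120, rng)
        fwd = scan_sequences(pwm, [("s", seq)], uniform_bg, p_max=1.0)
        rev = scan_sequences(pwm, [("s", reverse_complement(seq))],
                             uniform_bg, p_max=1.0)
        fwd_set = {(h.start, h.strand, round(h.score, 6), h.pvalue) for h in fwd}
        n = len(seq)
        flipped = {(n - h.end + 1, "+" if h.strand == "-" else "-",
                    round(h.score, 6), h.pvalue) for h in rev}
        assert fwd_set == flipped

    def test_short_sequence_yields_no_hits(self, uniform_bg):
        pwm = consensus_pwm("TGCACCATTGGT", p=0.94)
        assert scan_sequences(pwm, [("s", "ACGT")], uniform_bg) == []

    def test_windows_with_n_skipped(self, uniform_bg):
        pwm = consensus_pwm("ACGTAC", p=0.94)
        hits = scan_sequences(pwm, [("s", "ACGNACGTACGT")], uniform_bg,
                              p_max=1.0)
        assert all(h.start > 4 for h in hits if h.strand == "+")


class TestFilterOverlaps:
    def test_best_score_wins_on_coincident_hits(self):
        a = SiteHit("s", 10, 21, "+", 10.0, 1e-6, "m")
        b = SiteHit("s", 10, 21, "-", 8.0, 1e-5, "m")
        assert filter_overlaps([a, b]) == [a]

    def test_forty_percent_overlap_both_kept(self):
        a = SiteHit("s", 1, 10, "+", 10.0, 1e-6, "m")
        b = SiteHit("s", 7, 16, "+", 8.0, 1e-5, "m")  # 4/10 overlap
        assert set((h.start, h.end) for h in filter_overlaps([a, b])) == \
            {(1, 10), (7, 16)}

    def test_equal_score_leftmost_kept(self):
        a = SiteHit("s", 5, 14, "+", 9.0, 1e-5, "m")
        b = SiteHit("s", 8, 17, "+", 9.0, 1e-5, "m")
        assert filter_overlaps([a, b]) == [a]

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 60), st.integers(0, 100),
                  st.sampled_from("+-")),
        min_size=0, max_size=12))
    def test_permutation_invariant_and_idempotent(self, raw):
        hits = [SiteHit("s", start, start + 9, strand, score / 7.0,
                        1.0 / (1 + score), "m")
                for start, score, strand in raw]
        ref = filter_overlaps(hits)
        assert filter_overlaps(list(reversed(hits))) == ref
        assert filter_overlaps(ref) == ref


@pytest.fixture(scope="module")
def planted():
    bg = MarkovBackground.uniform(0)
    truth = consensus_pwm("TGCACCATTGGT", p=0.94, motif_id="truth")
    rng = np.random.default_rng(42)
    seqs = [SequenceRecord(f"s{i}", sample_background_sequence(bg, 200, rng))
            for i in range(30)]
    planted_seqs, sites = plant_sites(seqs, truth, 0.8, rng)
    return bg, truth, planted_seqs, sites


class TestZoops:

    def test_recovers_planted_pwm_and_occupancy(self, planted):
        bg, truth, seqs, sites = planted
        found = discover_motifs_zoops(seqs, widths=[12], n_motifs=1,
                                      background=bg, seed=42)
        dm = found[0]
        r, _, _ = align_pwms(truth, dm.pwm)
        assert r >= 0.9
        assert abs(dm.gamma_hat - 0.8) <= 0.15

    def test_loglik_trace_nondecreasing(self, planted):
        bg, truth, seqs, _ = planted
        for seed in (42, 7):
            dm = discover_motifs_zoops(seqs, widths=[12], n_motifs=1,
                                       background=bg, seed=seed)[0]
            diffs = np.diff(dm.loglik_trace)
            assert np.all(diffs >= -1e-9)

    def test_width_selection_brackets_truth(self, planted):
        bg, truth, seqs, _ = planted
        found = discover_motifs_zoops(seqs, widths=[10, 12, 14], n_motifs=1,
                                      background=bg, seed=42)
        r, _, _ = align_pwms(truth, found[0].pwm)
        assert r >= 0.85

    def test_null_sequences_give_weak_motif(self, uniform_bg):
        # EM on 30 random 200-mers overfits an apparent ~0.7 bits/column
        # pattern; a planted high-IC motif is well separated from that
        rng = np.random.default_rng(17)
        nulls = [SequenceRecord(f"n{i}",
                                sample_background_sequence(uniform_bg, 200, rng))
                 for i in range(30)]
        dm = discover_motifs_zoops(nulls, widths=[12], n_motifs=1,
                                   background=uniform_bg, seed=42)[0]
        n_eff = max(1, int(round(dm.gamma_hat * 30)))
        ic = information_content(dm.pwm, nsites=n_eff).mean()
        assert ic < 1.1  # far below the >=1.5 bits/column of planted motifs

    def test_needs_two_sequences(self, uniform_bg):
        with pytest.raises(ValueError):
            discover_motifs_zoops([("a", "ACGTACGTACGT")], widths=[5],
                                  background=uniform_bg)

    def test_too_short_sequences_rejected(self, uniform_bg):
        with pytest.raises(ValueError):
            discover_motifs_zoops([("a", "ACG"), ("b", "ACG")], widths=[12],
                                  background=uniform_bg)
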