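"""Cross-validation folds, focused rank metrics, significance tests."""

import numpy as np
import pytest
from scipy import stats

from mbenrich.evaluation import (generalized_spearman, make_folds,
                                 mcnemar_test, paired_t_test,
                                 selectivity_analysis,
                                 top_fraction_identification_accuracy,
                                 williams_t_test)


class TestFolds:
    def test_nine_sequences_three_folds(self):
        fa = make_folds([f"s{i}" for i in range(9)], k=3, seed=0)
        sizes = np.bincount(fa.fold)
        assert sizes.tolist() == [3, 3, 3]

    def test_partition_and_determinism(self):
        seqs = [f"s{i}" for i in range(20)]
        a = make_folds(seqs, k=3, seed=4)
        b = make_folds(seqs, k=3, seed=4)
        np.testing.assert_array_equal(a.fold, b.fold)
        for f in range(3):
            assert set(a.test_indices(f)) & set(a.train_indices(f)) == set()
        assert sorted(np.concatenate([a.test_indices(f) for f in range(3)])) \
            == list(range(20))

    def test_too_few_sequences_or_folds(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=3)
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], k=1)

    def test_heldout_reads_never_in_training(self, rng):
        """Reads follow their source sequence's fold, even truncated ones."""
        from mbenrich.fitness import simulate_fitness
        from mbenrich.simulate import (nnk_library, sample_reads,
                                       simulate_selection)
        lib = nnk_library(30, 60, rng)
        sel = simulate_selection(lib, simulate_fitness(30, T=10, seed=0), rng)
        rs = sample_reads(sel, 400, 400, read_mode="short", window_codons=10,
                          rng=rng)
        fa = make_folds(list(range(len(lib))), k=3, seed=1)
        for f in range(3):
            train = set(fa.train_indices(f).tolist())
            table = rs.to_count_table(sources=train)
            held_out_reads = {r for i in fa.test_indices(f)
                              for cond in rs.by_source
                              for r in cond.get(int(i), {})}
            held_out_only = held_out_reads - {
                r for i in train for cond in rs.by_source
                for r in cond.get(int(i), {})}
            from mbenrich.alphabets import translate
            assert {translate(r) for r in held_out_only}.isdisjoint(
                set(table.sequences))


class TestGeneralizedSpearman:
    def test_full_fraction_is_standard_spearman(self, rng):
        pred, truth = rng.normal(size=30), rng.normal(size=30)
        assert generalized_spearman(pred, truth, 1.0) == pytest.approx(
            stats.spearmanr(pred, truth).statistic)
        assert generalized_spearman(pred, truth, 1.0, tail="bottom") == \
            pytest.approx(stats.spearmanr(pred, truth).statistic)

    def test_perfect_prediction_all_fractions(self, rng):
        truth = rng.normal(size=50)
        for f in (0.1, 0.4, 1.0):
            assert generalized_spearman(truth, truth, f) == pytest.approx(1.0)

    def test_five_point_hand_example(self):
        truth = np.array([1.0, 2, 3, 4, 5])
        pred = np.array([2.0, 1, 3, 5, 4])
        # top 60% of truth: indices 2,3,4 -> truth (3,4,5), pred (3,5,4);
        # ranks: truth (1,2,3), pred (1,3,2) -> rho = 1 - 6*2/(3*8) = 0.5
        assert generalized_spearman(pred, truth, 0.6, tail="top") == \
            pytest.approx(0.5)

    def test_degenerate_subsets_rejected(self):
        with pytest.raises(ValueError):
            generalized_spearman([1, 2, 3], [1, 2, 3], 0.3)
        with pytest.raises(ValueError):
            generalized_spearman([1.0, 1.0, 1.0], [1, 2, 3], 1.0)


class TestSelectivity:
    def test_oracle_predictor_selects_truly_best(self, rng):
        tp, tn = rng.normal(size=40), rng.normal(size=40)
        rep = selectivity_analysis(tp, tn, tp, tn, top_k=10)
        truly = np.argsort(-(tp - tn), kind="stable")[:10]
        np.testing.assert_array_equal(np.sort(rep.selected_indices),
                                      np.sort(truly))

    def test_distance_zero_iff_mean_is_optimum(self):
        tp = np.array([1.0, 0.0, 0.0, 1.0])
        tn = np.array([0.0, 1.0, 1.0, 0.0])
        rep = selectivity_analysis(tp, tn, tp, tn, top_k=2)
        assert rep.distance == pytest.approx(0.0)
        np.testing.assert_array_equal(rep.optimum, [1.0, 0.0])

    def test_four_sequence_hand_example(self):
        truth_pos = np.array([2.0, 1.0, 0.0, -1.0])
        truth_neg = np.array([0.0, -2.0, 1.0, 0.5])
        pred_pos = np.array([1.9, 1.1, 0.1, -0.9])
        pred_neg = np.array([0.1, -1.9, 0.9, 0.4])
        rep = selectivity_analysis(pred_pos, pred_neg, truth_pos, truth_neg,
                                   top_k=2)
        # predicted selectivity: 1.8, 3.0, -0.8, -1.3 -> picks 1 then 0
        np.testing.assert_array_equal(rep.selected_indices, [1, 0])
        np.testing.assert_allclose(rep.mean_point, [1.5, -1.0])
        # optimum (2, -2); distance = sqrt(0.5^2 + 1^2)
        assert rep.distance == pytest.approx(np.sqrt(1.25))

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            selectivity_analysis([1], [1, 2], [1], [1])


class TestTopFractionAccuracy:
    def test_perfect_and_reversed(self):
        sel = np.arange(100, dtype=float)
        assert top_fraction_identification_accuracy(sel, sel, 0.05).tolist() \
            == [1] * 5
        assert top_fraction_identification_accuracy(-sel, sel, 0.05).tolist() \
            == [0] * 5

    def test_matches_set_intersection_oracle(self, rng):
        truth = rng.normal(size=100)
        pred = rng.normal(size=100)
        hits = top_fraction_identification_accuracy(pred, truth, 0.1)
        true_top = set(np.argsort(-truth, kind="stable")[:10].tolist())
        pred_top = set(np.argsort(-pred, kind="stable")[:10].tolist())
        assert hits.sum() == len(true_top & pred_top)


class TestWilliamsT:
    def test_equal_correlations_give_zero(self):
        t, p = williams_t_test(0.5, 0.5, 0.3, 50)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        t1, p1 = williams_t_test(0.7, 0.4, 0.5, 40)
        t2, p2 = williams_t_test(0.4, 0.7, 0.5, 40)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_against_independent_formula(self):
        """Steiger's T2, coded independently, reproduced to 3+ decimals."""
        r1g, r2g, r12, n = 0.63, 0.21, 0.051, 66
        detR = (1 - r1g ** 2 - r2g ** 2 - r12 ** 2 + 2 * r1g * r2g * r12)
        rbar = (r1g + r2g) / 2
        expected_t = (r1g - r2g) * np.sqrt(
            (n - 1) * (1 + r12)
            / (2 * (n - 1) / (n - 3) * detR + rbar ** 2 * (1 - r12) ** 3))
        t, p = williams_t_test(r1g, r2g, r12, n)
        assert t == pytest.approx(expected_t, abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), n - 3))
        assert t == pytest.approx(3.0138, abs=2e-3)  # frozen from the formula

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            williams_t_test(1.5, 0.0, 0.0, 10)
        with pytest.raises(ValueError):
            williams_t_test(0.5, 0.4, 0.3, 3)


class TestMcNemar:
    def test_symmetric_discordance(self):
        _, p = mcnemar_test(7, 7)
        assert p == pytest.approx(1.0)

    def test_one_sided_discordance_exact(self):
        _, p = mcnemar_test(10, 0)
        assert p == pytest.approx(2 / 1024)

    def test_no_discordance_warns(self):
        with pytest.warns(UserWarning):
            _, p = mcnemar_test(0, 0)
        assert p == 1.0

    def test_chi2_close_to_exact_for_large_counts(self, rng):
        """Both paths agree closely where the p-value is decision-relevant.

        The continuity-corrected chi-squared approximation is conservative
        near b = c (where the exact two-sided p saturates at 1), so
        agreement is checked in absolute terms there and in relative terms
        in the moderate-p regime.
        """
        for _ in range(40):
            b = int(rng.integers(5, 30))
            c = int(rng.integers(5, 30))
            if b + c < 25:
                continue
            _, p_chi2 = mcnemar_test(b, c, exact_threshold=0)
            _, p_exact = mcnemar_test(b, c, exact_threshold=10 ** 9)
            assert abs(p_chi2 - p_exact) < 0.16
            if 0.01 < p_exact < 0.9:
                assert p_chi2 == pytest.approx(p_exact, rel=0.13)


class TestPairedT:
    def test_five_pair_hand_example(self):
        pairs = [(0.9, 0.8), (0.7, 0.6), (0.85, 0.8), (0.6, 0.55), (0.95, 0.7)]
        diffs = np.array([a - b for a, b in pairs])
        expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        t, p = paired_t_test(pairs)
        assert t == pytest.approx(expected)

    def test_sign_flip_and_zero_variance(self):
        pairs = [(0.9, 0.8), (0.7, 0.75), (0.85, 0.8)]
        t1, _ = paired_t_test(pairs)
        t2, _ = paired_t_test([(b, a) for a, b in pairs])
        assert t1 == pytest.approx(-t2)
        with pytest.raises(ValueError):
            paired_t_test([(0.5, 0.4), (0.6, 0.5)])
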