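"""Library construction, selection, and read simulation."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from mbenrich.alphabets import translate
from mbenrich.fitness import FitnessFunction, simulate_fitness
from mbenrich.simulate import (Library, add_substitution_errors,
                               mutagenesis_library, nnk_library,
                               random_parents, recombination_library,
                               sample_condition_reads, sample_reads,
                               simulate_selection, simulate_selectivity)


def _flat_fitness(L_a, alphabet="protein"):
    A = 20 if alphabet == "protein" else 4
    return FitnessFunction(L_a=L_a, terms=[(i,) for i in range(L_a)],
                           coefficients=[np.zeros(A)] * L_a,
                           term_seeds=[None] * L_a, alphabet=alphabet)


class TestNnkLibrary:
    def test_single_codon_exhaustion(self, rng):
        lib = nnk_library(1, 31, rng, chunk=500)
        # 32 NNK codons, one of which (TAG) is a stop and is rejected
        assert len(lib) == 31
        assert all(len(s) == 3 and s[2] in "GT" for s in lib.sequences)
        assert "TAG" not in lib.sequences
        assert lib.counts.sum() >= 31

    def test_codon_frequencies_uniform(self, rng):
        lib = nnk_library(1, 31, rng, chunk=100_000, reject_stops=False)
        # use the accumulated multiplicities as draws of the 32 codons
        observed = lib.counts
        expected = observed.sum() / 32
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=31) > 1e-4

    def test_stop_free_translations(self, rng):
        lib = nnk_library(4, 500, rng)
        assert all("*" not in t for t in lib.translated())
        assert lib.n_rejected > 0  # 12-mers hit TAG often enough

    def test_unreachable_target_rejected(self, rng):
        with pytest.raises(ValueError):
            nnk_library(1, 33, rng)


class TestMutagenesisLibrary:
    def test_mutation_count_matches_binomial_mean(self, rng):
        ref = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                      for i in rng.integers(0, 20, 50))
        lib = mutagenesis_library(ref, 0.05, 3000, rng)
        aa = lib.translated()
        dists = np.array([sum(a != b for a, b in zip(t, ref)) for t in aa])
        # generation-weighted mean distance; unique-set selection skews low
        # (the unmutated reference is drawn repeatedly), so weight by counts
        mean = np.average(dists, weights=lib.counts)
        se = np.sqrt(50 * 0.05 * 0.95 / lib.counts.sum())
        assert abs(mean - 50 * 0.05) < 4 * se + 0.05

    def test_same_seed_identical(self):
        ref = "MKV" * 10
        a = mutagenesis_library(ref, 0.02, 200, np.random.default_rng(5))
        b = mutagenesis_library(ref, 0.02, 200, np.random.default_rng(5))
        assert a.sequences == b.sequences
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_degenerate_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            mutagenesis_library("MKV", 0.0, 5, rng)


class TestRecombinationLibrary:
    def test_two_parents_three_blocks_exhaustive(self):
        p1, p2 = "AAA" * 3, "CCC" * 3  # 3 codon blocks, all differing
        lib = recombination_library([p1, p2], 3)
        assert len(lib) == 8  # 2^3 chimeras

    def test_identical_parents_collapse(self):
        lib = recombination_library(["ACGACG", "ACGACG"], 2)
        assert len(lib) == 1 and lib.counts[0] == 4

    def test_shared_block_collapsing(self):
        # parents share block 2 -> 2 * 1 * 2 = 4 distinct, from 8 choices
        p1 = "AAA" + "GGG" + "AAA"
        p2 = "CCC" + "GGG" + "TTT"
        lib = recombination_library([p1, p2], 3)
        assert len(lib) == 4
        assert lib.counts.sum() == 8

    def test_unequal_parents_rejected(self):
        with pytest.raises(ValueError):
            recombination_library(["AAACCC", "AAA"], 2)

    def test_sampled_construction_counts(self, rng):
        parents = random_parents(4, 10, rng)
        lib = recombination_library(parents, 5, rng=rng, target_unique=50)
        assert len(lib) == 50
        assert all("*" not in t for t in lib.translated())


class TestSelection:
    def test_constant_fitness_preserves_distribution(self, rng):
        lib = nnk_library(2, 50, rng)
        sel = simulate_selection(lib, _flat_fitness(2), rng)
        np.testing.assert_allclose(sel.p_post, sel.p_pre, rtol=1e-12)

    def test_two_sequence_hand_normalization(self, rng):
        lib = Library(["AAAAAA", "TGCTGC"], [1, 1], "nnk")
        F = FitnessFunction(L_a=2, terms=[(0,), (1,)],
                            coefficients=[np.array([np.log(3.0)] + [0.0] * 19),
                                          np.zeros(20)],
                            term_seeds=[None, None])
        # translations: KK (K idx 8) and CC; give K log(3) at site 0, else 0
        coef = np.zeros(20)
        coef[8] = np.log(3.0)
        F.coefficients[0] = coef
        sel = simulate_selection(lib, F, rng)
        q = sel.p_pre[0]
        np.testing.assert_allclose(sel.p_post[0], 3 * q / (2 * q + 1), rtol=1e-12)
        np.testing.assert_allclose(sel.p_post[1], (1 - q) / (2 * q + 1), rtol=1e-12)

    def test_dirichlet_mean_matches_counts(self, rng):
        lib = Library(["AAA", "CCC", "GGG"], [1, 2, 7], "nnk")
        F = _flat_fitness(1)
        draws = np.array([simulate_selection(lib, F, rng).p_pre
                          for _ in range(10_000)])
        mean = draws.mean(axis=0)
        expected = np.array([0.1, 0.2, 0.7])
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(mean - expected) < 4 * se)

    def test_ground_truth_invariant(self, rng):
        """log(p_post/p_pre) - F is constant across sequences."""
        lib = nnk_library(3, 200, rng)
        F = simulate_fitness(3, T=20, seed=8)
        sel = simulate_selection(lib, F, rng)
        c = np.log(sel.p_post / sel.p_pre) - sel.fitness_values
        assert c.max() - c.min() < 1e-10

    def test_replicates_differ_but_share_support(self, rng):
        lib = nnk_library(2, 30, rng)
        F = simulate_fitness(2, T=5, seed=1)
        a = simulate_selection(lib, F, np.random.default_rng(1))
        b = simulate_selection(lib, F, np.random.default_rng(2))
        assert not np.allclose(a.p_pre, b.p_pre)
        assert a.library is b.library


class TestSampleReads:
    def test_multinomial_totals(self, rng):
        lib = nnk_library(2, 50, rng)
        sel = simulate_selection(lib, simulate_fitness(2, T=5, seed=0), rng)
        rs = sample_reads(sel, 500, 700, rng=rng)
        assert rs.totals.tolist() == [500, 700]
        assert rs.library_counts.sum(axis=0).tolist() == [500, 700]

    def test_single_sequence_full_mode(self, rng):
        lib = Library(["ACGACG"], [3], "nnk")
        sel = simulate_selection(lib, _flat_fitness(2), rng)
        rs = sample_reads(sel, 10, 10, rng=rng)
        assert rs.condition_counts(0) == Counter({"ACGACG": 10})

    def test_short_read_windows_codon_aligned_uniform(self, rng):
        n_cod, window = 150, 100
        from mbenrich.alphabets import back_translate
        aa = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                     for i in np.random.default_rng(0).integers(0, 20, n_cod))
        seq = back_translate(aa)
        lib = Library([seq], [1], "nnk")
        F = _flat_fitness(n_cod)
        sel = simulate_selection(lib, F, rng)
        rs = sample_reads(sel, 20000, 1, read_mode="short",
                          window_codons=window, rng=rng)
        starts = Counter()
        for r, n in rs.condition_counts(0).items():
            assert len(r) == 3 * window
            pos = seq.find(r)
            assert pos >= 0 and pos % 3 == 0
            starts[pos // 3] += n
        assert len(starts) == n_cod - window + 1 == 51
        observed = np.array([starts.get(i, 0) for i in range(51)])
        expected = observed.sum() / 51
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=50) > 1e-4

    def test_window_longer_than_sequence_emits_full(self, rng):
        lib = Library(["ACGACG"], [1], "nnk")
        sel = simulate_selection(lib, _flat_fitness(2), rng)
        rs = sample_reads(sel, 5, 5, read_mode="short", window_codons=100,
                          rng=rng)
        assert set(rs.condition_counts(0)) == {"ACGACG"}

    def test_hybrid_mode_mixes_depths(self, rng):
        lib = nnk_library(40, 30, rng)
        sel = simulate_selection(lib, _flat_fitness(40), rng)
        rs = sample_reads(sel, (10, 90), (10, 90), read_mode="hybrid",
                          window_codons=10, rng=rng)
        lengths = Counter()
        for r, n in rs.condition_counts(0).items():
            lengths[len(r)] += n
        assert rs.totals.tolist() == [100, 100]
        assert lengths[120] >= 10  # full-length reads present
        assert lengths[30] > 0     # truncated reads present

    def test_three_condition_sampling(self, rng):
        lib = nnk_library(2, 30, rng)
        fits = [simulate_fitness(2, T=3, seed=s) for s in (1, 2)]
        sel = simulate_selectivity(lib, fits, rng)
        rs = sample_condition_reads(lib, [sel.p_pre] + sel.p_posts,
                                    [100, 100, 100], rng=rng)
        assert rs.n_conditions == 3
        assert rs.totals.tolist() == [100, 100, 100]


class TestSubstitutionErrors:
    def test_rate_zero_is_identity(self, rng):
        reads = ["ACGT", "GGGG"]
        assert add_substitution_errors(reads, 0.0, "dna", rng) == reads

    def test_error_rate_within_binomial_band(self, rng):
        reads = ["A" * 100] * 10_000  # 1e6 positions
        out = add_substitution_errors(reads, 0.001, "dna", rng)
        n_subs = sum(sum(c != "A" for c in r) for r in out)
        se = np.sqrt(1e6 * 0.001 * 0.999)
        assert abs(n_subs - 1000) < 4 * se

    def test_lengths_always_preserved(self, rng):
        reads = ["ACG", "ACGTACGT", "A"]
        out = add_substitution_errors(reads, 0.5, "dna", rng)
        assert [len(r) for r in out] == [3, 8, 1]

    def test_substituted_base_differs(self, rng):
        out = add_substitution_errors(["A" * 1000], 1.0 - 1e-12, "dna", rng)
        assert "A" not in out[0]
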