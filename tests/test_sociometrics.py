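"""Dominance indices, interaction matrices, TauKr, rank tests, Hochberg."""

import itertools

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from conftest import manual_log
from groofiworld import pcmc, sociometrics
from groofiworld.sociometrics import (average_dominance_index, build_matrices,
                                      build_wins_matrix, hochberg_combine,
                                      kendall_tau_b, mann_whitney_u, taukr,
                                      taukr_statistic, wilcoxon_matched)

FEMALES = [0, 1, 2, 3]


class TestAverageDominanceIndex:
    def test_mean_of_dyadic_proportions(self):
        wins = np.zeros((3, 3))
        wins[0, 1], wins[1, 0] = 3, 1   # beats 1 in 3 of 4
        wins[0, 2] = 2                   # beats 2 in 2 of 2
        adi, ranks = average_dominance_index(wins)
        assert adi[0] == pytest.approx(np.mean([0.75, 1.0]))
        assert ranks[0] == 1

    def test_individual_without_fights_is_missing_and_ranked_last(self):
        wins = np.zeros((3, 3))
        wins[0, 1] = 1
        adi, ranks = average_dominance_index(wins)
        assert np.isnan(adi[2])
        assert ranks[2] == 3

    def test_single_fight_dyad(self):
        wins = np.zeros((2, 2))
        wins[0, 1] = 1
        adi, _ = average_dominance_index(wins)
        assert adi[0] == 1.0 and adi[1] == 0.0

    def test_invariant_to_duplicating_every_fight(self):
        rng = np.random.default_rng(3)
        wins = rng.integers(0, 5, (6, 6)).astype(float)
        np.fill_diagonal(wins, 0)
        a1, r1 = average_dominance_index(wins)
        a2, r2 = average_dominance_index(2 * wins)
        np.testing.assert_allclose(a1, a2)
        assert np.array_equal(r1, r2)


class TestKendallTauB:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_and_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 13).astype(float)  # ties likely
        y = rng.integers(0, 4, 13).astype(float)
        ours = kendall_tau_b(x, y)
        ref = stats.kendalltau(x, y).statistic
        if np.isnan(ref):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(ref)

    def test_constant_vector_is_undefined(self):
        assert np.isnan(kendall_tau_b([1, 1, 1], [1, 2, 3]))


class TestTauKr:
    def test_self_correlation_of_tie_free_matrix_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(196).reshape(14, 14).astype(float)
        assert taukr_statistic(x, x) == pytest.approx(1.0)

    def test_null_mean_is_near_zero(self):
        """Independent random matrices over 200 replicates: row-wise tau
        averages out to ~0."""
        rng = np.random.default_rng(1)
        stats_ = [taukr_statistic(rng.random((14, 14)), rng.random((14, 14)))
                  for _ in range(200)]
        assert abs(np.mean(stats_)) < 0.05

    def test_exhaustive_permutation_p_matches_brute_force_oracle(self):
        """4x4 matrices: the permutation p over all 4! = 24 relabelings of Y,
        computed with an independent scipy-based statistic, equals the exact
        p of our statistic computed the same way."""
        rng = np.random.default_rng(5)
        x = rng.random((4, 4))
        y = x + rng.normal(0, 0.3, (4, 4))

        def scipy_taukr(a, b):
            taus = []
            for i in range(4):
                mask = np.arange(4) != i
                t = stats.kendalltau(a[i, mask], b[i, mask]).statistic
                if np.isfinite(t):
                    taus.append(t)
            return np.mean(taus)

        for statistic in (taukr_statistic, scipy_taukr):
            obs = statistic(x, y)
            null = [statistic(x, y[np.ix_(p, p)])
                    for p in map(list, itertools.permutations(range(4)))]
            p_exact = np.mean([s >= obs for s in null])
            if statistic is taukr_statistic:
                ours = p_exact
            else:
                theirs = p_exact
        assert ours == pytest.approx(theirs)

    def test_permutation_p_detects_planted_association(self):
        rng = np.random.default_rng(2)
        x = rng.random((10, 10))
        res = taukr(x, x + rng.normal(0, 0.05, x.shape), n_perm=200,
                    rng=np.random.default_rng(3))
        assert res.statistic > 0.5
        assert res.p_value < 0.05

    def test_null_p_values_are_super_uniform(self):
        """P(p <= 0.05) stays at or below ~0.05 for independent matrices."""
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            x = rng.random((8, 8))
            y = rng.random((8, 8))
            hits += taukr(x, y, n_perm=99, rng=rng).p_value <= 0.05
        assert hits / n_rep <= 0.07

    def test_all_constant_rows_is_an_error(self):
        with pytest.raises(ValueError, match="TauKr undefined"):
            taukr_statistic(np.ones((4, 4)), np.eye(4))


class TestBuildMatrices:
    def test_single_groom_gives_single_count(self):
        log = manual_log([t % 6 for t in range(120)], app=60,
                         events={14: ("groom", 1)})  # actor 2 grooms 1
        mat = build_matrices(log, FEMALES, "groom_given")
        expected = np.zeros((4, 4))
        expected[2, 1] = 1
        np.testing.assert_array_equal(mat, expected)

    def test_empty_log_gives_zero_matrix(self):
        log = manual_log([t % 6 for t in range(120)], app=60)
        assert build_matrices(log, FEMALES, "groom_given").sum() == 0

    def test_unknown_stratum_rejected(self):
        log = manual_log([t % 6 for t in range(120)], app=60)
        with pytest.raises(ValueError, match="unknown stratum"):
            build_matrices(log, FEMALES, "groom_total")

    def test_pc_received_counts_only_bystander_grooms_in_windows(self):
        log = manual_log([t % 6 for t in range(120)], app=60, events={
            12: ("fight", 0, 1, 0),
            14: ("groom", 0),   # bystander 2 -> focal 0, inside PC window
            50: ("groom", 0),   # bystander 2 -> 0, outside any window
        })
        result = pcmc.analyze_log(log, FEMALES)
        mat = build_matrices(log, FEMALES, "pc_affil_received_by_role",
                             role="aggressor", result=result)
        expected = np.zeros((4, 4))
        expected[0, 2] = 1
        np.testing.assert_array_equal(mat, expected)

    def test_other_context_grooming_excludes_focal_window_grooms(self):
        log = manual_log([t % 6 for t in range(120)], app=60, events={
            12: ("fight", 0, 1, 0),
            14: ("groom", 0),   # inside focal 0's PC window: excluded
            50: ("groom", 0),   # outside: kept
        })
        result = pcmc.analyze_log(log, FEMALES)
        mat = build_matrices(log, FEMALES, "grooming_in_other_context",
                             result=result)
        assert mat[2, 0] == 1


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    def test_identical_samples_give_half_the_pairs(self):
        a = [1.0, 2.0, 3.0]
        u, _ = mann_whitney_u(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)

    def test_u_statistic_matches_brute_force_count(self):
        rng = np.random.default_rng(6)
        a, b = rng.random(9), rng.random(7)
        u, _ = mann_whitney_u(a, b)
        brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert u == pytest.approx(brute)

    def test_sum_over_both_orders_is_the_pair_count(self):
        rng = np.random.default_rng(7)
        a, b = rng.integers(0, 5, 12).astype(float), rng.integers(0, 5, 9).astype(float)
        u_ab, _ = mann_whitney_u(a, b)
        u_ba, _ = mann_whitney_u(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_exact_and_approximate_p_agree_for_small_samples(self):
        rng = np.random.default_rng(8)
        a, b = rng.random(8), rng.random(8)
        p_exact = stats.mannwhitneyu(a, b, method="exact").pvalue
        p_approx = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert abs(p_exact - p_approx) < 0.01

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_positive_differences_give_maximal_statistic(self):
        a = np.arange(1, 11, dtype=float)
        w, p = wilcoxon_matched(a + 1.0, a)
        assert w == 55.0
        assert p < 0.01

    def test_identical_samples_are_undefined(self):
        with pytest.raises(ValueError, match="all differences are zero"):
            wilcoxon_matched([1.0, 2.0], [1.0, 2.0])

    def test_single_smallest_negative_difference(self):
        # differences +5, +4, +3, +2, -1: positive ranks 5+4+3+2 = 14
        a = np.array([5.0, 4.0, 3.0, 2.0, 0.0])
        b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        w, _ = wilcoxon_matched(a, b)
        assert w == 14.0


class TestHochberg:
    def test_step_up_worked_example(self):
        rejected, report = hochberg_combine([0.01, 0.02, 0.30], alpha=0.05)
        assert list(rejected) == [True, True, False]
        assert report["n_rejected"] == 2

    def test_all_at_alpha_reject_everything(self):
        rejected, _ = hochberg_combine([0.05, 0.05, 0.05], alpha=0.05)
        assert all(rejected)

    def test_all_ones_reject_nothing(self):
        rejected, report = hochberg_combine([1.0, 1.0, 1.0])
        assert not any(rejected)
        assert report["combined_p"] == 1.0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            hochberg_combine([0.0, 0.5])

    @pytest.mark.parametrize("seed", range(4))
    def test_adjusted_p_matches_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(10)
        _, report = hochberg_combine(p)
        ref = multipletests(p, method="simes-hochberg")[1]
        np.testing.assert_allclose(report["adjusted_p"], ref)

    @pytest.mark.parametrize("seed", range(4))
    def test_rejects_a_superset_of_bonferroni(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = rng.random(8) * 0.2
        rejected, _ = hochberg_combine(p, alpha=0.05)
        bonferroni = p <= 0.05 / len(p)
        assert (rejected | ~bonferroni).all()


def test_wins_matrix_counts_winners_per_dyad():
    log = manual_log([t % 6 for t in range(120)], app=60, events={
        12: ("fight", 0, 1, 1),   # aggressor 0 loses
        18: ("fight", 0, 1, 0),   # aggressor 0 wins
    })
    wins = build_wins_matrix(log, 6)
    assert wins[0, 1] == 1 and wins[1, 0] == 1
    assert wins.sum() == 2
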