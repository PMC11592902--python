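"""Metric arithmetic and statistical tests against brute-force oracles."""

import itertools

import numpy as np
import pytest

from cytorl.metrics import (ConfusionMatrix, confusion_matrix, group_comparison,
                            macro_metrics, mcnemar, paired_comparison,
                            read_report, write_report)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_total_equals_sample_count(self):
        rng = np.random.default_rng(0)
        preds = rng.integers(0, 4, 57)
        labels = rng.integers(0, 4, 57)
        assert confusion_matrix(preds, labels, 4).total == 57

    def test_two_class_swap_moves_offdiagonal_mass(self):
        # enumerate by hand: labels (0,0,1,1), preds (0,1,0,1)
        cm = confusion_matrix([0, 1, 0, 1], [0, 0, 1, 1], 2)
        assert np.array_equal(cm.counts, [[1, 1], [1, 1]])
        cm_swapped = confusion_matrix([1, 0, 1, 0], [0, 0, 1, 1], 2)
        assert np.array_equal(cm_swapped.counts, cm.counts[:, ::-1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([0, 3], [0, 1], 3)


class TestMacroMetrics:
    def test_perfect_three_class_matrix_all_ones(self):
        rep = macro_metrics(ConfusionMatrix(np.diag([5, 3, 7])))
        for v in (rep.accuracy, rep.macro_precision, rep.macro_recall,
                  rep.macro_f1, rep.macro_specificity, rep.g_means):
            assert v == pytest.approx(1.0)

    def test_binary_recall_specificity_gmeans(self):
        """TP=9, FN=1, TN=90, FP=10 for the positive class: recall and
        specificity both 0.9, G-mean 0.9."""
        cm = ConfusionMatrix(np.array([[90, 10], [1, 9]]))
        rep = macro_metrics(cm)
        pc = rep.per_class
        assert pc.loc[1, "recall"] == pytest.approx(0.9)
        assert pc.loc[1, "specificity"] == pytest.approx(0.9)
        # symmetric counts here: macro recall = macro specificity = 0.9
        assert rep.g_means == pytest.approx(0.9)

    def test_hand_computed_macro_recall(self):
        cm = ConfusionMatrix(np.array([[5, 0, 0], [0, 5, 0], [5, 0, 0]]))
        rep = macro_metrics(cm)
        assert rep.macro_recall == pytest.approx((1 + 1 + 0) / 3)

    def test_zero_predicted_class_gets_zero_precision_and_flag(self):
        cm = ConfusionMatrix(np.array([[4, 0], [2, 0]]))
        rep = macro_metrics(cm)
        assert rep.per_class.loc[1, "precision"] == 0.0
        assert bool(rep.per_class.loc[1, "zero_predicted"])

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, (4, 4))
        rep = macro_metrics(ConfusionMatrix(counts))
        perm = rng.permutation(4)
        rep_p = macro_metrics(ConfusionMatrix(counts[np.ix_(perm, perm)]))
        for k in ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                  "macro_specificity", "g_means"):
            assert getattr(rep, k) == pytest.approx(getattr(rep_p, k))

    def test_gmeans_bounds_and_zero_condition(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.integers(0, 15, (3, 3))
            if counts.sum() == 0:
                continue
            rep = macro_metrics(ConfusionMatrix(counts))
            assert 0.0 <= rep.g_means <= min(1.0, np.sqrt(rep.macro_recall) + 1e-12)
            if rep.g_means == 0.0:
                assert rep.macro_recall == 0.0 or rep.macro_specificity == 0.0


class TestMcNemar:
    def test_symmetric_discordance_is_null(self):
        labels = np.zeros(8, int)
        a = np.array([0, 0, 0, 0, 1, 1, 0, 0])
        b = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        res = mcnemar(a, b, labels, exact_threshold=1)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chi_square_closed_form_b10_c2(self):
        labels = np.zeros(40, int)
        a = np.concatenate([np.zeros(10), np.ones(2), np.zeros(28)]).astype(int)
        b = np.concatenate([np.ones(10), np.zeros(2), np.zeros(28)]).astype(int)
        res = mcnemar(a, b, labels, exact_threshold=1)
        assert res.statistic == pytest.approx(64 / 12)

    def test_exact_binomial_b3_c0(self):
        """p = 2 * (1/2)^3 = 0.25 from the binomial tail."""
        labels = np.zeros(3, int)
        res = mcnemar(np.zeros(3, int), np.ones(3, int), labels)
        assert res.test_name == "mcnemar_exact"
        assert res.p_value == pytest.approx(0.25)

    def test_no_discordance_degenerate(self):
        labels = np.zeros(5, int)
        res = mcnemar(np.zeros(5, int), np.zeros(5, int), labels)
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert "degenerate" in res.note


def _wilcoxon_exact_p(diffs):
    """Enumerate all sign assignments of |d| ranks for the two-sided p."""
    d = np.asarray(diffs, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = ranks.sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        w_all.append(w)
    w_all = np.asarray(w_all)
    # two-sided: distance from the mean of the null distribution
    mu = total / 2
    p = np.mean(np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-12)
    return min(1.0, p)


class TestPairedComparison:
    def test_identical_samples_degenerate_p_one(self):
        res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert "zero" in res.note

    def test_constant_nonzero_difference_flagged(self):
        res = paired_comparison(np.arange(10) + 2.0, np.arange(10).astype(float))
        assert res.test_name == "paired_degenerate"
        assert "deterministic" in res.note

    def test_t_branch_ci_excludes_zero_for_clear_shift(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        res = paired_comparison(base + 2.0 + rng.normal(0, 0.1, 10), base,
                                method="t")
        assert res.conf_int is not None
        lo, hi = res.conf_int
        assert lo > 0.0
        assert res.significant

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        diffs = np.array([1.0, 2.0, 3.0, -1.5, 4.0, 5.0])
        a = diffs
        b = np.zeros(6)
        res = paired_comparison(a, b, method="wilcoxon")
        # statistic: scipy reports min(W+, W-); recompute from ranks
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
        w_plus = ranks[diffs > 0].sum()
        w_minus = ranks[diffs < 0].sum()
        assert res.statistic == pytest.approx(min(w_plus, w_minus))
        assert res.p_value == pytest.approx(_wilcoxon_exact_p(diffs))


class TestGroupComparison:
    def test_identical_groups_f_zero(self):
        g = [1.0, 2.0, 3.0]
        res = group_comparison([g, g, g])
        assert res.statistic == pytest.approx(0.0)

    def test_two_group_anova_equals_squared_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        res = group_comparison([a, b], method="anova")
        from scipy import stats
        t, _ = stats.ttest_ind(a, b)
        assert res.test_name == "anova"
        assert res.statistic == pytest.approx(t * t)

    def test_kruskal_wallis_hand_ranked(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: rank sums 6,15,24 give
        H = 12/90 * (36+225+576)/3 - 30 = 7.2."""
        res = group_comparison([[1, 2, 3], [4, 5, 6], [7, 8, 9]],
                               method="kruskal")
        assert res.test_name == "kruskal_wallis"
        assert res.statistic == pytest.approx(7.2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_comparison([[1.0, 2.0, 3.0], []])


class TestReportIO:
    def test_round_trip(self, tmp_path):
        rep = macro_metrics(ConfusionMatrix(np.array([[8, 2], [1, 9]])))
        tests = [mcnemar(np.zeros(5, int), np.ones(5, int), np.zeros(5, int))]
        json_path, csv_path = write_report(rep, tests, tmp_path / "report.json")
        back = read_report(json_path)
        assert back["metrics"]["accuracy"] == pytest.approx(rep.accuracy)
        assert back["tests"][0]["test_name"] == tests[0].test_name
        import pandas as pd
        per_class = pd.read_csv(csv_path)
        assert len(per_class) == 2
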