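"""Metric definitions pinned to published fractions, plus oracle equivalences."""

import numpy as np
import pandas as pd
import pytest

from ftirnet.exceptions import DataError, NumericError
from ftirnet.metrics import (
    ConfusionMatrix,
    anova_from_summary,
    chi_square_contingency,
    cohort_table,
    confusion_matrix,
    macro_average,
    macro_report,
    per_class_accuracy,
    roc_auc_ovr,
)


def random_cm(rng, k=4, balanced=False, n_per_class=25):
    counts = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        n = n_per_class if balanced else int(rng.integers(5, 40))
        counts[i] = rng.multinomial(n, rng.dirichlet(np.ones(k)))
    return ConfusionMatrix(counts, tuple("ABCD"[:k]))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        labels = ["AS", "RA", "OA", "HC"] * 2
        cm = confusion_matrix(labels, labels, ["AS", "RA", "OA", "HC"])
        assert np.trace(cm.counts) == 8
        assert cm.counts.sum() - np.trace(cm.counts) == 0

    def test_degenerate_predictor_single_column(self):
        cm = confusion_matrix(["A", "B", "A", "B"], ["B"] * 4, ["A", "B"])
        assert (cm.counts[:, 0] == 0).all() and cm.counts[:, 1].sum() == 4

    def test_hand_counted_two_class(self):
        cm = confusion_matrix(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError):
            confusion_matrix(["A", "X"], ["A", "A"], ["A", "B"])


class TestPerClassAccuracy:
    def test_diagonal_gives_ones(self):
        cm = ConfusionMatrix(np.diag([3, 5, 7, 9]), tuple("ABCD"))
        np.testing.assert_array_equal(per_class_accuracy(cm), 1.0)

    def test_published_fraction_19_of_27(self):
        counts = np.zeros((4, 4), dtype=np.int64)
        counts[0, 0], counts[0, 1] = 19, 8  # 19 correct of 27
        counts[1, 1] = counts[2, 2] = counts[3, 3] = 1
        cm = ConfusionMatrix(counts, tuple("ABCD"))
        assert round(per_class_accuracy(cm)[0], 4) == 0.7037

    def test_hand_counted(self):
        cm = ConfusionMatrix(np.array([[1, 1], [0, 1]]), ("A", "B"))
        np.testing.assert_allclose(per_class_accuracy(cm), [0.5, 1.0])

    def test_empty_row_rejected(self):
        cm = ConfusionMatrix(np.array([[2, 0], [0, 0]]), ("A", "B"))
        with pytest.raises(DataError, match="B"):
            per_class_accuracy(cm)


class TestMacroAverage:
    def test_singleton(self):
        assert macro_average([0.7]) == 0.7

    def test_published_per_class_rows(self):
        # plain CNN row of the published comparison table
        assert round(macro_average([0.7037, 0.7059, 0.9615, 0.8846]), 4) == 0.8139
        # multi-scale CNN row, from the exact test-count fractions
        assert round(macro_average([23 / 27, 15 / 17, 22 / 26, 23 / 26]), 4) == 0.8662

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            macro_average([])


class TestMacroReport:
    def test_sensitivity_is_mean_recall_published_row(self):
        # the best model's printed per-class accuracies average to its
        # printed overall sensitivity, pinning sensitivity = macro recall
        vals = [0.8889, 0.7647, 0.8846, 0.9615]
        assert round(macro_average(vals), 4) == 0.8749

    def test_all_scalars_one_for_diagonal(self):
        cm = ConfusionMatrix(np.diag([5, 5, 5, 5]), tuple("ABCD"))
        r = macro_report(cm)
        assert (r.accuracy, r.sensitivity, r.precision, r.specificity) == (1, 1, 1, 1)

    def test_balanced_specificity_identity(self):
        # 4 equal-size classes: macro specificity == 1 - (1 - accuracy) / 3
        rng = np.random.default_rng(0)
        for _ in range(20):
            cm = random_cm(rng, balanced=True)
            r = macro_report(cm)
            assert abs(r.specificity - (1 - (1 - r.accuracy) / 3)) < 1e-12

    def test_accuracy_recovered_from_weighted_recalls(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cm = random_cm(rng)
            rec = per_class_accuracy(cm)
            weights = cm.counts.sum(axis=1)
            assert abs((rec * weights).sum() / weights.sum() - cm.accuracy()) < 1e-12

    def test_sensitivity_equals_mean_per_class_accuracy(self):
        rng = np.random.default_rng(2)
        cm = random_cm(rng)
        r = macro_report(cm)
        assert r.sensitivity == macro_average(per_class_accuracy(cm))

    def test_never_predicted_class_contributes_zero_precision(self, caplog):
        counts = np.array([[2, 0], [2, 0]])
        r = macro_report(ConfusionMatrix(counts, ("A", "B")))
        assert r.precision == pytest.approx(0.25)  # (2/4 + 0) / 2


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        y = ["A", "A", "B", "B", "C", "C"]
        scores = np.eye(3)[[0, 0, 1, 1, 2, 2]] + 0.0
        out = roc_auc_ovr(scores, y, ["A", "B", "C"])
        assert out["macro"] == 1.0

    def test_constant_scores_give_chance(self):
        y = ["A", "B"] * 5
        scores = np.full((10, 2), 0.5)
        out = roc_auc_ovr(scores, y, ["A", "B"])
        assert out["per_class"] == {"A": 0.5, "B": 0.5}

    @staticmethod
    def concordance_auc(scores, positives):
        """Brute-force pairwise concordance with ties counted 0.5."""
        pos = scores[positives]
        neg = scores[~positives]
        total = 0.0
        for p in pos:
            for n in neg:
                total += 1.0 if p > n else (0.5 if p == n else 0.0)
        return total / (len(pos) * len(neg))

    def test_trapezoidal_equals_concordance_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(6, 16))
            k = 3
            scores = np.round(rng.random((n, k)), 1)  # coarse grid forces ties
            y = [str(c) for c in rng.integers(0, k, size=n)]
            while len(set(y)) < k:
                y = [str(c) for c in rng.integers(0, k, size=n)]
            out = roc_auc_ovr(scores, y, [str(c) for c in range(k)])
            for c, auc in out["per_class"].items():
                pos = np.array([t == c for t in y])
                assert abs(auc - self.concordance_auc(scores[:, int(c)], pos)) < 1e-12

    def test_single_class_labels_rejected(self):
        with pytest.raises(NumericError):
            roc_auc_ovr(np.ones((3, 2)), ["A", "A", "A"], ["A", "B"])


class TestChiSquare:
    def test_published_gender_table(self):
        stat, dof, p = chi_square_contingency(
            [[32, 48], [38, 42], [43, 37], [42, 38]]
        )
        assert round(stat, 3) == 3.741
        assert dof == 3
        assert round(p, 3) == 0.291

    def test_homogeneous_table(self):
        stat, dof, p = chi_square_contingency([[10, 10], [10, 10]])
        assert stat == 0 and p == 1

    def test_perfect_association(self):
        stat, _, _ = chi_square_contingency([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)  # expected all 5; sum (+-5)^2/5

    def test_row_permutation_invariance(self):
        t = [[12, 7], [5, 19], [8, 8]]
        a = chi_square_contingency(t)[0]
        b = chi_square_contingency([t[2], t[0], t[1]])[0]
        assert a == pytest.approx(b)

    def test_linear_scaling_under_count_multiplication(self):
        t = np.array([[12, 7], [5, 19]])
        a = chi_square_contingency(t)[0]
        b = chi_square_contingency(3 * t)[0]
        assert b == pytest.approx(3 * a)

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError):
            chi_square_contingency([[0, 0], [3, 4]])


class TestAnovaFromSummary:
    def test_equal_means_give_zero_F(self):
        F, _, p = anova_from_summary([5, 5, 5], [1, 2, 1], [10, 10, 10])
        assert F == 0 and p == 1

    def test_two_groups_F_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1.3, 17)
        from scipy import stats

        t, _ = stats.ttest_ind(a, b, equal_var=True)
        F, dfs, _ = anova_from_summary(
            [a.mean(), b.mean()], [a.std(ddof=1), b.std(ddof=1)], [12, 17]
        )
        assert F == pytest.approx(t**2, rel=1e-10)
        assert dfs == (1, 27)

    def test_published_cohort_age_row_evaluates_via_formula(self):
        # direct evaluation of the summary-statistic formula on the printed
        # rounded means/SDs; frozen from an independent hand computation
        # (grand mean 40.4; SSB = 80 * 2.96; MSW = mean of variances)
        F, dfs, p = anova_from_summary(
            [39.4, 39.8, 41.6, 40.8], [8.2, 5.9, 3.2, 5.2], [80, 80, 80, 80]
        )
        msb = 80 * (1.0 + 0.36 + 1.44 + 0.16) / 3
        msw = (8.2**2 + 5.9**2 + 3.2**2 + 5.2**2) / 4
        assert F == pytest.approx(msb / msw, rel=1e-12)
        assert dfs == (3, 316)

    def test_zero_variance_rejected(self):
        with pytest.raises(NumericError):
            anova_from_summary([1, 2], [0, 0], [5, 5])


class TestCohortTable:
    def test_summary_from_subject_level_table(self):
        rng = np.random.default_rng(0)
        rows = []
        for g, n_f, n_m in [("AS", 3, 5), ("HC", 4, 4)]:
            for i in range(n_f + n_m):
                rows.append({"group": g, "age": float(40 + rng.integers(-5, 6)),
                             "sex": "F" if i < n_f else "M"})
        out = cohort_table(pd.DataFrame(rows))
        assert out["groups"]["AS"]["female"] == 3
        assert out["groups"]["HC"]["n"] == 8
        assert out["gender_chi2"]["dof"] == 1
        assert 0 <= out["age_anova"]["p_value"] <= 1
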