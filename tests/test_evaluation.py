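"""Fold arithmetic, confusion metrics vs brute force, ROC/PRC, CV reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorkit import (
    ConfusionCounts,
    DataError,
    compute_metrics,
    confusion,
    cross_validate,
    roc_pr_curves,
    stratified_kfold,
)
from tremorkit.evaluation import mean_roc_curve


class TestStratifiedKFold:
    def test_clinical_scale_fold_arithmetic(self):
        y = np.r_[np.ones(728, int), np.zeros(1544, int)]  # 2272 records
        assignment = stratified_kfold(y, k=5, seed=0)
        for fold in range(5):
            n_test = (assignment == fold).sum()
            assert n_test in (454, 455)
            assert len(y) - n_test in (1817, 1818)

    def test_stratification_within_one_record(self):
        rng = np.random.default_rng(1)
        y = (rng.random(500) < 0.32).astype(int)
        assignment = stratified_kfold(y, k=5, seed=3)
        global_prop = y.mean()
        for fold in range(5):
            test = assignment == fold
            assert abs(y[test].mean() - global_prop) <= 1.0 / test.sum()

    def test_ten_records_five_positive(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        assignment = stratified_kfold(y, k=5, seed=0)
        for fold in range(5):
            test = assignment == fold
            assert test.sum() == 2
            assert y[test].sum() == 1

    def test_partition_property(self):
        y = (np.random.default_rng(2).random(97) < 0.4).astype(int)
        assignment = stratified_kfold(y, k=5, seed=1)
        assert set(assignment) == set(range(5))
        assert assignment.shape == y.shape

    def test_deterministic_given_seed(self):
        y = (np.random.default_rng(3).random(60) < 0.5).astype(int)
        np.testing.assert_array_equal(
            stratified_kfold(y, seed=7), stratified_kfold(y, seed=7)
        )

    def test_too_few_positives_raise(self):
        y = np.r_[np.ones(3, int), np.zeros(50, int)]
        with pytest.raises(DataError):
            stratified_kfold(y, k=5)


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.TP, c.FP, c.TN, c.FN) == (2, 0, 2, 0)

    def test_all_predicted_absent(self):
        yt = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        c = confusion(yt, [0] * 10)
        assert (c.TP, c.FN, c.TN, c.FP) == (0, 3, 7, 0)

    def test_string_labels_accepted(self):
        c = confusion(["present", "absent"], ["absent", "absent"])
        assert (c.TP, c.FN, c.TN, c.FP) == (0, 1, 1, 0)

    def test_length_mismatch_raises(self):
        with pytest.raises(DataError):
            confusion([1, 0], [1])

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=60))
    def test_matches_per_record_loop(self, pairs):
        yt = [a for a, _ in pairs]
        yp = [b for _, b in pairs]
        tp = fp = tn = fn = 0
        for a, b in pairs:  # brute-force per-record counting
            if a == 1 and b == 1:
                tp += 1
            elif a == 0 and b == 1:
                fp += 1
            elif a == 0 and b == 0:
                tn += 1
            else:
                fn += 1
        c = confusion(yt, yp)
        assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)
        assert c.total == len(pairs)


class TestMetrics:
    def test_perfect_counts_give_all_ones(self):
        m = compute_metrics(ConfusionCounts(TP=10, FP=0, TN=10, FN=0))
        assert all(getattr(m, k) == 1.0 for k in ("accuracy", "precision", "recall", "specificity", "f1"))

    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(TP=8, FP=2, TN=88, FN=2))
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.96)
        assert m.specificity == pytest.approx(88 / 90)

    def test_zero_over_zero_convention(self):
        m = compute_metrics(ConfusionCounts(TP=0, FP=0, TN=0, FN=5))
        assert m.precision == 0.0
        assert m.recall == 0.0
        assert m.f1 == 0.0

    def test_printed_specificity_variant(self):
        c = ConfusionCounts(TP=5, FP=3, TN=10, FN=2)
        assert compute_metrics(c).specificity == pytest.approx(10 / 13)
        assert compute_metrics(c, specificity_as_printed=True).specificity == pytest.approx(10 / 12)

    def test_empty_counts_raise(self):
        with pytest.raises(DataError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_f1_between_precision_and_recall(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert 0.0 <= m.f1 <= 1.0
        if m.precision > 0 and m.recall > 0:
            assert min(m.precision, m.recall) - 1e-12 <= m.f1 <= max(m.precision, m.recall) + 1e-12


class TestRocPrc:
    def test_perfect_separation(self):
        cs = roc_pr_curves([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert cs.auroc == pytest.approx(1.0)
        assert cs.auprc == pytest.approx(1.0)

    def test_constant_scores_are_chance(self):
        cs = roc_pr_curves([0.5] * 10, [0, 1] * 5)
        assert cs.auroc == pytest.approx(0.5)

    def test_single_class_truth_raises(self):
        with pytest.raises(DataError):
            roc_pr_curves([0.1, 0.9], [1, 1])

    def test_auroc_equals_exhaustive_concordance(self, rng):
        for _ in range(5):
            n = int(rng.integers(20, 200))
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # coarse scores force ties
            conc = 0.0
            n_pairs = 0
            for i in np.flatnonzero(y == 1):
                for j in np.flatnonzero(y == 0):
                    n_pairs += 1
                    if s[i] > s[j]:
                        conc += 1.0
                    elif s[i] == s[j]:
                        conc += 0.5
            assert roc_pr_curves(s, y).auroc == pytest.approx(conc / n_pairs)

    def test_mean_roc_curve_grid(self):
        curves = [roc_pr_curves([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1]) for _ in range(3)]
        grid, mean_tpr, sd = mean_roc_curve(curves)
        assert grid.shape == mean_tpr.shape == sd.shape == (101,)
        assert mean_tpr[0] <= mean_tpr[-1]


class TestCrossValidate:
    def test_report_structure_and_fold_sizes(self, small_dataset):
        res = cross_validate("a2r", small_dataset.records, small_dataset.labels, k=5, seed=2)
        assert len(res.folds) == 5
        assert res.curves == []  # rule pipelines have no operating range
        sizes = [f.counts.total for f in res.folds]
        assert sum(sizes) == len(small_dataset)
        assert max(sizes) - min(sizes) <= 1

    def test_mean_equals_mean_of_folds(self, small_dataset):
        res = cross_validate("a2r", small_dataset.records, small_dataset.labels, k=5, seed=2)
        assert res.mean["f1"] == pytest.approx(np.mean([f.f1 for f in res.folds]))
        assert res.sd["accuracy"] == pytest.approx(
            np.std([f.accuracy for f in res.folds], ddof=1)
        )

    def test_trainable_spectral_pipeline_emits_curves(self, small_dataset):
        res = cross_validate("b2", small_dataset.records, small_dataset.labels, k=5, seed=2)
        assert len(res.curves) == 5
        assert all(f.auroc is not None and f.auprc is not None for f in res.folds)
        assert "auroc" in res.mean

    def test_deterministic_given_seed(self, small_dataset):
        r1 = cross_validate("b2", small_dataset.records, small_dataset.labels, k=5, seed=4)
        r2 = cross_validate("b2", small_dataset.records, small_dataset.labels, k=5, seed=4)
        assert r1.mean == r2.mean
        assert [f.as_dict() for f in r1.folds] == [f.as_dict() for f in r2.folds]

    def test_curves_can_be_forced_on_reference_pipelines(self, small_dataset):
        res = cross_validate(
            "a2r", small_dataset.records, small_dataset.labels, k=5, seed=2, emit_curves=True
        )
        assert len(res.curves) == 5
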