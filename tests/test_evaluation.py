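import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfbs import (
    FeatureTable,
    confusion_metrics,
    cross_validate,
    f1_from_precision_recall,
    fold_variance,
    overfit_diff,
    roc_auc,
    stratified_kfold,
)
from pfbs.errors import DataError, StratificationError
from sklearn.linear_model import LogisticRegression


def pair_count_auc(y, scores):
    """Concordant-pair oracle: AUC = P(score_pos > score_neg) + 0.5 ties."""
    pos = [s for s, v in zip(scores, y) if v == 1]
    neg = [s for s, v in zip(scores, y) if v == 0]
    total = len(pos) * len(neg)
    conc = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return conc / total


class TestStratifiedKfold:
    def test_balanced_binary_each_fold_one_per_class(self):
        labels = ["a", "b"] * 10
        plan = stratified_kfold(labels, k=10, seed=0)
        for fold in range(10):
            in_fold = [labels[i] for i in np.flatnonzero(plan.assignments == fold)]
            assert sorted(in_fold) == ["a", "b"]

    def test_partition_property(self):
        labels = ["a"] * 30 + ["b"] * 20 + ["c"] * 10
        plan = stratified_kfold(labels, k=5, seed=1)
        assert plan.assignments.shape == (60,)
        assert set(plan.assignments) == set(range(5))

    def test_exact_per_fold_class_counts(self):
        labels = ["a"] * 30 + ["b"] * 20 + ["c"] * 10
        plan = stratified_kfold(labels, k=5, seed=2)
        for fold in range(5):
            idx = np.flatnonzero(plan.assignments == fold)
            counts = {c: sum(labels[i] == c for i in idx) for c in "abc"}
            assert counts == {"a": 6, "b": 4, "c": 2}

    def test_small_class_raises_naming_it(self):
        labels = ["a"] * 20 + ["rare"] * 3
        with pytest.raises(StratificationError, match="rare"):
            stratified_kfold(labels, k=5, seed=0)

    def test_random_label_vectors_satisfy_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            n_classes = int(rng.integers(2, 4))
            counts = rng.integers(k, 4 * k, size=n_classes)
            labels = np.repeat([f"c{j}" for j in range(n_classes)], counts)
            rng.shuffle(labels)
            plan = stratified_kfold(labels, k=k, seed=int(rng.integers(1 << 30)))
            sizes = np.bincount(plan.assignments, minlength=k)
            assert sizes.max() - sizes.min() <= 1
            for j in range(n_classes):
                per_fold = np.bincount(
                    plan.assignments[labels == f"c{j}"], minlength=k
                )
                # each fold's class count within 1 of the proportional share
                assert per_fold.max() - per_fold.min() <= 1


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        assert confusion_metrics(["a", "b"], ["a", "b"]) == (1.0, 1.0, 1.0, 1.0)

    def test_binary_counts_match_direct_substitution(self):
        # TP=2, FP=1, FN=1, TN=6 with positive class "1"
        y_true = ["1"] * 3 + ["0"] * 7
        y_pred = ["1", "1", "0", "1"] + ["0"] * 6
        p, r, f1, acc = confusion_metrics(y_true, y_pred)
        assert p == pytest.approx(2 / 3)
        assert r == pytest.approx(2 / 3)
        assert f1 == pytest.approx(2 / 3)
        assert acc == pytest.approx(0.8)

    def test_random_confusion_tables_match_formulas(self):
        """Binary metrics equal direct TP/FP/FN/TN substitution."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, fn, tn = rng.integers(0, 20, size=4)
            if tp + fp + fn + tn == 0 or (tp + fn == 0 and fp == 0) \
               or (tn + fp == 0 and fn == 0):
                continue
            y_true = ["1"] * (tp + fn) + ["0"] * (fp + tn)
            y_pred = (["1"] * tp + ["0"] * fn + ["1"] * fp + ["0"] * tn)
            if len(set(y_true) | set(y_pred)) < 2:
                continue
            p, r, f1, acc = confusion_metrics(y_true, y_pred)
            p_exp = tp / (tp + fp) if tp + fp else 0.0
            r_exp = tp / (tp + fn) if tp + fn else 0.0
            f1_exp = 2 * p_exp * r_exp / (p_exp + r_exp) if p_exp + r_exp else 0.0
            assert p == pytest.approx(p_exp)
            assert r == pytest.approx(r_exp)
            assert f1 == pytest.approx(f1_exp)
            assert acc == pytest.approx((tp + tn) / (tp + fp + fn + tn))

    def test_macro_reduces_to_per_class_mean(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "b", "b", "b", "c", "a"]
        p, r, f1, acc = confusion_metrics(y_true, y_pred)
        # per-class one-vs-rest precision: a=1/2, b=2/3, c=1/1
        assert p == pytest.approx((1 / 2 + 2 / 3 + 1) / 3)
        # per-class recall: a=1/2, b=2/2, c=1/2
        assert r == pytest.approx((1 / 2 + 1 + 1 / 2) / 3)
        assert f1 == pytest.approx(f1_from_precision_recall(p, r))
        assert acc == pytest.approx(4 / 6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            confusion_metrics(["a"], ["a", "b"])

    def test_printed_precision_recall_f1_identity(self):
        assert round(f1_from_precision_recall(0.999, 0.998), 3) == 0.998

    @settings(max_examples=200, derandomize=True)
    @given(p=st.floats(0, 1), r=st.floats(0, 1))
    def test_f1_harmonic_identity(self, p, r):
        f1 = f1_from_precision_recall(p, r)
        assert 0.0 <= f1 <= 1.0
        if p + r > 0:
            assert f1 == pytest.approx(2 * p * r / (p + r))
        else:
            assert f1 == 0.0


class TestOverfitDiffAndVariance:
    @pytest.mark.parametrize("train, test, expected", [
        (100.0, 99.8, pytest.approx(0.2)),
        (50.0, 50.0, 0.0),
        (90.0, 95.0, -5.0),
    ])
    def test_overfit_diff(self, train, test, expected):
        assert overfit_diff(train, test) == expected

    @pytest.mark.parametrize("accs, expected", [
        ([0.7, 0.7, 0.7], 0.0),
        ([1.0, 0.0], 0.25),
        ([0.9, 1.0, 0.95, 0.95], pytest.approx(0.00125)),
    ])
    def test_population_variance(self, accs, expected):
        assert fold_variance(accs) == expected


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_textbook_binary_example(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_exhaustive_small_n(self):
        """Trapezoidal AUC equals the concordant-pair count on small inputs."""
        rng = np.random.default_rng(3)
        for n in range(2, 13):
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                scores = rng.integers(0, 4, size=n) / 4.0  # ties likely
                assert roc_auc(list(labels), scores) == pytest.approx(
                    pair_count_auc(labels, scores)
                )

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=2000)
        scores = rng.random(2000)
        assert roc_auc(y, scores) == pytest.approx(0.5, abs=0.03)

    def test_single_class_returns_nan(self):
        assert np.isnan(roc_auc([1, 1, 1], [0.1, 0.2, 0.3]))

    def test_multiclass_macro_one_vs_rest(self):
        y = ["a", "b", "c"]
        scores = np.eye(3)
        assert roc_auc(y, scores) == 1.0


class TestCrossValidate:
    def make_table(self, n=40, seed=0, separable=True):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        x = y.astype(float) if separable else rng.normal(size=n)
        values = np.column_stack([x, rng.normal(size=n)])
        return FeatureTable(values=values, feature_names=("a", "b"),
                            labels=tuple(str(v) for v in y),
                            sample_ids=tuple(f"s{i}" for i in range(n)))

    def classifier(self):
        return lambda: LogisticRegression(max_iter=200)

    def test_separable_table_is_perfect(self):
        t = self.make_table()
        plan = stratified_kfold(t.labels, k=5, seed=0)
        m = cross_validate(t, self.classifier(), plan)
        assert m.test_accuracy == 100.0
        assert m.variance == 0.0
        assert m.overfit_diff == 0.0
        assert m.auc == 1.0

    def test_deterministic(self):
        t = self.make_table(seed=2, separable=False)
        plan = stratified_kfold(t.labels, k=4, seed=1)
        a = cross_validate(t, self.classifier(), plan)
        b = cross_validate(t, self.classifier(), plan)
        assert a.as_dict(include_timings=False) == b.as_dict(include_timings=False)

    def test_null_data_near_majority_rate(self):
        accs = []
        for seed in range(10):
            t = self.make_table(n=60, seed=seed, separable=False)
            plan = stratified_kfold(t.labels, k=5, seed=seed)
            accs.append(cross_validate(t, self.classifier(), plan).test_accuracy)
        assert np.mean(accs) == pytest.approx(50.0, abs=5.0)

    def test_plan_must_cover_rows(self):
        t = self.make_table()
        plan = stratified_kfold(t.labels[:20], k=2, seed=0)
        with pytest.raises(DataError):
            cross_validate(t, self.classifier(), plan)
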