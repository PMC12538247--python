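import numpy as np
import pytest

from eegaffect import evaluation
from eegaffect.errors import ValidationError


def brute_force_metrics(y_true, y_pred):
    """Independent oracle: count pairs one by one, apply the formulas literally."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    acc = (tp + tn) / (tp + tn + fp + fn)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


class TestConfusion:
    def test_hand_counted_example(self):
        cm = evaluation.confusion([1, 0, 1, 1], [1, 0, 0, 1])
        assert (cm.tp, cm.tn, cm.fn, cm.fp) == (2, 1, 1, 0)
        assert cm.total == 4

    def test_perfect_and_inverted_predictions(self):
        y = [1, 0, 1, 0, 1]
        perfect = evaluation.confusion(y, y)
        assert perfect.fp == perfect.fn == 0
        inverted = evaluation.confusion(y, [1 - v for v in y])
        assert inverted.tp == inverted.tn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            evaluation.confusion([1, 0], [1])

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValidationError):
            evaluation.confusion([1, 2], [1, 0])

    def test_table_layout(self):
        table = evaluation.ConfusionMatrix(tp=3, fp=1, tn=4, fn=2).as_table()
        assert table.loc["positive", "positive"] == 3
        assert table.loc["negative", "positive"] == 1
        assert table.loc["positive", "negative"] == 2


class TestScalarMetrics:
    def test_formula_arithmetic(self):
        cm = evaluation.ConfusionMatrix(tp=3, tn=2, fp=1, fn=0)
        assert evaluation.accuracy(cm) == pytest.approx(5 / 6)
        assert evaluation.precision(cm) == pytest.approx(0.75)
        assert evaluation.recall(cm) == pytest.approx(1.0)

    def test_hand_arithmetic_f1(self):
        cm = evaluation.ConfusionMatrix(tp=9, fp=1, fn=3, tn=0)
        assert evaluation.precision(cm) == pytest.approx(0.9)
        assert evaluation.recall(cm) == pytest.approx(0.75)
        assert evaluation.f1(cm) == pytest.approx(2 * 0.675 / 1.65)

    def test_degenerate_counts_return_zero(self, caplog):
        cm = evaluation.ConfusionMatrix(tp=0, fp=0, tn=3, fn=2)
        with caplog.at_level("WARNING"):
            assert evaluation.precision(cm) == 0.0
        assert "precision" in caplog.text
        assert evaluation.f1(cm) == 0.0

    def test_exact_match_with_brute_force_oracle(self):
        """All four metrics equal literal counting on 500 random vectors."""
        rng = np.random.default_rng(123)
        for _ in range(500):
            n = int(rng.integers(1, 60))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            oracle = brute_force_metrics(y_true, y_pred)
            cm = evaluation.confusion(y_true, y_pred)
            assert (cm.tp, cm.fp, cm.tn, cm.fn) == (
                oracle["tp"], oracle["fp"], oracle["tn"], oracle["fn"])
            got = evaluation.metrics_record(cm)
            for name in evaluation.METRIC_NAMES:
                assert got[name] == oracle[name], name

    def test_agreement_with_sklearn(self):
        from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                                     recall_score)

        rng = np.random.default_rng(5)
        for _ in range(50):
            y_true = rng.integers(0, 2, 40)
            y_pred = rng.integers(0, 2, 40)
            cm = evaluation.confusion(y_true, y_pred)
            assert evaluation.accuracy(cm) == pytest.approx(accuracy_score(y_true, y_pred))
            assert evaluation.precision(cm) == pytest.approx(
                precision_score(y_true, y_pred, zero_division=0))
            assert evaluation.recall(cm) == pytest.approx(
                recall_score(y_true, y_pred, zero_division=0))
            assert evaluation.f1(cm) == pytest.approx(
                f1_score(y_true, y_pred, zero_division=0))

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            y_true = rng.integers(0, 2, 30)
            y_pred = rng.integers(0, 2, 30)
            cm = evaluation.confusion(y_true, y_pred)
            p, r = evaluation.precision(cm), evaluation.recall(cm)
            if p > 0 and r > 0:
                assert min(p, r) <= evaluation.f1(cm) <= max(p, r)


class TestMacroMetrics:
    def test_ternary_accuracy_is_hit_rate(self):
        y_true = [-1, 0, 1, 1, -1, 0]
        y_pred = [-1, 0, 0, 1, 1, 0]
        out = evaluation.macro_metrics(y_true, y_pred, classes=(-1, 0, 1))
        assert out["accuracy"] == pytest.approx(4 / 6)
        assert 0.0 <= out["f1"] <= 1.0


class TestRoc:
    def test_hand_enumerated_curve(self):
        """Four scores, two classes: sweep thresholds by hand."""
        points = evaluation.roc_curve([1, 1, 0, 0], [0.9, 0.8, 0.4, 0.2])
        coords = [(p.fpr, p.tpr) for p in points]
        assert coords == [(0, 0), (0, 0.5), (0, 1), (0.5, 1), (1, 1)]
        assert evaluation.auc(points) == pytest.approx(1.0)

    def test_perfect_separation_hits_corner(self):
        points = evaluation.roc_curve([0, 1, 1, 0], [0.1, 0.8, 0.9, 0.2])
        assert (0.0, 1.0) in [(p.fpr, p.tpr) for p in points]

    def test_all_scores_equal_is_diagonal(self):
        points = evaluation.roc_curve([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert [(p.fpr, p.tpr) for p in points] == [(0, 0), (1, 1)]
        assert evaluation.auc(points) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            evaluation.roc_curve([1, 1, 1], [0.2, 0.5, 0.9])

    def test_monotone_with_correct_endpoints(self):
        """Random score vectors: curve runs (0,0) -> (1,1), never decreasing."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.random(n), 2)  # duplicates exercise tie grouping
            pts = evaluation.roc_curve(y, scores)
            assert (pts[0].fpr, pts[0].tpr) == (0.0, 0.0)
            assert (pts[-1].fpr, pts[-1].tpr) == (1.0, 1.0)
            fprs = [p.fpr for p in pts]
            tprs = [p.tpr for p in pts]
            assert fprs == sorted(fprs)
            assert tprs == sorted(tprs)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = rng.random(30)
            pts = evaluation.roc_curve(y, scores)
            assert evaluation.auc(pts) == pytest.approx(roc_auc_score(y, scores))


class TestCrossValidation:
    def test_kfold_partition_properties(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            k = int(rng.integers(2, min(n, 8) + 1))
            folds = evaluation.kfold_indices(n, k, seed=int(rng.integers(100)))
            flat = np.concatenate(folds)
            assert len(flat) == n
            assert set(flat.tolist()) == set(range(n))
            assert max(map(len, folds)) - min(map(len, folds)) <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            evaluation.kfold_indices(3, 5)

    def test_stub_fold_metrics_mean_and_sample_std(self):
        """Hand computation: mean 0.944, std with the (k-1) denominator."""
        fold_accs = [0.94, 0.95, 0.94, 0.95, 0.94]
        it = iter(fold_accs)
        report = evaluation.cross_validate(
            list(range(10)), 5,
            lambda train, test: {"valence": {"accuracy": next(it)}})
        row = report.summary().iloc[0]
        assert row["mean"] == pytest.approx(np.mean(fold_accs))
        assert row["std"] == pytest.approx(np.std(fold_accs, ddof=1))
        assert row["std"] == pytest.approx(0.00548, abs=1e-4)

    def test_identical_folds_zero_std(self):
        report = evaluation.cross_validate(
            list(range(8)), 4, lambda tr, te: {"v": {"accuracy": 0.9}})
        assert report.summary()["std"].iloc[0] == 0.0

    def test_leave_one_out_fold_sizes(self):
        sizes = []
        report = evaluation.cross_validate(
            list(range(6)), 6,
            lambda tr, te: (sizes.append((len(tr), len(te))),
                            {"v": {"accuracy": 1.0}})[1])
        assert sizes == [(5, 1)] * 6
        assert report.k == 6

    def test_each_unit_in_exactly_one_test_fold(self):
        seen: list[int] = []
        evaluation.cross_validate(
            list(range(17)), 5,
            lambda tr, te: (seen.extend(te), {"v": {"accuracy": 0.5}})[1])
        assert sorted(seen) == list(range(17))

    def test_formatted_report_shape(self):
        report = evaluation.cross_validate(
            list(range(10)), 5,
            lambda tr, te: {"arousal": {"accuracy": 0.9, "f1": 0.8}})
        wide = report.formatted()
        assert "arousal" in wide.columns
        assert "±" in wide.loc["accuracy", "arousal"]
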