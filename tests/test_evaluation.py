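import itertools

import numpy as np
import pytest

import cenkd as ck
from cenkd.evaluation import (
    MetricsReport,
    confusion,
    f1_score,
    overall_metrics,
    per_class_metrics,
    round_half_up,
)

# published per-class validation results of the six-class mosquito benchmark
BENCH_CLASSES = ["Non-Vector", "Aedes albopictus", "Aedes vexans",
                 "Anopheles sinensis", "Culex pipiens", "Culex tritaeniorhynchus"]
BENCH_COUNTS = [120, 120, 118, 108, 180, 119]
BENCH_PR = [100.0, 100.0, 97.52, 100.0, 100.0, 97.54]
BENCH_RC = [100.0, 98.33, 100.0, 97.22, 99.44, 100.0]
BENCH_F1 = [100.0, 99.16, 98.74, 98.59, 99.72, 98.76]


def bench_confusion():
    """The (unique up to error placement) confusion matrix consistent with
    the published per-class table: 759/765 correct, with the six errors
    drawn from Aedes albopictus (2), Anopheles sinensis (3) and Culex
    pipiens (1) and absorbed by Aedes vexans (3) and C. tritaeniorhynchus (3).
    """
    cm = np.diag([120, 118, 118, 105, 179, 119])
    cm[1, 2] = 1  # albopictus → vexans
    cm[1, 5] = 1  # albopictus → tritaeniorhynchus
    cm[3, 2] = 2  # sinensis → vexans
    cm[3, 5] = 1  # sinensis → tritaeniorhynchus
    cm[4, 5] = 1  # pipiens → tritaeniorhynchus
    return cm


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        cm = confusion([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert np.array_equal(cm, np.diag([1, 2, 1]))

    def test_single_error_off_diagonal(self):
        cm = confusion([2], [0], 3)
        assert cm[2, 0] == 1 and cm.sum() == 1

    def test_total_equals_sample_count(self, rng):
        t = rng.integers(0, 4, 50)
        p = rng.integers(0, 4, 50)
        assert confusion(t, p, 4).sum() == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0], 2)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 3], [0, 1], 3)


class TestPerClassMetrics:
    @pytest.mark.parametrize(
        "pr,rc,expected", [(100.0, 98.33, 99.16), (97.52, 100.0, 98.74)]
    )
    def test_f1_reproduces_published_rows(self, pr, rc, expected):
        assert round_half_up(f1_score(pr, rc)) == expected

    def test_one_vs_rest_accuracy_with_two_errors(self):
        """2 misclassifications touching one class out of 765 → 99.74%."""
        cm = np.zeros((6, 6), dtype=int)
        for c, n in enumerate(BENCH_COUNTS):
            cm[c, c] = n
        # two errors: class 1 loses 2 to class 2
        cm[1, 1] -= 2
        cm[1, 2] += 2
        rep = per_class_metrics(cm)
        assert round_half_up(rep.per_class["acc"][1]) == 99.74

    def test_brute_force_equivalence_small_matrices(self):
        """Sweep all 3×3 confusion matrices with entries ≤ 2 against
        exhaustive one-vs-rest TP/TN/FP/FN counting."""
        for entries in itertools.product(range(3), repeat=9):
            cm = np.array(entries).reshape(3, 3)
            if cm.sum() == 0:
                continue
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = per_class_metrics(cm)
            total = cm.sum()
            for c in range(3):
                tp = sum(
                    cm[i, j]
                    for i in range(3)
                    for j in range(3)
                    if i == c and j == c
                )
                fp = sum(cm[i, c] for i in range(3) if i != c)
                fn = sum(cm[c, j] for j in range(3) if j != c)
                tn = total - tp - fp - fn
                assert rep.per_class["acc"][c] == pytest.approx(
                    100 * (tp + tn) / total
                )
                if tp + fp:
                    assert rep.per_class["pr"][c] == pytest.approx(100 * tp / (tp + fp))
                else:
                    assert rep.per_class["pr"][c] is None
                if tp + fn:
                    assert rep.per_class["rc"][c] == pytest.approx(100 * tp / (tp + fn))
                else:
                    assert rep.per_class["rc"][c] is None

    def test_matches_sklearn_on_random_labels(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        t = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        rep = per_class_metrics(confusion(t, p, 4))
        pr, rc, f1, _ = precision_recall_fscore_support(t, p, labels=range(4))
        assert np.allclose(rep.per_class["pr"], 100 * pr)
        assert np.allclose(rep.per_class["rc"], 100 * rc)
        assert np.allclose(rep.per_class["f1"], 100 * f1)

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(20):
            cm = rng.integers(0, 6, (4, 4))
            if cm.sum() == 0 or (cm.sum(0) == 0).any() or (cm.sum(1) == 0).any():
                continue
            rep = per_class_metrics(cm)
            for pr, rc, f1 in zip(*(rep.per_class[m] for m in ("pr", "rc", "f1"))):
                assert min(pr, rc) - 1e-9 <= f1 <= max(pr, rc) + 1e-9

    def test_undefined_metric_warns(self):
        cm = np.array([[2, 0], [1, 0]])  # class 1 never predicted
        with pytest.warns(UserWarning, match="precision undefined"):
            per_class_metrics(cm)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            per_class_metrics(np.zeros((3, 3), dtype=int))


class TestOverall:
    def test_reproduces_published_benchmark_table(self):
        """Full pipeline on the reconstructed benchmark confusion matrix
        reproduces every printed per-class and overall value."""
        rep = per_class_metrics(bench_confusion(), BENCH_CLASSES)
        assert rep.counts == BENCH_COUNTS
        for c in range(6):
            assert round_half_up(rep.per_class["pr"][c]) == BENCH_PR[c]
            assert round_half_up(rep.per_class["rc"][c]) == BENCH_RC[c]
            assert round_half_up(rep.per_class["f1"][c]) == BENCH_F1[c]
        # printed per-class one-vs-rest accuracies
        accs = [round_half_up(v) for v in rep.per_class["acc"]]
        assert accs == [100.0, 99.74, 99.61, 99.61, 99.87, 99.61]
        # overall row: 99.22 / 99.24 / 99.22 / 99.22
        assert round_half_up(rep.overall["acc"]) == 99.22
        assert round_half_up(rep.overall["pr"]) == 99.24
        assert round_half_up(rep.overall["rc"]) == 99.22
        assert round_half_up(rep.overall["f1"]) == 99.22

    def test_single_class_equals_itself(self):
        rep = MetricsReport(["a"], [10],
                            {"acc": [None], "pr": [90.0], "rc": [80.0], "f1": [84.71]})
        overall = overall_metrics(rep)
        assert overall["pr"] == 90.0 and overall["rc"] == 80.0

    def test_equal_counts_reduce_to_unweighted_mean(self):
        rep = MetricsReport(["a", "b"], [5, 5],
                            {"acc": [None] * 2, "pr": [80.0, 100.0],
                             "rc": [60.0, 100.0], "f1": [68.57, 100.0]})
        overall = overall_metrics(rep)
        assert overall["pr"] == pytest.approx(90.0)
        assert overall["rc"] == pytest.approx(80.0)

    def test_micro_recall_equals_overall_accuracy(self, rng):
        t = rng.integers(0, 3, 120)
        p = rng.integers(0, 3, 120)
        rep = per_class_metrics(confusion(t, p, 3))
        assert rep.overall["acc"] == pytest.approx(rep.overall["rc"])


class TestEvaluate:
    def test_perfect_classifier_scores_hundred(self, tiny_dataset, tiny_arrays):
        class Oracle:
            graph = ck.build_teacher(32, 6)

            def predict(self, x, batch_size=64):
                _, (xv, yv) = tiny_arrays
                return yv

        rep = ck.evaluate(Oracle(), tiny_dataset)
        for m in ("acc", "pr", "rc", "f1"):
            assert all(v == pytest.approx(100.0) for v in rep.per_class[m])
            assert rep.overall[m] == pytest.approx(100.0)
        assert rep.cost is not None and rep.cost.n_params > 0

    def test_repeat_evaluations_identical(self, tiny_dataset):
        model = ck.Model(ck.build_teacher(32, 6, seed=0), seed=0)
        r1 = ck.evaluate(model, tiny_dataset)
        r2 = ck.evaluate(model, tiny_dataset)
        assert r1.to_frame().equals(r2.to_frame())

    def test_empty_validation_split_rejected(self, tiny_dataset):
        import copy

        broken = copy.deepcopy(tiny_dataset)
        for s in broken.samples:
            s.split = "train"
        with pytest.raises(ValueError, match="validation"):
            ck.evaluate(ck.Model(ck.build_teacher(32, 6)), broken)


def test_round_half_up_matches_table_convention():
    assert round_half_up(99.215) == 99.22
    assert round_half_up(99.224) == 99.22
    assert round_half_up(2.675) == 2.68  # plain round() would give 2.67
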