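"""Metrics, the micro-average identity, ROC oracles and the pipeline wiring."""

import numpy as np
import pytest
from sklearn.metrics import f1_score, precision_score, recall_score

from semgfat import cnn as cnn_mod
from semgfat.baselines import SVMConfig
from semgfat.evaluation import (
    ConfusionMatrix,
    RunConfig,
    accuracy,
    compare_models,
    confusion,
    evaluate_predictions,
    micro_metrics,
    roc_curves,
    run_pipeline,
)
from semgfat.preprocessing import SplitSpec


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        true = np.array([0, 1, 2, 3, 3, 1])
        cm = confusion(true, true)
        assert np.all(cm.counts == np.diag(np.bincount(true, minlength=4)))

    def test_single_sample(self):
        cm = confusion([2], [3])
        assert cm.counts[2, 3] == 1
        assert cm.total == 1

    def test_additivity_over_concatenated_runs(self, rng):
        t1, p1 = rng.integers(0, 4, 50), rng.integers(0, 4, 50)
        t2, p2 = rng.integers(0, 4, 30), rng.integers(0, 4, 30)
        joint = confusion(np.r_[t1, t2], np.r_[p1, p2])
        np.testing.assert_array_equal(
            joint.counts, (confusion(t1, p1) + confusion(t2, p2)).counts
        )

    def test_row_percentages_sum_to_100(self, rng):
        cm = confusion(rng.integers(0, 4, 100), rng.integers(0, 4, 100))
        sums = cm.row_percentages().sum(axis=1)
        np.testing.assert_allclose(sums[cm.counts.sum(axis=1) > 0], 100.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])
        with pytest.raises(ValueError):
            confusion([0, 4], [0, 1])


class TestAccuracyIdentity:
    def test_all_correct(self):
        cm = ConfusionMatrix(np.diag([10, 10, 10, 10]))
        assert accuracy(cm) == 1.0

    def test_binary_arithmetic(self):
        # TP=3, TN=2, FP=1, FN=2 -> (3+2)/8
        cm = ConfusionMatrix(np.array([[2, 1], [2, 3]]))
        assert accuracy(cm) == pytest.approx(5 / 8)

    def test_micro_metrics_equal_accuracy_exactly(self, rng):
        for _ in range(100):
            cm = ConfusionMatrix(rng.integers(0, 30, (4, 4)))
            if cm.total == 0 or np.trace(cm.counts) == 0:
                continue
            mm = micro_metrics(cm)
            assert mm["acc"] == mm["prem"] == mm["recm"] == mm["f1m"]
            assert float(mm["acc"]) == pytest.approx(accuracy(cm))

    def test_micro_metrics_match_sklearn(self, rng):
        true = rng.integers(0, 4, 200)
        pred = rng.integers(0, 4, 200)
        mm = micro_metrics(confusion(true, pred))
        assert float(mm["prem"]) == pytest.approx(
            precision_score(true, pred, average="micro")
        )
        assert float(mm["recm"]) == pytest.approx(
            recall_score(true, pred, average="micro")
        )
        assert float(mm["f1m"]) == pytest.approx(f1_score(true, pred, average="micro"))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(np.zeros((4, 4), dtype=int)))


def _mann_whitney_auc(scores, positive):
    """Brute-force pairwise-comparison AUC (ties count 1/2)."""
    pos = scores[positive]
    neg = scores[~positive]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_ranking_auc_one(self):
        true = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        scores = np.eye(4)[true] + 0.01  # highest score on the true class
        roc = roc_curves(scores, true)
        for c, (_, _, auc) in roc["per_class"].items():
            assert auc == pytest.approx(1.0)
        assert roc["average"][2] == pytest.approx(1.0, abs=0.02)

    def test_auc_equals_mann_whitney_count(self, rng):
        for trial in range(10):
            n = 30
            true = rng.integers(0, 4, n)
            # quantized scores force ties to exercise the tie handling
            scores = np.round(rng.normal(size=(n, 4)), 1)
            roc = roc_curves(scores, true)
            for c, (_, _, auc) in roc["per_class"].items():
                expected = _mann_whitney_auc(scores[:, c], true == c)
                assert auc == pytest.approx(expected, abs=1e-12)

    def test_random_scores_auc_near_half(self, rng):
        n = 4000
        true = (rng.random(n) < 0.5).astype(int)
        scores = np.stack([rng.normal(size=n)] * 4, axis=1)
        _, _, auc = roc_curves(scores, true, n_classes=2)["per_class"][1]
        n_pos = int((true == 1).sum())
        n_neg = n - n_pos
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(auc - 0.5) < 3 * se

    def test_curves_anchored_and_monotone(self, rng):
        true = rng.integers(0, 4, 60)
        scores = rng.normal(size=(60, 4))
        roc = roc_curves(scores, true)
        for fpr, tpr, auc in roc["per_class"].values():
            assert fpr[0] == tpr[0] == 0.0
            assert fpr[-1] == tpr[-1] == 1.0
            assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
            assert 0.0 <= auc <= 1.0

    def test_absent_class_omitted_with_warning(self, rng):
        true = np.array([0, 0, 1, 1])
        scores = rng.normal(size=(4, 4))
        with pytest.warns(UserWarning, match="class 2"):
            roc = roc_curves(scores, true)
        assert set(roc["per_class"]) == {0, 1}

    def test_micro_average_mode(self, rng):
        true = rng.integers(0, 4, 80)
        scores = rng.normal(size=(80, 4))
        roc = roc_curves(scores, true, average="micro")
        assert 0.0 <= roc["average"][2] <= 1.0


class TestCompareModels:
    def _report(self, rng, model, acc_target):
        n = 200
        true = rng.integers(0, 4, n)
        pred = true.copy()
        flip = rng.random(n) > acc_target
        pred[flip] = (pred[flip] + 1) % 4
        scores = np.eye(4)[pred] + rng.normal(0, 0.01, (n, 4))
        return evaluate_predictions(true, pred, scores, model=model, speed=60)

    def test_single_report_single_row(self, rng):
        table = compare_models([self._report(rng, "CNN", 0.9)])
        assert len(table) == 1
        assert table.iloc[0]["model"] == "CNN"

    def test_sorted_by_descending_accuracy_and_order_invariant(self, rng):
        r1 = self._report(rng, "A", 0.95)
        r2 = self._report(rng, "B", 0.7)
        r3 = self._report(rng, "C", 0.5)
        t_fwd = compare_models([r1, r2, r3])
        t_rev = compare_models([r3, r1, r2])
        assert list(t_fwd["model"]) == list(t_rev["model"])
        assert t_fwd["accuracy"].is_monotonic_decreasing

    def test_holdout_mean_and_sample_sd(self, rng):
        rep = self._report(rng, "CNN", 0.9)
        rep.holdout_subject_acc = {"S1": 0.8, "S2": 0.9}
        assert rep.holdout_mean == pytest.approx(0.85)
        assert rep.holdout_sd == pytest.approx(0.0707, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_models([])


@pytest.fixture(scope="module")
def tiny_run_config(tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    return RunConfig(
        seed=2,
        n_subjects=6,
        speed=60,
        split=SplitSpec(holdout_subjects=1, seed=2),
        cnn=cnn_mod.TrainConfig(base_rate=10.0, max_iterations=60, seed=2),
        svm=SVMConfig(sigma=3.0, C=10.0),
        out_dir=out,
    )


class TestPipeline:
    def test_end_to_end_artifacts_and_reports(self, tiny_run_config):
        res = run_pipeline(tiny_run_config)
        assert set(res.reports) == {"CNN", "Multi-SVM", "Multi-LDA"}
        for rep in res.reports.values():
            assert 0.0 <= rep.acc <= 1.0
            assert rep.acc == rep.prem == rep.recm == rep.f1m
            assert len(rep.holdout_subject_acc) == 1
        out = tiny_run_config.out_dir
        for fname in (
            "comparison.tsv",
            "features.tsv",
            "training_curve.tsv",
            "confusion_cnn.csv",
            "roc_multi_svm.tsv",
            "cnn_model.npz",
            "run_config.json",
            "run_log.jsonl",
        ):
            assert (out / fname).exists(), fname

    def test_rerun_reproduces_metrics(self, tiny_run_config):
        cfg = RunConfig(
            **{
                **tiny_run_config.__dict__,
                "out_dir": None,
            }
        )
        r1 = run_pipeline(cfg)
        r2 = run_pipeline(cfg)
        for name in r1.reports:
            assert r1.reports[name].acc == r2.reports[name].acc
            np.testing.assert_array_equal(
                r1.reports[name].cm.counts, r2.reports[name].cm.counts
            )
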