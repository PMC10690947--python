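"""Training loop, cross-validation, and metric contracts."""

import numpy as np
import pytest

from gfacnn.graph import GraphConfig
from gfacnn.model import ArchConfig, init_params, one_hot
from gfacnn.pipeline import build_graph_samples, run_pipeline
from gfacnn.synthetic import SimConfig, simulate_dataset
from gfacnn.train_eval import (
    EvalMetrics, TrainConfig, aggregate_metrics, evaluate, holdout_split,
    kfold_cv, metrics_from_scores, roc_auc, stack_samples, train,
)


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise AUC: wins over all positive-negative pairs,
    ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def small_stacked():
    """60 fast small-window segments per class, stacked once."""
    ds = simulate_dataset(30, 30, SimConfig(window=256), seed=11)
    return stack_samples(build_graph_samples(ds.segments))


@pytest.fixture(scope="module")
def fast_cfg():
    return TrainConfig(epochs=15, k_folds=3, seed=11)


class TestTrain:
    def test_runs_all_epochs_while_improving(self, small_stacked):
        """With the validation set equal to the training set and a tiny
        learning rate, every epoch strictly improves the monitored loss,
        so training must run to the epoch cap with best_epoch at the end."""
        cfg = TrainConfig(lr=1e-4, epochs=20, seed=0)
        arch = ArchConfig(n_nodes=19, feature_dim=4)
        _, h = train(small_stacked, small_stacked, init_params(arch, 0), cfg)
        assert h.stopped_epoch == 20
        assert h.best_epoch == 20
        assert all(b < a for a, b in zip(h.val_loss, h.val_loss[1:]))

    def test_constant_validation_loss_stops_after_patience(self, small_stacked):
        """A learning rate too small to change any parameter in floating
        point freezes the validation loss, so training stops at epoch
        1 + patience."""
        cfg = TrainConfig(lr=1e-300, epochs=100, patience=10, seed=0)
        arch = ArchConfig(n_nodes=19, feature_dim=4)
        _, h = train(small_stacked, small_stacked, init_params(arch, 0), cfg)
        assert h.stopped_epoch == 11
        assert h.best_epoch == 1

    def test_same_seed_reproduces_history_and_params(self, small_stacked, fast_cfg):
        arch = ArchConfig(n_nodes=19, feature_dim=4)
        p1, h1 = train(small_stacked, small_stacked,
                       init_params(arch, 1), fast_cfg)
        p2, h2 = train(small_stacked, small_stacked,
                       init_params(arch, 1), fast_cfg)
        assert h1.train_loss == h2.train_loss
        np.testing.assert_array_equal(p1.to_vector(), p2.to_vector())

    def test_single_class_training_warns(self, small_stacked, fast_cfg):
        only_pos = small_stacked.subset(small_stacked.y == 0)
        arch = ArchConfig(n_nodes=19, feature_dim=4)
        with pytest.warns(UserWarning, match="single class"):
            train(only_pos, only_pos, init_params(arch, 0),
                  TrainConfig(epochs=2, seed=0))


class TestEvaluateMetrics:
    def test_perfect_predictions(self):
        m = metrics_from_scores(np.array([0.9, 0.8, 0.1, 0.2]),
                                np.array([True, True, False, False]))
        assert m.accuracy == m.sensitivity == m.specificity == 1.0
        assert m.auc == 1.0

    def test_hand_counted_confusion_table(self):
        """labels [1,1,0,0], predictions [1,0,0,0]: TP=1 FN=1 TN=2 FP=0."""
        m = metrics_from_scores(np.array([0.9, 0.2, 0.3, 0.1]),
                                np.array([True, True, False, False]))
        assert (m.tp, m.fn, m.tn, m.fp) == (1, 1, 2, 0)
        assert m.accuracy == 0.75
        assert m.sensitivity == 0.5
        assert m.specificity == 1.0

    def test_all_positive_predictions_on_balanced_set(self):
        m = metrics_from_scores(np.array([0.9, 0.8, 0.7, 0.6]),
                                np.array([True, True, False, False]))
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0
        assert m.accuracy == 0.5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics_from_scores(np.array([]), np.array([], dtype=bool))

    def test_aggregation_hand_arithmetic(self):
        """Fold accuracies [1.0, .9, .95, 1.0, .95]: mean .96, sd .0418."""
        folds = [
            EvalMetrics(accuracy=a, sensitivity=a, specificity=a, auc=a,
                        roc_points=[], tp=0, tn=0, fp=0, fn=0)
            for a in (1.0, 0.9, 0.95, 1.0, 0.95)
        ]
        mean, std = aggregate_metrics(folds)
        assert mean["accuracy"] == pytest.approx(0.96)
        assert std["accuracy"] == pytest.approx(0.0418, abs=5e-5)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]),
                         np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_three_of_four_pairs(self):
        _, auc = roc_auc(np.array([0.9, 0.8, 0.3, 0.2]),
                         np.array([1, 0, 1, 0]))
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc(np.array([0.5, 0.6]), np.array([1, 1]))

    def test_random_scores_near_half(self):
        r = np.random.default_rng(77)
        labels = r.integers(0, 2, 2000)
        while np.unique(labels).size < 2:
            labels = r.integers(0, 2, 2000)
        scores = r.uniform(size=2000)
        _, auc = roc_auc(scores, labels)
        assert 0.45 <= auc <= 0.55

    def test_trapezoid_equals_pairwise_mann_whitney(self):
        """Threshold-sweep trapezoid area must equal the rank statistic,
        ties counted one half, on small random instances with ties."""
        r = np.random.default_rng(5)
        for _ in range(200):
            n = int(r.integers(4, 15))
            labels = r.integers(0, 2, n)
            if np.unique(labels).size < 2:
                continue
            scores = np.round(r.uniform(size=n), 1)  # induce ties
            roc_points, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels),
                                        abs=1e-12)
            fpr = [p[0] for p in roc_points]
            tpr = [p[1] for p in roc_points]
            assert fpr == sorted(fpr) and tpr == sorted(tpr)


class TestKFold:
    def test_every_sample_in_exactly_one_validation_fold(self, small_stacked):
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        seen = np.zeros(len(small_stacked), dtype=int)
        for _, va in skf.split(np.zeros(len(small_stacked)), small_stacked.y):
            seen[va] += 1
        assert (seen == 1).all()

    def test_stratification_within_one_sample(self):
        """A 60/40 class mix over 100 samples must split into folds whose
        mix is within one sample of 12/8."""
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0] * 60 + [1] * 40)
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        for _, va in skf.split(np.zeros(100), y):
            counts = np.bincount(y[va], minlength=2)
            assert abs(counts[0] - 12) <= 1 and abs(counts[1] - 8) <= 1

    def test_cv_reports_per_fold_and_aggregate(self, small_stacked, fast_cfg):
        cv = kfold_cv(small_stacked, fast_cfg)
        assert len(cv.fold_metrics) == 3
        assert set(cv.mean) == {"accuracy", "sensitivity", "specificity", "auc"}
        assert 0 <= cv.mean["accuracy"] <= 1

    def test_too_few_samples_per_class_rejected(self, small_stacked):
        tiny = small_stacked.subset(np.arange(4))
        with pytest.raises(ValueError, match="per class"):
            kfold_cv(tiny, TrainConfig(k_folds=5))

    def test_fixed_seed_reproduces_metrics(self, small_stacked, fast_cfg):
        cv1 = kfold_cv(small_stacked, fast_cfg)
        cv2 = kfold_cv(small_stacked, fast_cfg)
        assert cv1.mean == cv2.mean


class TestHoldout:
    def test_split_is_stratified_partition(self, small_stacked):
        cfg = TrainConfig(holdout_fraction=0.2, seed=3)
        rest, hold = holdout_split(small_stacked, cfg)
        assert len(rest) + len(hold) == len(small_stacked)
        assert len(hold) == round(0.2 * len(small_stacked))
        assert abs(np.mean(hold.y) - 0.5) <= 0.1

    def test_zero_fraction_keeps_everything(self, small_stacked):
        rest, hold = holdout_split(small_stacked,
                                   TrainConfig(holdout_fraction=0.0))
        assert len(rest) == len(small_stacked)
        assert len(hold) == 0

    def test_pipeline_produces_full_report(self, small_stacked, fast_cfg):
        result = run_pipeline(small_stacked, fast_cfg)
        report = result.report()
        assert len(report["cv"]["per_fold"]) == 3
        assert "holdout" in report
        assert 0 <= report["holdout"]["accuracy"] <= 1
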