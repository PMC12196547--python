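"""Schedule, grouped folds, metrics and the training loop."""

import numpy as np
import pytest

from gaitpd import (
    ConfusionCounts,
    LossWeights,
    ModelConfig,
    StepSample,
    TrainConfig,
    aggregate_folds,
    compute_metrics,
    f1_from_pr,
    grouped_kfold,
    learning_rate,
    roc_auc,
    run_training,
)
from gaitpd.train_eval import FoldResult


class TestLearningRate:
    def test_warmup_constant_decay_anchors(self):
        cfg = TrainConfig()
        assert learning_rate(0, cfg) == pytest.approx(1e-8)
        for e in (200, 400, 599):
            assert learning_rate(e, cfg) == pytest.approx(1e-4)
        assert learning_rate(1000, cfg) == pytest.approx(1e-6)

    def test_warmup_is_monotone_increasing(self):
        cfg = TrainConfig()
        lrs = [learning_rate(e, cfg) for e in range(0, 200)]
        assert all(b > a for a, b in zip(lrs, lrs[1:]))

    def test_decay_is_monotone_decreasing(self):
        cfg = TrainConfig()
        lrs = [learning_rate(e, cfg) for e in range(600, 1001)]
        assert all(b < a for a, b in zip(lrs, lrs[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            learning_rate(1001, TrainConfig())
        with pytest.raises(ValueError):
            learning_rate(-1, TrainConfig())

    def test_phases_must_sum_to_epochs(self):
        with pytest.raises(ValueError, match="sum"):
            TrainConfig(epochs=100, warmup_epochs=10, constant_epochs=10,
                        decay_epochs=10)

    def test_cosine_decay_shares_anchors(self):
        cfg = TrainConfig(decay_shape="cosine")
        assert learning_rate(600, cfg) == pytest.approx(1e-4)
        assert learning_rate(1000, cfg) == pytest.approx(1e-6)


def _fake_samples(n_subjects, steps_each=4, seed=0, pd_frac=0.3):
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_subjects):
        label = int(rng.random() < pd_frac)
        for _ in range(steps_each + int(rng.integers(0, 3))):
            m = rng.normal(size=(50, 39))
            samples.append(StepSample(f"sub{i}", label, m, m.copy(), 50))
    return samples


class TestGroupedKFold:
    def test_subjects_never_straddle_folds(self):
        samples = _fake_samples(17, seed=3)
        folds = grouped_kfold(samples, k=5, seed=1)
        seen = {}
        for s, f in zip(samples, folds):
            assert seen.setdefault(s.subject_id, f) == f

    def test_partition_is_complete_and_disjoint(self):
        samples = _fake_samples(12, seed=4)
        folds = grouped_kfold(samples, k=5, seed=0)
        assert folds.shape == (len(samples),)
        assert set(folds) == set(range(5))

    def test_ten_subjects_five_folds_two_each(self):
        samples = _fake_samples(10, seed=5)
        folds = grouped_kfold(samples, k=5, seed=0)
        per_fold = [
            len({s.subject_id for s, f in zip(samples, folds) if f == k})
            for k in range(5)
        ]
        assert per_fold == [2] * 5

    def test_deterministic_given_seed(self):
        samples = _fake_samples(9, seed=6)
        a = grouped_kfold(samples, k=3, seed=7)
        b = grouped_kfold(samples, k=3, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            grouped_kfold(_fake_samples(3), k=5)


class TestMetrics:
    def test_perfect_predictions(self):
        res = compute_metrics(ConfusionCounts(TP=1, TN=1, FP=0, FN=0))
        assert (res.acc, res.prec, res.rec, res.f1) == (100.0, 100.0, 100.0, 100.0)

    def test_accuracy_exact_formula(self):
        c = ConfusionCounts(TP=3, TN=5, FP=2, FN=1)
        res = compute_metrics(c)
        assert res.acc == pytest.approx(100.0 * 8 / 11)
        assert res.prec == pytest.approx(100.0 * 3 / 5)
        assert res.rec == pytest.approx(100.0 * 3 / 4)
        assert min(res.prec, res.rec) <= res.f1 <= max(res.prec, res.rec)

    def test_undefined_precision_flagged(self):
        res = compute_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=2))
        assert "precision" in res.undefined

    def test_f1_harmonic_mean(self):
        assert f1_from_pr(50.0, 50.0) == pytest.approx(50.0)
        assert f1_from_pr(100.0, 0.5) < 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_hand_case_matches_pair_counting(self):
        scores = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.1])
        labels = np.array([1, 0, 1, 0, 1, 0])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = pairs / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_matches_sklearn_on_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = np.round(rng.random(200), 1)  # heavy ties
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestAggregateFolds:
    def _folds(self):
        vals = [(89.3, 85.0, 77.6, 81.1, 0.940), (85.0, 75.0, 72.3, 73.6, 0.882)]
        return [FoldResult(acc=a, prec=p, rec=r, f1=f, auc=u)
                for a, p, r, f, u in vals]

    def test_mean_row_is_arithmetic_mean(self):
        rep = aggregate_folds(self._folds())
        assert rep.mean.acc == pytest.approx(87.15)
        assert rep.mean.auc == pytest.approx(0.911)

    def test_single_fold_mean_is_itself(self):
        one = self._folds()[:1]
        rep = aggregate_folds(one)
        assert rep.mean.f1 == one[0].f1

    def test_permutation_invariance(self):
        folds = self._folds()
        a = aggregate_folds(folds).mean
        b = aggregate_folds(folds[::-1]).mean
        assert a.acc == b.acc and a.f1 == b.f1


@pytest.fixture(scope="module")
def tiny_run():
    """Two-epoch smoke training on a tiny synthetic set."""
    from gaitpd import cohort_to_samples, synth_cohort

    cohort = synth_cohort(n_subjects=8, effect_size=1.0, seed=5, duration=12.0)
    samples = cohort_to_samples(cohort, use_true_boundaries=True)
    cfg = TrainConfig(batch_size=64, epochs=2, warmup_epochs=1,
                      constant_epochs=1, decay_epochs=0, lr_peak=1e-3, seed=0)
    return run_training(samples, ModelConfig(), cfg, LossWeights(), k=3)


class TestRunTraining:
    def test_emits_all_artifacts(self, tiny_run):
        assert len(tiny_run.folds) == 3
        for fa in tiny_run.folds:
            assert len(fa.history) == 2
            assert fa.stats.mu_frontal.shape == (39,)
            assert fa.val_scores.shape == fa.val_labels.shape
        assert np.isfinite(tiny_run.report.mean.acc)

    def test_best_checkpoint_f1_is_max_of_logged_series(self, tiny_run):
        for fa in tiny_run.folds:
            logged = [h["val_f1"] for h in fa.history]
            assert fa.result.f1 == pytest.approx(max(logged))
            assert fa.result.best_epoch == int(np.argmax(logged))

    def test_validation_subjects_not_in_training(self, tiny_run):
        # leakage check via the fold assignment
        assignment = tiny_run.fold_assignment
        assert assignment.min() >= 0 and assignment.max() <= 2

    def test_subject_majority_report(self, tiny_run):
        rep = tiny_run.subject_majority_report()
        assert 0 <= rep["subject_accuracy"] <= 100
        assert rep["n_subjects"] == 8
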