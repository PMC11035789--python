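"""Metrics against independent oracles, fold hygiene, label schemes,
baselines and the Wilcoxon comparison machinery."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, f1_score

from eegssl import (EvalConfig, EvalReport, LinearProbeEvaluation, accuracy,
                    compare_methods, crossval_evaluate, f1_macro,
                    f1_per_class, make_va_labels, permute_trial_labels,
                    random_baseline_crossval, wilcoxon_compare)


class TestMetrics:
    def test_accuracy_arithmetic(self):
        true = np.r_[np.zeros(90), np.ones(10)]
        pred = np.zeros(100)
        assert accuracy(pred, true) == pytest.approx(0.90)
        assert accuracy(true, true) == 1.0

    def test_accuracy_from_confusion_counts(self):
        # TP=40, TN=30, FP=20, FN=10 -> 70/100
        true = np.r_[np.ones(50), np.zeros(50)]
        pred = np.r_[np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)]
        assert accuracy(pred, true) == pytest.approx(0.70)

    def test_f1_substitution(self):
        # TP=2, FP=1, FN=1 -> 2*2/(2*2+1+1) = 2/3
        true = np.array([1, 1, 1, 0, 0])
        pred = np.array([1, 1, 0, 1, 0])
        assert f1_per_class(pred, true, 1) == pytest.approx(2 / 3)

    def test_f1_worked_two_class_example(self):
        true = [1, 1, 2, 2]
        pred = [1, 2, 1, 2]
        assert f1_per_class(pred, true, 1) == pytest.approx(0.5)
        assert f1_macro(pred, true, n_classes=3) == pytest.approx(
            (0.0 + 0.5 + 0.5) / 3)

    def test_f1_absent_class_pinned_to_zero(self):
        assert f1_per_class([0, 0], [0, 0], 5) == 0.0

    def test_metrics_match_sklearn_on_random_vectors(self):
        """Independent confusion-matrix oracle (sklearn), 1000 draws."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n_classes = rng.integers(2, 5)
            n = rng.integers(2, 40)
            true = rng.integers(0, n_classes, n)
            pred = rng.integers(0, n_classes, n)
            assert accuracy(pred, true) == accuracy_score(true, pred)
            ours = f1_macro(pred, true, n_classes)
            ref = f1_score(true, pred, labels=range(n_classes),
                           average="macro", zero_division=0)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_random_uniform_macro_f1_near_third(self):
        rng = np.random.default_rng(1)
        n = 100_000
        true = rng.permutation(np.repeat(np.arange(3), n // 3 + 1)[:n])
        pred = rng.integers(0, 3, n)
        assert f1_macro(pred, true, 3) == pytest.approx(1 / 3, abs=0.01)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], [])


class TestVALabels:
    def test_quadrant_mapping(self):
        assert make_va_labels(7, 3) == 2      # high-V / low-A
        assert make_va_labels(2, 2) == 0      # low-V / low-A
        assert make_va_labels(3, 8) == 1      # low-V / high-A
        assert make_va_labels(9, 9) == 3      # high-V / high-A

    def test_threshold_tie_counts_as_high(self):
        assert make_va_labels(5, 5) == 3

    def test_vectorized(self):
        out = make_va_labels([1, 9], [9, 1])
        np.testing.assert_array_equal(out, [1, 2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_va_labels(11, 5)


def _toy_features(n_trials=12, windows_per_trial=30, n_classes=3, seed=0,
                  separation=3.0):
    """Gaussian blobs per class, grouped into trials."""
    rng = np.random.default_rng(seed)
    X, y, g = [], [], []
    for t in range(n_trials):
        label = t % n_classes
        mu = np.zeros(4)
        mu[label % 4] = separation
        X.append(rng.normal(mu, 1.0, size=(windows_per_trial, 4)))
        y.append(np.full(windows_per_trial, label))
        g.append(np.full(windows_per_trial, t))
    return np.vstack(X), np.concatenate(y), np.concatenate(g)


class TestCrossval:
    def test_cheating_features_reach_100(self):
        X, y, g = _toy_features()
        rep = crossval_evaluate(np.eye(3)[y], y, g,
                                EvalConfig(n_folds=4, seed=0))
        assert np.all(rep.fold_accuracy == 100.0)

    def test_separable_features_score_high(self):
        X, y, g = _toy_features(separation=4.0)
        rep = crossval_evaluate(X, y, g, EvalConfig(n_folds=4, seed=0))
        assert rep.mean_accuracy > 90.0

    def test_folds_group_by_trial(self):
        from eegssl.evaluation import _grouped_folds
        _, y, g = _toy_features()
        for train, test in _grouped_folds(y, g, 4, seed=0):
            assert not set(g[train]) & set(g[test])

    def test_label_fraction_uses_fewer_labels(self):
        X, y, g = _toy_features(separation=4.0)
        rep = crossval_evaluate(X, y, g, EvalConfig(n_folds=4, seed=0,
                                                    label_fraction=0.1))
        assert rep.mean_accuracy > 80.0  # blobs are easy even at 10%

    def test_fine_tune_mode_learns_separable_classes(self, small_windows):
        X = np.concatenate([ws.windows for ws in small_windows])
        y = np.concatenate([[ws.label] * ws.n_windows
                            for ws in small_windows])
        g = np.concatenate([[i] * ws.n_windows
                            for i, ws in enumerate(small_windows)])
        from eegssl import EncoderConfig, WindowEncoder
        enc = WindowEncoder(EncoderConfig(embedding_dim=8, n_filters=8,
                                          kernel_size=25, stride=10,
                                          seed=0), X.shape[1:])
        cfg = EvalConfig(mode="fine_tune", n_folds=3, seed=0)
        rep = LinearProbeEvaluation(X, y, g, cfg, encoder=enc,
                                    method="fine-tune").fit()
        assert rep.mean_accuracy > 60.0   # well above 33% chance

    def test_fine_tune_requires_encoder(self):
        X, y, g = _toy_features()
        with pytest.raises(ValueError, match="encoder"):
            LinearProbeEvaluation(X, y, g,
                                  EvalConfig(mode="fine_tune", n_folds=3))

    def test_deterministic_under_seed(self):
        X, y, g = _toy_features(separation=1.0)
        cfg = EvalConfig(n_folds=4, seed=3)
        a = crossval_evaluate(X, y, g, cfg)
        b = crossval_evaluate(X, y, g, cfg)
        np.testing.assert_array_equal(a.fold_accuracy, b.fold_accuracy)

    def test_report_invariants(self):
        with pytest.raises(ValueError):
            EvalReport(method="x", fold_accuracy=[101.0],
                       fold_f1_macro=[50.0])


class TestBaselinesAndNull:
    def test_random_baseline_three_class(self):
        rng = np.random.default_rng(2)
        n_trials, wpt = 60, 300
        y = np.repeat(np.arange(n_trials) % 3, wpt)
        g = np.repeat(np.arange(n_trials), wpt)
        rep = random_baseline_crossval(y, g, 3, EvalConfig(n_folds=10),
                                       seed=1)
        assert rep.mean_accuracy == pytest.approx(100 / 3, abs=1.5)

    def test_permuted_labels_constant_within_trial(self):
        _, y, g = _toy_features()
        out = permute_trial_labels(y, g, np.random.default_rng(0))
        for t in np.unique(g):
            assert len(np.unique(out[g == t])) == 1
        assert sorted(np.bincount(out)) == sorted(np.bincount(y))

    def test_permuted_labels_score_at_chance(self):
        X, y, g = _toy_features(n_trials=18, separation=4.0)
        y_perm = permute_trial_labels(y, g, np.random.default_rng(4))
        rep = crossval_evaluate(X, y_perm, g, EvalConfig(n_folds=6, seed=0))
        assert abs(rep.mean_accuracy - 100 / 3) < 12.0


class TestWilcoxon:
    def test_identical_scores_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_compare(np.arange(10.0), np.arange(10.0))

    def test_constant_shift_gives_zero_statistic(self):
        a = np.arange(10.0)
        stat, p = wilcoxon_compare(a + 1.0, a)
        assert stat == 0.0
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_statistic_matches_hand_ranking(self):
        a = np.array([10.0, 12.0, 9.0, 15.0, 11.0, 13.0])
        b = np.array([11.0, 10.0, 10.5, 12.0, 11.5, 12.0])
        d = a - b
        # midranks of |d|, computed by hand (ties share the average rank)
        absd = np.abs(d)
        ranks = np.array([
            np.mean(np.flatnonzero(np.sort(absd) == v) + 1.0) for v in absd])
        w_pos = ranks[d > 0].sum()
        w_neg = ranks[d < 0].sum()
        stat, _ = wilcoxon_compare(a, b)
        assert stat == min(w_pos, w_neg)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1.0, 2.0], [2.0, 1.0])

    def test_compare_methods_bonferroni(self):
        rng = np.random.default_rng(5)
        reports = {}
        for i, name in enumerate(["a", "b", "c"]):
            acc = 50 + 10 * i + rng.normal(0, 1, 10)
            acc = np.clip(acc, 0, 100)
            reports[name] = EvalReport(method=name, fold_accuracy=acc,
                                       fold_f1_macro=acc)
        df = compare_methods(reports)
        assert len(df) == 3
        np.testing.assert_allclose(df["p_bonferroni"],
                                   np.minimum(df["p"] * 3, 1.0))
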