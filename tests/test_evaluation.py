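import numpy as np
import pytest

import lithowarn as lw
from lithowarn.errors import ConfigError, ValidationError
from lithowarn.evaluation import FPR_GRID, iter_cv_splits, make_dummy_segments


def _constant_segments(n_per_class, length=50):
    """Disjoint constant feature values per class: trivially separable."""
    segs = []
    for c in (0, 1, 2):
        for i in range(n_per_class):
            segs.append(
                lw.Segment(values=np.full(length, float(c)), label=c, origin=("k", i))
            )
    return segs


def _auc_pairwise_oracle(scores, truth):
    """Mann-Whitney U statistic: fraction of (pos, neg) pairs ranked
    correctly, ties counted half."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBalancedSubset:
    def test_exact_counts(self, rng):
        segs = []
        for c, count in zip((0, 1, 2), (30, 25, 40)):
            segs += [lw.Segment(values=rng.random(10), label=c) for _ in range(count)]
        subset = lw.pick_balanced_subset(segs, m=20, seed=0)
        counts = np.bincount([int(s.label) for s in subset], minlength=3)
        assert len(subset) == 60 and (counts == 20).all()

    def test_smallest_class_fully_included(self, rng):
        segs = []
        for c, count in zip((0, 1, 2), (5, 9, 12)):
            segs += [
                lw.Segment(values=rng.random(10), label=c, origin=("r", c * 100 + i))
                for i in range(count)
            ]
        subset = lw.pick_balanced_subset(segs, m=5, seed=3)
        idle_origins = {s.origin for s in subset if s.label == 0}
        assert idle_origins == {("r", i) for i in range(5)}

    def test_undersized_class_named_in_error(self, rng):
        segs = [lw.Segment(values=rng.random(10), label=c) for c in (0, 1, 2)]
        segs += [lw.Segment(values=rng.random(10), label=0) for _ in range(10)]
        with pytest.raises(ValidationError, match="Stone"):
            lw.pick_balanced_subset(segs, m=2, seed=0)

    def test_different_seeds_give_different_subsets(self, rng):
        segs = [
            lw.Segment(values=rng.random(10), label=c, origin=("r", 1000 * c + i))
            for c in (0, 1, 2)
            for i in range(100)
        ]
        a = {s.origin for s in lw.pick_balanced_subset(segs, m=20, seed=1)}
        b = {s.origin for s in lw.pick_balanced_subset(segs, m=20, seed=2)}
        assert a != b


class TestCvSplits:
    def test_folds_are_disjoint_and_stratified(self):
        labels = np.repeat([0, 1, 2], 40)
        cfg = lw.ValidationConfig(m=20, n_reps=5, k=10, seed=9)
        seen = 0
        for rep, fold, train, test in iter_cv_splits(labels, cfg):
            seen += 1
            assert len(np.intersect1d(train, test)) == 0
            assert len(test) == 6
            assert (np.bincount(labels[test], minlength=3) == 2).all()
            assert (np.bincount(labels[train], minlength=3) == 18).all()
        assert seen == 5 * 10

    def test_test_folds_partition_each_subset(self):
        labels = np.repeat([0, 1, 2], 40)
        cfg = lw.ValidationConfig(m=20, n_reps=3, k=10, seed=4)
        per_rep = {}
        for rep, fold, train, test in iter_cv_splits(labels, cfg):
            per_rep.setdefault(rep, []).append(test)
        for tests in per_rep.values():
            stacked = np.concatenate(tests)
            assert len(stacked) == 60 and len(np.unique(stacked)) == 60


class TestValidationConfig:
    def test_combination_count(self):
        assert lw.ValidationConfig(m=20, n_reps=100, k=10).combination_count == 20000

    @pytest.mark.parametrize(
        "kwargs", [{"k": 1}, {"m": 1, "k": 10}, {"n_reps": 0}, {"wavelets": ()}]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            lw.ValidationConfig(**kwargs)


class TestNormalizedConfusion:
    def test_perfect_predictions_identity(self):
        y = [0, 0, 1, 1, 2, 2]
        assert np.array_equal(lw.normalized_confusion(y, y), np.eye(3))

    def test_constant_predictions_fill_first_column(self):
        y = [0, 1, 2, 1, 2]
        m = lw.normalized_confusion(y, [0] * 5)
        assert np.array_equal(m[:, 0], np.ones(3))

    def test_hand_counted_nine_samples(self):
        true = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        pred = [0, 1, 0, 1, 1, 2, 2, 2, 0]
        m = lw.normalized_confusion(true, pred)
        expected = np.array(
            [[2 / 3, 1 / 3, 0], [0, 2 / 3, 1 / 3], [1 / 3, 0, 2 / 3]]
        )
        assert np.allclose(m, expected)

    def test_rows_sum_to_one(self, rng):
        true = rng.integers(0, 3, 200)
        pred = rng.integers(0, 3, 200)
        assert np.allclose(lw.normalized_confusion(true, pred).sum(axis=1), 1.0)

    def test_zero_support_row_flagged(self):
        with pytest.warns(UserWarning, match="Tissue"):
            m = lw.normalized_confusion([0, 1], [0, 1])
        assert np.array_equal(m[2], np.zeros(3))

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            lw.normalized_confusion([], [])


class TestOvrRoc:
    def test_perfect_scores(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        truth = np.array([1, 1, 0, 0])
        *_, auc = lw.ovr_roc(scores, truth, positive_class=1)
        assert auc == pytest.approx(1.0)

    def test_inverted_scores(self):
        scores = np.array([0.1, 0.2, 0.9, 0.8])
        truth = np.array([1, 1, 0, 0])
        *_, auc = lw.ovr_roc(scores, truth, positive_class=1)
        assert auc == pytest.approx(0.0)

    def test_six_point_hand_set_matches_u_statistic(self):
        scores = np.array([0.9, 0.6, 0.55, 0.5, 0.3, 0.1])
        truth = np.array([1, 0, 1, 1, 0, 0])
        *_, auc = lw.ovr_roc(scores, truth, positive_class=1)
        assert auc == pytest.approx(_auc_pairwise_oracle(scores, truth))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_scores_match_u_statistic(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(60)
        truth = rng.integers(0, 2, 60)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        *_, auc = lw.ovr_roc(scores, truth, positive_class=1)
        assert auc == pytest.approx(_auc_pairwise_oracle(scores, truth), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValidationError):
            lw.ovr_roc(np.array([0.1, 0.9]), [1, 1], positive_class=1)


class TestRepeatedCv:
    def test_trivially_separable_data_is_perfect(self):
        segs = _constant_segments(12)
        cfg = lw.ValidationConfig(m=10, n_reps=2, k=5, seed=0)
        report = lw.run_repeated_cv(segs, "haar", val_cfg=cfg)
        assert report.mean_accuracy == 1.0
        assert np.array_equal(report.confusion, np.eye(3))
        assert report.combination_count == 10 * 2 * 5

    def test_accuracy_bookkeeping_identity(self, short_segments):
        cfg = lw.ValidationConfig(m=15, n_reps=3, k=5, seed=1)
        report = lw.run_repeated_cv(short_segments, "db2", val_cfg=cfg)
        assert report.mean_accuracy == pytest.approx(report.fold_accuracies.mean())
        assert len(report.fold_accuracies) == 3 * 5
        assert len(report.rep_accuracies) == 3
        assert report.rep_accuracies.mean() == pytest.approx(report.mean_accuracy)

    def test_report_structure(self, short_segments):
        cfg = lw.ValidationConfig(m=10, n_reps=2, k=5, seed=2)
        report = lw.run_repeated_cv(short_segments, "dmey", val_cfg=cfg)
        assert set(report.roc) == {
            "Idle vs rest",
            "Stone vs rest",
            "Tissue vs rest",
        }
        for summary in report.roc.values():
            assert summary.fpr_grid.shape == FPR_GRID.shape
            assert 0.0 <= summary.auc_mean <= 1.0
            assert (summary.tpr_std >= 0).all()
        assert np.allclose(report.confusion.sum(axis=1), 1.0)
        payload = report.to_dict()
        assert payload["combination_count"] == 100
        assert len(payload["roc"]) == 3

    def test_simulated_data_high_accuracy(self, default_segments_60s):
        cfg = lw.ValidationConfig(m=20, n_reps=3, k=10, seed=3)
        report = lw.run_repeated_cv(default_segments_60s, "dmey", val_cfg=cfg)
        assert report.mean_accuracy >= 0.95


class TestWaveletSweep:
    def test_family_spread_is_small(self, default_segments_60s):
        """All five families perform alike on separable simulated data."""
        cfg = lw.ValidationConfig(
            m=20, n_reps=3, k=10, seed=8,
            wavelets=("haar", "db2", "db4", "rbio2.4", "dmey"),
        )
        reports = lw.sweep_wavelets(default_segments_60s, cfg)
        accs = [r.mean_accuracy for r in reports.values()]
        assert len(accs) == 5
        assert max(accs) - min(accs) <= 0.05


class TestDummyNull:
    def test_dummy_report_is_chance_like(self):
        cfg = lw.ValidationConfig(m=10, n_reps=5, k=5, seed=6)
        report = lw.run_dummy_null(cfg, segment_shape=(50, 50), seed=6)
        assert abs(report.mean_accuracy - 1.0 / 3.0) < 0.15
        assert np.allclose(report.confusion.sum(axis=1), 1.0)

    def test_constant_dummy_segments_are_separable_control(self):
        # sanity inversion: distinct constant values per class are learnable
        segs = _constant_segments(12)
        cfg = lw.ValidationConfig(m=10, n_reps=2, k=5, seed=0)
        report = lw.run_repeated_cv(segs, "dmey", val_cfg=cfg)
        assert report.mean_accuracy == 1.0

    def test_null_distribution_covers_one_third(self):
        """One-sample t-test over 30 independent dummy runs must not reject
        mean accuracy = 1/3 at alpha = 0.01."""
        means = []
        for run in range(30):
            cfg = lw.ValidationConfig(m=10, n_reps=2, k=5, seed=1000 + run)
            fcfg = lw.ForestConfig(n_trees=25, seed=run)
            rep = lw.run_dummy_null(cfg, fcfg, segment_shape=(30, 50), seed=run)
            means.append(rep.mean_accuracy)
        means = np.asarray(means)
        t_stat = (means.mean() - 1.0 / 3.0) / (means.std(ddof=1) / np.sqrt(30))
        assert abs(t_stat) < 2.756  # two-sided t critical value, df=29, alpha=.01

    def test_dummy_segments_are_uniform_and_balanced(self):
        segs = make_dummy_segments(40, 50, seed=2)
        values = np.concatenate([s.values for s in segs])
        assert values.min() >= 0.0 and values.max() <= 1.0
        counts = np.bincount([int(s.label) for s in segs], minlength=3)
        assert (counts == 40).all()
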