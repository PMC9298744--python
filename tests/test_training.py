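import numpy as np
import pytest
from scipy import stats

from dfcrnn import model as M
from dfcrnn import train as T
from dfcrnn.dfc import SlidingWindowConfig
from dfcrnn.io_cohort import Cohort, ScanRecord


def _records_cohort(spec):
    """Build a records-only cohort from (subject, scans, label, baseline_idx)."""
    records = []
    for subj, n_scans, label, baseline_idx in spec:
        for i in range(n_scans):
            records.append(
                ScanRecord(subj, f"{subj}_V{i}", label, is_baseline=(i == baseline_idx))
            )
    return Cohort(records=records, series={})


def _random_records_cohort(rng, n_subjects=12):
    spec = []
    for i in range(n_subjects):
        n_scans = int(rng.integers(1, 4))
        baseline = int(rng.integers(0, n_scans)) if rng.random() > 0.2 else -1
        label = ["NC", "AD"][int(rng.integers(0, 2))]
        spec.append((f"s{i}", n_scans, label, baseline))
    cohort = _records_cohort(spec)
    n_base = sum(1 for s in spec if s[3] >= 0)
    return cohort, n_base


def _subjects(cohort, scan_ids):
    by_scan = {r.scan_id: r.subject_id for r in cohort.records}
    return {by_scan[s] for s in scan_ids}


class TestSubjectLevelFolds:
    def test_test_sets_are_disjoint_baseline_scans(self, rng):
        cohort = _records_cohort([(f"s{i}", 1, "NC" if i % 2 else "AD", 0) for i in range(10)])
        folds = T.make_subject_level_folds(cohort, k=5, seed=1)
        for f in folds:
            assert len(f.test_scan_ids) == 2
            assert not _subjects(cohort, f.train_scan_ids | f.val_scan_ids) & _subjects(
                cohort, f.test_scan_ids
            )

    def test_followups_of_held_out_subject_unused(self):
        spec = [(f"s{i}", 1, "NC", 0) for i in range(9)] + [("sx", 3, "AD", 0)]
        cohort = _records_cohort(spec)
        folds = T.make_subject_level_folds(cohort, k=5, seed=0)
        held = [f for f in folds if "sx_V0" in f.test_scan_ids]
        assert len(held) == 1
        f = held[0]
        # only baseline scans enter the test set; the held-out subject's
        # follow-ups are used nowhere in that fold
        assert all(s.endswith("_V0") for s in f.test_scan_ids)
        for follow in ("sx_V1", "sx_V2"):
            assert follow not in f.train_scan_ids | f.val_scan_ids | f.test_scan_ids

    def test_subject_without_baseline_in_every_training_pool(self):
        spec = [(f"s{i}", 1, "NC", 0) for i in range(8)] + [("snb", 2, "AD", -1)]
        cohort = _records_cohort(spec)
        for f in T.make_subject_level_folds(cohort, k=4, seed=0):
            pool = f.train_scan_ids | f.val_scan_ids
            assert {"snb_V0", "snb_V1"} <= pool

    def test_every_baseline_subject_tested_exactly_once(self, rng):
        cohort, _ = _random_records_cohort(rng, 20)
        folds = T.make_subject_level_folds(cohort, k=5, seed=3)
        tested = [s for f in folds for s in _subjects(cohort, f.test_scan_ids)]
        with_baseline = {
            r.subject_id for r in cohort.records if r.is_baseline
        }
        assert sorted(tested) == sorted(with_baseline)

    def test_subset_sizes_differ_by_at_most_one(self):
        cohort = _records_cohort([(f"s{i}", 1, "NC", 0) for i in range(13)])
        folds = T.make_subject_level_folds(cohort, k=5, seed=0)
        sizes = [len(f.test_scan_ids) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_insufficient_baseline_subjects_rejected(self):
        cohort = _records_cohort([("s1", 1, "NC", 0), ("s2", 1, "AD", 0)])
        with pytest.raises(ValueError):
            T.make_subject_level_folds(cohort, k=5)

    def test_no_leakage_over_many_random_cohorts(self):
        """Subjects never straddle the train/val vs test boundary."""
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(50):
            cohort, n_base = _random_records_cohort(rng, n_subjects=int(rng.integers(8, 25)))
            if n_base < 5:
                continue
            for f in T.make_subject_level_folds(cohort, k=5, seed=int(rng.integers(1000))):
                assert not _subjects(cohort, f.train_scan_ids | f.val_scan_ids) & _subjects(
                    cohort, f.test_scan_ids
                )
                assert all(
                    r.is_baseline
                    for r in cohort.records
                    if r.scan_id in f.test_scan_ids
                )
            checked += 1
        assert checked >= 40


class TestBinaryMetrics:
    def test_perfect_prediction(self):
        m = T.binary_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert (m["acc"], m["sen"], m["spe"]) == (100.0, 100.0, 100.0)

    def test_confusion_counts(self):
        # TP=2, FN=1, TN=2, FP=1
        y_true = [1, 1, 1, 0, 0, 0]
        y_pred = [1, 1, 0, 0, 0, 1]
        m = T.binary_metrics(y_true, y_pred)
        assert m["acc"] == pytest.approx(100 * 4 / 6)
        assert m["sen"] == pytest.approx(100 * 2 / 3)
        assert m["spe"] == pytest.approx(100 * 2 / 3)

    def test_all_positive_predictions(self):
        m = T.binary_metrics([1, 1, 0, 0], [1, 1, 1, 1])
        assert (m["sen"], m["spe"], m["acc"]) == (100.0, 0.0, 50.0)

    def test_missing_class_warns_and_reports_nan(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = T.binary_metrics([0, 0], [0, 1])
        assert np.isnan(m["sen"])


class TestMulticlassMetrics:
    def test_identity_predictions(self):
        m = T.multiclass_metrics([0, 1, 2, 3], [0, 1, 2, 3], 4)
        assert m["acc"] == 100.0
        assert m["per_class_acc"] == [100.0] * 4

    def test_per_class_recall(self):
        # class 0: 2/2 correct; class 1: 1/2 correct
        m = T.multiclass_metrics([0, 0, 1, 1], [0, 0, 0, 1], 4)
        assert m["acc"] == pytest.approx(75.0)
        assert m["per_class_acc"][0] == 100.0
        assert m["per_class_acc"][1] == 50.0
        assert np.isnan(m["per_class_acc"][2])

    def test_random_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        n = 4000
        y = np.repeat(np.arange(4), n // 4)
        pred = rng.integers(0, 4, size=n)
        m = T.multiclass_metrics(y, pred, 4)
        sigma = 100 * np.sqrt(0.25 * 0.75 / n)
        assert abs(m["acc"] - 25.0) < 3 * sigma


class TestRoc:
    def test_perfect_separation(self):
        r = T.roc_points([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert r["auc"] == pytest.approx(1.0)

    def test_constant_scores_give_chance(self):
        r = T.roc_points([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert r["auc"] == pytest.approx(0.5)

    def test_matches_concordant_pair_counting(self, rng):
        """AUC equals the Mann-Whitney probability of correct ranking."""
        y = np.array([0, 0, 0, 1, 1, 1])
        s = np.array([0.1, 0.4, 0.35, 0.3, 0.8, 0.9])
        pairs = [(a, b) for a in s[y == 1] for b in s[y == 0]]
        oracle = np.mean([1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs])
        assert T.roc_points(y, s)["auc"] == pytest.approx(oracle)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            T.roc_points([1, 1], [0.2, 0.9])

    def test_curve_is_monotone(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        r = T.roc_points(y, s)
        assert np.all(np.diff(r["fpr"]) >= 0)
        assert np.all(np.diff(r["tpr"]) >= 0)


class TestFit:
    def _tiny_data(self, rng, n=12, T_=8, N=5):
        X = rng.standard_normal((n, T_, N, N))
        y = np.arange(n) % 2
        X[y == 1] += 0.8  # crude but separable shift
        return X, y

    def _cfg(self):
        return M.CrnnConfig(s1=2, s2=2, s3=2, k1=2, k2=3, k3=4, stride3_time=2,
                            lstm_hidden=4, fc_sizes=(4,), n_classes=2, dropout_rate=0.0)

    def test_loss_decreases_on_separable_data(self, rng):
        X, y = self._tiny_data(rng)
        res = T.fit(X, y, X, y, self._cfg(), T.TrainConfig(epochs=15, batch_size=4, seed=0))
        assert res.history["train_loss"][-1] < res.history["train_loss"][0]
        # best-validation bookkeeping: the retained epoch indexes the recorded
        # minimum, and the convergence flag reports whether it preceded the budget
        h = res.history
        assert h["val_loss"][h["best_epoch"]] == min(h["val_loss"])
        assert h["converged"] == (h["best_epoch"] < 15 - 1)

    def test_same_seed_reproduces_loss_curve(self, rng):
        X, y = self._tiny_data(rng)
        tc = T.TrainConfig(epochs=5, batch_size=4, seed=42)
        h1 = T.fit(X, y, X, y, self._cfg(), tc).history
        h2 = T.fit(X, y, X, y, self._cfg(), tc).history
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_missing_class_rejected(self, rng):
        X, _ = self._tiny_data(rng)
        with pytest.raises(ValueError):
            T.fit(X, np.zeros(len(X), dtype=int), X[:2], np.array([0, 1]),
                  self._cfg(), T.TrainConfig(epochs=1))


def test_four_class_cross_validation(rng):
    """All four diagnostic stages, each with its own covariance signature:
    the multiclass path reports overall and per-class accuracy and beats
    chance (25%)."""
    from dfcrnn import synthetic as S
    from dfcrnn.io_cohort import trim_cohort

    base = S.exchangeable_correlation(12)
    states, schedules = {}, {}
    for gi, g in enumerate(["NC", "eMCI", "lMCI", "AD"]):
        edges = [(3 * gi, 3 * gi + 1), (3 * gi + 1, 3 * gi + 2)]
        states[g] = S.make_group_covariance(base, edges, 0.8)
        schedules[g] = [(g, 140)]
    cfg = S.SyntheticConfig(
        state_covariances=states, state_schedule_per_group=schedules,
        n_subjects_per_group=8, n_rois=12, seed=3,
    )
    cohort = trim_cohort(S.simulate_cohort(cfg), 3)
    res = T.cross_validate(
        cohort, SlidingWindowConfig(L=70, S=4),
        M.CrnnConfig(k1=4, k2=8, k3=8, lstm_hidden=8, n_classes=4),
        T.TrainConfig(epochs=100, batch_size=8, seed=0), k=3,
    )
    assert set(res.summary) == {"acc", "acc_NC", "acc_eMCI", "acc_lMCI", "acc_AD"}
    assert res.mean_accuracy > 35.0


def test_cross_validation_learns_separable_cohort(small_separable_cohort):
    """End-to-end smoke: the CRNN beats chance on a small injected-effect
    cohort under the subject-level protocol."""
    cfg = M.CrnnConfig(k1=4, k2=4, k3=8, lstm_hidden=8, n_classes=2)
    res = T.cross_validate(
        small_separable_cohort,
        SlidingWindowConfig(L=70, S=4),
        cfg,
        T.TrainConfig(epochs=80, batch_size=8, seed=1),
        k=3,
    )
    assert res.mean_accuracy > 60.0
    y_true = np.concatenate([o.y_true for o in res.outcomes])
    y_pred = np.concatenate([o.y_pred for o in res.outcomes])
    assert stats.binomtest(int((y_true == y_pred).sum()), len(y_true), 0.5,
                           alternative="greater").pvalue < 0.05
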