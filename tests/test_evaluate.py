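"""CV split algebra, confusion-matrix metrics, and minimal-set selection."""

import numpy as np
import pytest

import imuplace as ip
from imuplace.core import SurfaceClass as S
from imuplace.evaluate import EvaluationReport


@pytest.fixture(scope="module")
def dataset(small_trials):
    return ip.assemble_dataset(small_trials, ip.get_combination(21))


@pytest.fixture(scope="module")
def aug_dataset(small_trials):
    # 42 source trials x factor 5 = 210 patterns, 30 per surface
    return ip.assemble_dataset(
        small_trials, ip.get_combination(21), augment_factor=5, rng_seed=0
    )


def _label_coded_dataset(n_per_class=10, comb_num=1):
    """Patterns whose matrix constant encodes the surface label."""
    spec = ip.get_combination(comb_num)
    patterns = []
    for s in S:
        for i in range(n_per_class):
            patterns.append(
                ip.WalkPattern(
                    combination=spec,
                    surface=s,
                    matrix=np.full((spec.n_channels, 400), float(s.index)),
                    participant_id=i + 1,
                    trial_index=1,
                )
            )
    return ip.WalkPatternDataset(combination=spec, patterns=patterns)


def _stub_train_fn(reader):
    def fn(Xtr, ytr, Xval, yval, config, seed):
        return lambda X: reader(X)

    return fn


class TestMakeCvSplits:
    def test_ten_folds_give_ninety_ordered_splits(self, aug_dataset):
        splits = ip.make_cv_splits(aug_dataset, n_folds=10, seed=0)
        assert len(splits) == 90

    def test_three_folds_give_six_splits(self, dataset):
        assert len(ip.make_cv_splits(dataset, n_folds=3, seed=0)) == 6

    def test_each_split_partitions_the_dataset(self, dataset):
        n = len(dataset)
        for split in ip.make_cv_splits(dataset, n_folds=6, seed=1):
            tr, va, te = (
                set(split.train_indices),
                set(split.val_indices),
                set(split.test_indices),
            )
            assert tr & va == tr & te == va & te == set()
            assert tr | va | te == set(range(n))

    def test_each_fold_serves_as_test_n_minus_1_times(self, dataset):
        splits = ip.make_cv_splits(dataset, n_folds=6, seed=1)
        counts = {}
        for s in splits:
            counts[s.test_fold] = counts.get(s.test_fold, 0) + 1
        assert all(v == 5 for v in counts.values())

    def test_folds_are_class_stratified(self, small_trials):
        ds = ip.assemble_dataset(small_trials, ip.get_combination(5))
        splits = ip.make_cv_splits(ds, n_folds=6, seed=2)
        _, y = ds.stack()
        fold = splits[0].fold_assignment
        for f in range(6):
            classes, counts = np.unique(y[fold == f], return_counts=True)
            assert len(classes) == 7
            assert np.all(counts == 1)  # 42 patterns: 6 per class over 6 folds

    def test_proportions_are_80_10_10_for_ten_folds(self, small_trials):
        ds = ip.assemble_dataset(
            small_trials, ip.get_combination(5), augment_factor=5, rng_seed=0
        )  # 210 patterns, 30 per class
        split = ip.make_cv_splits(ds, n_folds=10, seed=0)[0]
        n = len(ds)
        assert len(split.train_indices) == int(0.8 * n)
        assert len(split.val_indices) == len(split.test_indices) == int(0.1 * n)

    def test_grouped_mode_keeps_augmented_siblings_together(self, small_trials):
        ds = ip.assemble_dataset(
            small_trials, ip.get_combination(5), augment_factor=5, rng_seed=0
        )
        splits = ip.make_cv_splits(ds, n_folds=6, seed=3, grouping="by_source_trial")
        groups = ds.group_ids()
        fold = splits[0].fold_assignment
        for g in np.unique(groups):
            assert len(np.unique(fold[groups == g])) == 1

    def test_too_many_folds_rejected(self, dataset):
        with pytest.raises(ValueError, match="fewer than n_folds"):
            ip.make_cv_splits(dataset, n_folds=12, seed=0)

    def test_non_divisible_counts_warn(self, small_trials):
        ds = ip.assemble_dataset(small_trials, ip.get_combination(5))
        with pytest.warns(UserWarning, match="not divisible"):
            ip.make_cv_splits(ds, n_folds=4, seed=0)


class TestConfusionMetrics:
    def test_stated_matrix_arithmetic(self):
        cm = np.diag([57, 54, 54, 60, 60, 60, 57])
        off = 60 - cm.sum(axis=1)
        for i, extra in enumerate(off):
            cm[i, (i + 1) % 7] += extra  # row sums 60
        np.testing.assert_allclose(
            ip.per_class_ccr(cm), [95, 90, 90, 100, 100, 100, 95]
        )
        assert ip.classification_accuracy(cm) == pytest.approx(95.714, abs=0.001)

    def test_weighted_ccr_recovers_ca(self, rng):
        for _ in range(50):
            cm = rng.integers(0, 30, size=(7, 7))
            cm[np.diag_indices(7)] += 1  # avoid empty rows
            rows = cm.sum(axis=1)
            ca = ip.classification_accuracy(cm)
            ccr = ip.per_class_ccr(cm)
            assert (rows * ccr).sum() / rows.sum() == pytest.approx(ca, rel=1e-12)


class TestEvaluateCombination:
    def test_oracle_predictor_scores_100(self):
        ds = _label_coded_dataset()
        splits = ip.make_cv_splits(ds, n_folds=5, seed=0)[:4]
        report = ip.evaluate_combination(
            ds, splits, train_fn=_stub_train_fn(lambda X: X[:, 0, 0].astype(int))
        )
        assert report.mean_ca == 100.0
        assert report.sd_ca == 0.0
        np.testing.assert_allclose(report.mean_ccr, 100.0)
        np.testing.assert_allclose(report.sd_ccr, 0.0)
        assert report.pass_flag

    def test_constant_predictor_scores_chance(self):
        ds = _label_coded_dataset()
        splits = ip.make_cv_splits(ds, n_folds=5, seed=0)[:2]
        report = ip.evaluate_combination(
            ds,
            splits,
            train_fn=_stub_train_fn(lambda X: np.zeros(len(X), dtype=int)),
        )
        np.testing.assert_allclose(report.mean_ccr, [100, 0, 0, 0, 0, 0, 0])
        assert report.mean_ca == pytest.approx(100.0 / 7.0)
        assert not report.pass_flag

    def test_training_failure_carries_split_context(self):
        ds = _label_coded_dataset()
        splits = ip.make_cv_splits(ds, n_folds=5, seed=0)[:1]

        def broken(*args):
            raise FloatingPointError("boom")

        with pytest.raises(RuntimeError, match="split"):
            ip.evaluate_combination(ds, splits, train_fn=broken)


def _fake_report(comb_num, mean_ccr, ca=95.0):
    spec = ip.get_combination(comb_num)
    ccr = np.tile(np.asarray(mean_ccr, dtype=float), (2, 1))
    return EvaluationReport(
        combination=spec,
        confusion_matrices=[],
        ca_per_split=np.array([ca, ca]),
        ccr_per_split=ccr,
    )


class TestSelection:
    def test_two_passing_pairs_give_minimal_cardinality_two(self):
        reports = [
            _fake_report(21, [95] * 7, ca=97.2),
            _fake_report(20, [92] * 7, ca=95.9),
            _fake_report(2, [95] * 6 + [40]),
            _fake_report(63, [99] * 7, ca=97.8),
        ]
        sel = ip.select_minimal_combinations(reports)
        assert sel.minimal_cardinality == 2
        assert [r.combination.comb_num for r in sel.best] == [21, 20]

    def test_empty_pass_set_reports_cleanly(self):
        reports = [_fake_report(21, [80] * 7), _fake_report(2, [10] * 7)]
        sel = ip.select_minimal_combinations(reports)
        assert sel.minimal_cardinality is None
        assert sel.best == []
        assert "no combination" in sel.summary()["note"]

    def test_pass_counts_grouped_by_cardinality(self):
        passing = (
            [(21, 2), (20, 2)]
            + [(n, 3) for n in (23, 38, 39, 22, 24, 25)]
            + [(n, 4) for n in range(42, 54)]
            + [(n, 5) for n in (57, 58, 59, 60)]
        )
        reports = [_fake_report(num, [95] * 7) for num, _ in passing]
        reports.append(_fake_report(2, [10] * 7))
        sel = ip.select_minimal_combinations(reports)
        assert sel.passes_by_cardinality() == {2: 2, 3: 6, 4: 12, 5: 4}
        assert sel.minimal_cardinality == 2

    def test_borderline_90_is_not_a_pass(self):
        rep = _fake_report(21, [90.0] * 7)
        assert not rep.pass_flag  # the criterion is strictly greater than 90%
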