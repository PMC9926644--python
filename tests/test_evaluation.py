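"""Evaluation protocol: schedule, subsampling, CV, aggregation, changes."""

import numpy as np
import pandas as pd
import pytest

from sizeval import (
    ClassifierSpec,
    EvaluationCurve,
    LabeledDataset,
    SampleSizeEvaluator,
    SimulationConfig,
    SubsampleSchedule,
    accuracy_change,
    aggregate_curve,
    build_schedule,
    crossval_accuracy,
    default_classifier_bank,
    generate_dataset,
    run_evaluation,
    subsample_balanced,
)
from sizeval.evaluation import effective_folds
from sizeval.errors import (
    ClassTooSmallError,
    DegenerateFoldError,
    EmptyGroupError,
    InsufficientDataError,
)

from conftest import two_class_dataset


def records_from_accuracies(acc_by_size_clf, d_average=0.5, d_grand=0.5):
    """Record table with explicit per-repetition accuracies.

    acc_by_size_clf: {size: {classifier: [accuracy per repetition]}}
    """
    rows = []
    for size, by_clf in acc_by_size_clf.items():
        for clf, accs in by_clf.items():
            for rep, a in enumerate(accs):
                rows.append({
                    "sample_size": size, "repetition": rep, "classifier": clf,
                    "accuracy": a, "d_average": d_average, "d_grand": d_grand,
                })
    return pd.DataFrame(rows)


class TestSchedule:
    def test_doubling_with_cap_appended(self):
        sched = build_schedule(5000)
        assert sched.sizes == (16, 32, 64, 128, 256, 512, 1024, 2048, 4096, 5000)

    def test_exact_minimum_gives_single_point(self):
        assert build_schedule(16).sizes == (16,)

    def test_below_floor_raises(self):
        with pytest.raises(InsufficientDataError):
            build_schedule(15)

    def test_odd_available_total_capped_to_even(self):
        assert build_schedule(129).sizes == (16, 32, 64, 128)

    def test_custom_sizes_validated(self):
        assert build_schedule(600, sizes=[20, 100, 500]).sizes == (20, 100, 500)
        with pytest.raises(InsufficientDataError):
            build_schedule(100, sizes=[16, 128])
        with pytest.raises(ValueError):
            SubsampleSchedule((16, 17))
        with pytest.raises(ValueError):
            SubsampleSchedule((32, 16))

    def test_protocol_defaults(self):
        sched = build_schedule(100)
        assert sched.sizes[0] == 16
        assert sched.repetitions == 100


class TestSubsampling:
    def test_full_draw_is_permutation_of_whole_dataset(self):
        rng = np.random.default_rng(0)
        ds = two_class_dataset(np.arange(20).reshape(10, 2), np.arange(100, 120).reshape(10, 2))
        sub = subsample_balanced(ds, 20, rng)
        assert sorted(map(tuple, sub.values)) == sorted(map(tuple, ds.values))

    def test_balanced_without_replacement(self):
        rng = np.random.default_rng(1)
        ds = two_class_dataset(
            np.arange(5000).reshape(2500, 2), np.arange(10000, 15000).reshape(2500, 2)
        )
        sub = subsample_balanced(ds, 16, rng)
        assert sub.class_counts() == {"a": 8, "b": 8}
        assert len(np.unique(sub.values, axis=0)) == 16

    def test_seeded_repeatability(self):
        ds = two_class_dataset(np.random.default_rng(0).normal(size=(50, 3)),
                               np.random.default_rng(1).normal(size=(50, 3)))
        s1 = subsample_balanced(ds, 30, np.random.default_rng(99))
        s2 = subsample_balanced(ds, 30, np.random.default_rng(99))
        assert np.array_equal(s1.values, s2.values)

    def test_class_too_small(self):
        ds = two_class_dataset(np.random.normal(size=(5, 2)), np.random.normal(size=(50, 2)))
        with pytest.raises(ClassTooSmallError):
            subsample_balanced(ds, 16, np.random.default_rng(0))

    def test_odd_total_rejected(self):
        ds = two_class_dataset(np.random.normal(size=(5, 2)), np.random.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            subsample_balanced(ds, 7, np.random.default_rng(0))


class TestCrossValidation:
    @pytest.mark.parametrize("family", ["support-vector", "logistic-regression",
                                        "neural-network"])
    def test_near_separable_data_scores_high(self, family):
        rng = np.random.default_rng(5)
        ds = two_class_dataset(rng.normal(0, 1, (32, 3)), rng.normal(10, 1, (32, 3)))
        acc, _ = crossval_accuracy(ds, ClassifierSpec(family), rng=0)
        assert acc >= 0.98

    @pytest.mark.parametrize("spec", default_classifier_bank(), ids=lambda s: s.label)
    def test_permuted_labels_score_at_chance(self, spec):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, (200, 5))
        labels = rng.permutation([0] * 100 + [1] * 100)
        ds = LabeledDataset(values, labels)
        acc, _ = crossval_accuracy(ds, spec, rng=1)
        assert 0.4 <= acc <= 0.6

    def test_fold_reduction_at_smallest_size(self):
        # 8 per class cannot support 10 stratified folds
        assert effective_folds(10, 8) == 8
        rng = np.random.default_rng(7)
        ds = two_class_dataset(rng.normal(0, 1, (8, 3)), rng.normal(2, 1, (8, 3)))
        acc, _ = crossval_accuracy(ds, ClassifierSpec("naive-bayes"), k=10, rng=0)
        assert 0.0 <= acc <= 1.0

    def test_too_few_samples_per_class(self):
        ds = two_class_dataset(np.random.normal(size=(1, 2)) * np.ones((1, 2)),
                               np.random.normal(size=(5, 2)))
        with pytest.raises((DegenerateFoldError, Exception)):
            crossval_accuracy(ds, ClassifierSpec("naive-bayes"), rng=0)

    def test_pooled_metrics_are_consistent(self):
        rng = np.random.default_rng(8)
        ds = two_class_dataset(rng.normal(0, 1, (40, 4)), rng.normal(1.5, 1, (40, 4)))
        acc, extra = crossval_accuracy(ds, ClassifierSpec("logistic-regression"),
                                       rng=2, metrics=True)
        assert set(extra) == {"auc_roc", "precision", "recall", "f1"}
        for v in extra.values():
            assert 0.0 <= v <= 1.0
        assert extra["auc_roc"] >= acc - 0.1  # separable data: ranking at least as good


class TestRunEvaluation:
    def test_record_cardinality(self, good_dataset):
        sched = SubsampleSchedule((16, 32), repetitions=3)
        records = run_evaluation(good_dataset, sched, seed=0)
        assert len(records) == 2 * 3 * 5
        counts = records.groupby(["sample_size", "classifier"]).size()
        assert (counts == 3).all()

    def test_identical_master_seed_gives_identical_tables(self, good_dataset):
        sched = SubsampleSchedule((16, 32), repetitions=2)
        specs = default_classifier_bank(("logistic-regression", "naive-bayes"))
        r1 = run_evaluation(good_dataset, sched, specs, seed=11)
        r2 = run_evaluation(good_dataset, sched, specs, seed=11)
        pd.testing.assert_frame_equal(r1, r2)

    def test_parallel_execution_matches_serial(self, good_dataset):
        sched = SubsampleSchedule((16,), repetitions=4)
        specs = default_classifier_bank(("naive-bayes",))
        serial = run_evaluation(good_dataset, sched, specs, seed=3, n_jobs=1)
        parallel = run_evaluation(good_dataset, sched, specs, seed=3, n_jobs=2)
        pd.testing.assert_frame_equal(serial, parallel)

    def test_learning_curve_rises_on_good_data(self, good_dataset):
        sched = SubsampleSchedule((16, 64, 256), repetitions=5)
        specs = default_classifier_bank(("logistic-regression", "support-vector"))
        curve = aggregate_curve(run_evaluation(good_dataset, sched, specs, seed=4))
        for clf in curve.classifiers:
            accs = [curve.mean_accuracy(s, clf) for s in curve.sizes]
            inversions = sum(b < a for a, b in zip(accs, accs[1:]))
            assert inversions <= 1, (clf, accs)

    def test_within_size_accuracy_sd_shrinks(self, good_dataset):
        sched = SubsampleSchedule((16, 256), repetitions=8)
        specs = default_classifier_bank(("logistic-regression",))
        curve = aggregate_curve(run_evaluation(good_dataset, sched, specs, seed=5))
        sd = curve.accuracy.set_index("sample_size")["accuracy_sd"]
        assert sd[16] > sd[256]


class TestAggregation:
    def test_zero_variance_collapses_ci(self):
        records = records_from_accuracies({16: {"LR": [0.8, 0.8, 0.8]}})
        curve = aggregate_curve(records)
        row = curve.accuracy.iloc[0]
        assert row["ci_low"] == row["mean_accuracy"] == row["ci_high"]
        assert row["mean_accuracy"] == pytest.approx(0.8)

    def test_two_point_mean_and_sd(self):
        records = records_from_accuracies({16: {"LR": [0.8, 0.9]}})
        row = aggregate_curve(records).accuracy.iloc[0]
        assert row["mean_accuracy"] == pytest.approx(0.85)
        assert row["accuracy_sd"] == pytest.approx(0.070710678, abs=1e-8)
        assert row["ci_low"] == pytest.approx(0.85 - 1.96 * 0.070710678 / np.sqrt(2))

    def test_cells_match_cardinality(self, good_dataset):
        sched = SubsampleSchedule((16, 32), repetitions=3)
        curve = aggregate_curve(run_evaluation(good_dataset, sched, seed=0))
        assert len(curve.accuracy) == 2 * 5
        assert len(curve.effect_sizes) == 2

    def test_single_repetition_rejected(self):
        records = records_from_accuracies({16: {"LR": [0.8]}})
        with pytest.raises(EmptyGroupError):
            aggregate_curve(records)

    def test_empty_rejected(self):
        with pytest.raises(EmptyGroupError):
            aggregate_curve(pd.DataFrame())

    def test_curve_json_round_trip(self, tmp_path, good_dataset):
        sched = SubsampleSchedule((16, 32), repetitions=2)
        curve = aggregate_curve(run_evaluation(good_dataset, sched, seed=1))
        path = tmp_path / "curve.json"
        curve.to_json(path)
        back = EvaluationCurve.from_json(path)
        pd.testing.assert_frame_equal(back.accuracy, curve.accuracy)
        pd.testing.assert_frame_equal(back.effect_sizes, curve.effect_sizes)
        assert back.dataset_fingerprint == curve.dataset_fingerprint


class TestAccuracyChange:
    def test_large_relative_change_instance(self):
        # 0.50 -> 0.71 is a 42% relative change
        records = records_from_accuracies(
            {16: {"LR": [0.50, 0.50]}, 32: {"LR": [0.71, 0.71]}}
        )
        change = aggregate_curve(records).changes
        assert change["change_pct"].tolist() == pytest.approx([42.0])

    def test_constant_accuracy_gives_zero_change(self):
        records = records_from_accuracies(
            {16: {"LR": [0.6, 0.6]}, 32: {"LR": [0.6, 0.6]}, 64: {"LR": [0.6, 0.6]}}
        )
        assert aggregate_curve(records).changes["change_pct"].tolist() == [0.0, 0.0]

    def test_criterion_boundary_instance(self):
        # 0.80 -> 0.88 is exactly a 10% relative change
        records = records_from_accuracies(
            {16: {"LR": [0.80, 0.80]}, 32: {"LR": [0.88, 0.88]}}
        )
        assert aggregate_curve(records).changes["change_pct"].tolist() == pytest.approx([10.0])

    def test_zero_accuracy_guarded(self):
        records = records_from_accuracies(
            {16: {"LR": [0.0, 0.0]}, 32: {"LR": [0.5, 0.5]}}
        )
        with pytest.warns(UserWarning, match="undefined"):
            curve = aggregate_curve(records)
        assert np.isnan(curve.changes["change_pct"].iloc[0])


class TestSampleSizeEvaluator:
    def test_estimator_contract_and_fit(self, good_dataset):
        ev = SampleSizeEvaluator(sizes=[16, 32], repetitions=2,
                                 families=("naive-bayes",), random_state=0)
        params = ev.get_params()
        assert params["repetitions"] == 2 and params["random_state"] == 0
        ev.fit(good_dataset)
        assert ev.schedule_.sizes == (16, 32)
        assert len(ev.records_) == 2 * 2 * 1
        assert set(ev.curve_.classifiers) == {"NB"}

    def test_default_schedule_from_data(self):
        config = SimulationConfig(n_per_class=24, n_variables=5, regime="good", seed=0)
        ds, _ = generate_dataset(config)
        ev = SampleSizeEvaluator(repetitions=2, families=("naive-bayes",), random_state=0)
        ev.fit(ds)
        assert ev.schedule_.sizes == (16, 32, 48)

    def test_accepts_plain_arrays(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(3, 1, (20, 3))])
        y = np.array([0] * 20 + [1] * 20)
        ev = SampleSizeEvaluator(sizes=[16], repetitions=2,
                                 families=("logistic-regression",), random_state=1)
        ev.fit(X, y)
        assert ev.curve_.mean_accuracy(16) > 0.8
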