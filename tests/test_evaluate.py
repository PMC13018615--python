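"""Outcome grouping, split protocol, metrics, models, ablation harness."""

import datetime

import numpy as np
import pandas as pd
import pytest
import sklearn.metrics

from riemecg import evaluate as E


def _outcome(pid="p", ve=25.0, pred=70.0, peak=1.4, date="2020-01-01"):
    return E.CpetOutcome(
        patient_id=pid, test_date=date, ve_vco2=ve, vo2_pred_pct=pred, vo2_peak=peak
    )


class TestGrouping:
    def test_normal_range_side_and_boundaries(self):
        scheme = E.GroupingScheme(vo2_peak_cut=1.5)
        g = E.group_cpet(_outcome(ve=25.0), scheme)
        assert g["ve_vco2"] == 0  # inside the 20-30 normal range
        # boundary values go to the upper group
        g = E.group_cpet(_outcome(ve=30.0, pred=60.0, peak=1.5), scheme)
        assert g == {"ve_vco2": 1, "vo2_pred_pct": 2, "vo2_peak": 1}

    def test_all_groups_realised_at_cut_midpoints(self):
        scheme = E.GroupingScheme(vo2_peak_cut=1.5)
        pred_vals = [40.0, 50.0, 70.0, 90.0]
        groups = {E.group_cpet(_outcome(pred=v), scheme)["vo2_pred_pct"] for v in pred_vals}
        assert groups == {0, 1, 2, 3}
        assert {E.group_cpet(_outcome(ve=v), scheme)["ve_vco2"] for v in (25.0, 35.0)} == {0, 1}

    def test_unset_peak_cut_rejected(self):
        with pytest.raises(ValueError, match="vo2_peak_cut"):
            E.group_cpet(_outcome(), E.GroupingScheme())

    def test_invalid_outcome_values(self):
        with pytest.raises(ValueError):
            _outcome(ve=-1.0)
        with pytest.raises(ValueError):
            _outcome(pred=250.0)


class TestSplitPlan:
    CLASSES = {f"p{i}": i % 5 for i in range(40)}

    def test_one_test_patient_per_class_no_overlap(self):
        plan = E.make_split_plan(self.CLASSES, n_repeats=100, seed=3)
        assert plan.n_repeats == 100
        for train, test in plan:
            assert len(test) == 5  # one per lesion class
            assert {self.CLASSES[p] for p in test} == set(range(5))
            assert not (train & test)
            assert train | test == set(self.CLASSES)

    def test_deterministic_under_seed(self):
        p1 = E.make_split_plan(self.CLASSES, n_repeats=20, seed=9)
        p2 = E.make_split_plan(self.CLASSES, n_repeats=20, seed=9)
        assert p1 == p2
        p3 = E.make_split_plan(self.CLASSES, n_repeats=20, seed=10)
        assert p1 != p3

    def test_selection_frequencies_within_binomial_bound(self):
        plan = E.make_split_plan(self.CLASSES, n_repeats=100, seed=1)
        counts = {p: 0 for p in self.CLASSES}
        for _, test in plan:
            for p in test:
                counts[p] += 1
        bound = 3 * np.sqrt(0.25 / 100)
        for pid, c in counts.items():
            k = sum(1 for q in self.CLASSES.values() if q == self.CLASSES[pid])
            assert abs(c / 100 - 1 / k) <= bound

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="'b'"):
            E.make_split_plan({"p1": "a", "p2": "a", "p3": "b"}, n_repeats=5, seed=0)


class TestRegressionMetrics:
    def test_hand_example(self):
        y, yhat = [1.0, 2.0, 3.0], [2.0, 2.0, 2.0]
        assert E.r_squared(y, yhat) == pytest.approx(0.0)
        assert E.rmse(y, yhat) == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_perfect_and_mean_prediction_limits(self, rng):
        y = rng.standard_normal(50)
        assert E.r_squared(y, y) == pytest.approx(1.0)
        assert E.rmse(y, y) == 0.0
        assert E.pearson_r(y, y) == pytest.approx(1.0)
        assert E.r_squared(y, np.full(50, y.mean())) == pytest.approx(0.0)

    def test_r_squared_can_be_negative(self, rng):
        y = rng.standard_normal(30)
        assert E.r_squared(y, -3 * y + 5) < 0

    def test_agreement_with_sklearn_to_1e10(self, rng):
        for _ in range(100):
            y = rng.standard_normal(20)
            yhat = rng.standard_normal(20)
            assert E.r_squared(y, yhat) == pytest.approx(
                sklearn.metrics.r2_score(y, yhat), abs=1e-10
            )
            assert E.rmse(y, yhat) == pytest.approx(
                sklearn.metrics.mean_squared_error(y, yhat) ** 0.5, abs=1e-10
            )
            assert E.pearson_r(y, yhat) == pytest.approx(
                np.corrcoef(y, yhat)[0, 1], abs=1e-12
            )

    def test_r2_rmse_sst_identity(self, rng):
        """Algebraic cross-check: R^2 == 1 - n*RMSE^2 / SST."""
        y = rng.standard_normal(40)
        yhat = y + 0.3 * rng.standard_normal(40)
        sst = np.sum((y - y.mean()) ** 2)
        assert E.r_squared(y, yhat) == pytest.approx(
            1.0 - len(y) * E.rmse(y, yhat) ** 2 / sst, rel=1e-12
        )

    def test_adjusted_r_squared(self, rng):
        y = rng.standard_normal(30)
        yhat = y + 0.1 * rng.standard_normal(30)
        r2 = E.r_squared(y, yhat)
        assert E.adjusted_r_squared(y, yhat, p=4) == pytest.approx(
            1 - (1 - r2) * 29 / (30 - 4 - 1)
        )
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(E.adjusted_r_squared(y, yhat, p=29))

    def test_zero_variance_target_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero variance"):
            assert np.isnan(E.r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1])
        scores = np.array([-1.0, 2.0, -2.0, 1.0])
        m = E.classification_metrics(y, y, scores, classes=[0, 1])
        assert m == {"accuracy": 1.0, "f1_macro": 1.0, "auc": 1.0}

    def test_constant_classifier_confusion_example(self):
        # class counts {4, 1}, always predicting the majority
        y = np.array([0, 0, 0, 0, 1])
        yhat = np.zeros(5, dtype=int)
        m = E.classification_metrics(y, yhat)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["f1_macro"] == pytest.approx((8 / 9 + 0.0) / 2, abs=1e-6)

    def test_reversed_scores_flip_auc(self, rng):
        y = rng.integers(0, 2, size=40)
        scores = y + 0.5 * rng.standard_normal(40)
        auc = E.macro_ovr_auc(y, scores, [0, 1])
        assert E.macro_ovr_auc(y, -scores, [0, 1]) == pytest.approx(1.0 - auc)

    def test_single_class_fold_gives_nan_auc(self):
        assert np.isnan(E.macro_ovr_auc(np.zeros(4, int), np.arange(4.0), [0, 1]))

    def test_multiclass_macro_ovr_matches_sklearn(self, rng):
        y = rng.integers(0, 4, size=60)
        scores = rng.standard_normal((60, 4)) + np.eye(4)[y]
        expected = np.mean(
            [
                sklearn.metrics.roc_auc_score((y == k).astype(int), scores[:, k])
                for k in range(4)
            ]
        )
        assert E.macro_ovr_auc(y, scores, [0, 1, 2, 3]) == pytest.approx(expected, abs=1e-12)


class TestFitPredict:
    def test_separable_classes_perfect_accuracy(self, rng):
        x0 = rng.standard_normal((30, 5))
        x1 = rng.standard_normal((30, 5)) + 8.0
        X = np.vstack([x0, x1])
        y = np.array([0] * 30 + [1] * 30)
        pred, scores, classes = E.fit_predict(X, y, X, "classification")
        assert np.array_equal(pred, y)
        assert classes == [0, 1]

    def test_noiseless_linear_regression_r2_one(self, rng):
        X = rng.standard_normal((40, 3))
        w = np.array([1.0, -2.0, 0.5])
        y = X @ w + 4.0
        pred, _, _ = E.fit_predict(X, y, X, "regression", E.ModelConfig(kind="baseline"))
        assert E.r_squared(y, pred) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_single_class_fold_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="single-class"):
            E.fit_predict(X, np.zeros(10, int), X, "classification")

    def test_model_config_round_trips(self):
        cfg = E.ModelConfig(kind="svm", C=2.0, epsilon=0.05)
        assert E.ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestCpetCsv:
    def test_round_trip(self, tmp_path):
        outs = [_outcome("p1"), _outcome("p2", ve=33.0, date="2021-05-05")]
        path = tmp_path / "cpet.csv"
        E.write_cpet_csv(outs, path)
        back = E.read_cpet_csv(path)
        assert [(o.patient_id, o.test_date, o.ve_vco2) for o in back] == [
            (o.patient_id, o.test_date, o.ve_vco2) for o in outs
        ]


class TestAblationHarness:
    def test_arms_share_split_plan_and_report_shape(self, small_dataset):
        plan = E.make_split_plan(small_dataset.class_by_patient, n_repeats=5, seed=4)
        arms = ("tangent_ecg", "tangent_ecg+text")
        rep = E.run_ablation(
            small_dataset, plan, "classification", labels=["ve_vco2"], arms=arms, seed=5
        )
        # one row per arm x label x metric
        assert len(rep) == len(arms) * 1 * 3
        assert set(rep.columns) == {"arm", "label", "metric", "mean", "std", "n_valid_repeats"}
        assert set(rep.arm) == set(arms)
        assert (rep.n_valid_repeats <= 5).all()

    def test_unknown_arm_rejected(self, small_dataset):
        plan = E.make_split_plan(small_dataset.class_by_patient, n_repeats=2, seed=0)
        with pytest.raises(ValueError, match="unknown arms"):
            E.run_ablation(small_dataset, plan, "classification", arms=("nope",))

    def test_deterministic_report(self, small_dataset):
        plan = E.make_split_plan(small_dataset.class_by_patient, n_repeats=4, seed=2)
        kw = dict(labels=["vo2_peak"], arms=("tangent_ecg", "tangent_ecg+text+cov_aug"), seed=6)
        r1 = E.run_ablation(small_dataset, plan, "classification", **kw)
        r2 = E.run_ablation(small_dataset, plan, "classification", **kw)
        pd.testing.assert_frame_equal(r1, r2)

    def test_regression_task_reports_expected_metrics(self, small_dataset):
        plan = E.make_split_plan(small_dataset.class_by_patient, n_repeats=3, seed=1)
        rep = E.run_ablation(
            small_dataset, plan, "regression", labels=["ve_vco2"], arms=("tangent_ecg",), seed=0
        )
        assert set(rep.metric) == {"r2", "rmse", "pearson_r"}

    def test_text_missing_patients_dropped_from_all_arms(self, small_dataset):
        import copy

        ds = E.CohortDataset(entries=[copy.copy(e) for e in small_dataset.entries])
        ds.entries[0].doc = None
        missing_pid = ds.entries[0].patient_id
        plan = E.make_split_plan(ds.class_by_patient, n_repeats=2, seed=0)
        with pytest.warns(RuntimeWarning, match="text-missing"):
            E.run_ablation(
                ds, plan, "classification", labels=["ve_vco2"],
                arms=("tangent_ecg", "tangent_ecg+text"), seed=0,
            )

    def test_leakage_guard_trips_on_test_sources(self, small_dataset):
        from riemecg.augment import FusedSample

        s = FusedSample(patient_id="x", label=0)
        with pytest.raises(AssertionError, match="leakage"):
            E._assert_no_leakage([s], train_ids={"a"}, test_ids={"x"})
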