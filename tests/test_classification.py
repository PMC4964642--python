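"""MCC, discriminant fits, homology-grouped cross-validation."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from pcnfold import fit_discriminant, grouped_kfold_cv, matthews_cc
from pcnfold.classification import LabeledDataset, _assign_folds
from pcnfold.errors import ConfigurationError, PcnfoldError
from pcnfold.synthetic import make_two_class_features


class TestMatthewsCC:
    def test_perfect_prediction(self):
        assert matthews_cc(5, 5, 0, 0) == pytest.approx(1.0)

    def test_total_disagreement(self):
        assert matthews_cc(0, 0, 5, 5) == pytest.approx(-1.0)

    def test_direct_formula(self):
        assert matthews_cc(2, 3, 1, 1) == pytest.approx(5 / 12)

    def test_zero_denominator_convention(self):
        assert matthews_cc(4, 0, 0, 3) == 0.0

    def test_all_zero_undefined(self):
        with pytest.raises(PcnfoldError):
            matthews_cc(0, 0, 0, 0)

    def test_matches_sklearn_on_random_confusions(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 8, size=4)
            if tp + tn + fp + fn == 0:
                continue
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            assert matthews_cc(tp, tn, fp, fn) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestFitDiscriminant:
    def test_wide_separation_classifies_training_set(self):
        data = make_two_class_features(
            n_per_class=20, means=((-10.0,), (10.0,)),
            covariances=([[0.01]], [[0.01]]), seed=1)
        for mode in ("linear", "quadratic"):
            model = fit_discriminant(data, ["f1"], mode=mode)
            pred = model.predict(data.features[["f1"]].to_numpy())
            assert (pred == np.asarray(data.labels)).all()

    def test_identical_distributions_predict_majority(self, rng):
        # 30 MS vs 10 TS drawn from the same cloud: prior dominates
        import pandas as pd
        pts = rng.normal(size=(40, 1))
        data = LabeledDataset(
            ids=[f"p{i}" for i in range(40)],
            features=pd.DataFrame(pts, columns=["f1"]),
            labels=["MS"] * 30 + ["TS"] * 10,
            groups=[f"g{i}" for i in range(40)],
        )
        model = fit_discriminant(data, ["f1"], mode="linear")
        pred = model.predict(pts)
        assert (pred == "MS").mean() > 0.9

    def test_1d_boundary_matches_analytic_posterior_equality(self, rng):
        from scipy.optimize import brentq
        data = make_two_class_features(
            n_per_class=60, means=((0.0,), (4.0,)),
            covariances=([[1.0]], [[2.5]]), seed=7)
        model = fit_discriminant(data, ["f1"], mode="quadratic")
        X = data.features["f1"].to_numpy()
        y = np.asarray(data.labels)
        stats = {}
        for c in np.unique(y):
            xs = X[y == c]
            stats[c] = (xs.mean(), xs.var(ddof=1), len(xs) / len(y))
        (m0, v0, p0), (m1, v1, p1) = stats[model.classes_[0]], stats[model.classes_[1]]

        def log_post_diff(x):
            a = -0.5 * np.log(v0) - (x - m0) ** 2 / (2 * v0) + np.log(p0)
            b = -0.5 * np.log(v1) - (x - m1) ** 2 / (2 * v1) + np.log(p1)
            return a - b

        analytic = brentq(log_post_diff, m0, m1, xtol=1e-12)

        def model_diff(x):
            lp = model.predict_proba([[x]])[0]
            return np.log(lp[0]) - np.log(lp[1])

        fitted = brentq(model_diff, m0, m1, xtol=1e-12)
        assert fitted == pytest.approx(analytic, abs=1e-6)

    def test_unknown_feature_rejected(self):
        data = make_two_class_features(n_per_class=10, seed=0)
        with pytest.raises(ConfigurationError):
            fit_discriminant(data, ["nope"])


class TestGroupedFolds:
    def test_groups_never_split(self, rng):
        groups = [f"g{i // 3}" for i in range(60)]  # 20 groups of 3
        for _ in range(100):
            folds = _assign_folds(groups, 10, rng)
            for g in set(groups):
                fold_set = {folds[i] for i, gi in enumerate(groups) if gi == g}
                assert len(fold_set) == 1

    def test_fewer_groups_than_folds(self, rng):
        with pytest.raises(ConfigurationError):
            _assign_folds(["a", "b", "c"], 10, rng)


class TestGroupedKFoldCV:
    def test_separable_clouds_recovered(self):
        data = make_two_class_features(n_per_class=50, group_size=2, seed=11)
        report = grouped_kfold_cv(data, ["f1", "f2"], n_resamplings=100, seed=5)
        assert report.overall_accuracy[0] > 95.0
        assert report.mcc[0] > 0.9
        n = len(data) * report.n_resamplings
        assert sum(report.confusion_totals.values()) == n

    def test_permuted_labels_give_null_mcc(self, rng):
        data = make_two_class_features(n_per_class=100, group_size=1, seed=2)
        labels = list(data.labels)
        perm = rng.permutation(len(labels))
        shuffled = LabeledDataset(ids=data.ids, features=data.features,
                                  labels=[labels[i] for i in perm],
                                  groups=data.groups)
        report = grouped_kfold_cv(shuffled, ["f1", "f2"],
                                  n_resamplings=60, seed=3)
        assert abs(report.mcc[0]) < 0.1

    def test_identical_seed_identical_report(self):
        data = make_two_class_features(n_per_class=30, seed=4)
        a = grouped_kfold_cv(data, ["f1", "f2"], n_resamplings=25, seed=9)
        b = grouped_kfold_cv(data, ["f1", "f2"], n_resamplings=25, seed=9)
        assert a.to_json() == b.to_json()

    def test_mean_stabilizes_with_more_resamplings(self):
        """Independent short and long runs agree within a few standard
        errors of the short run's mean (the mean converges ~1/sqrt(n))."""
        data = make_two_class_features(
            n_per_class=30, means=((0.0, 0.0), (2.0, 2.0)), seed=6)
        short = grouped_kfold_cv(data, ["f1", "f2"], n_resamplings=150, seed=1)
        long = grouped_kfold_cv(data, ["f1", "f2"], n_resamplings=1500, seed=2)
        sem_short = short.overall_accuracy[1] / np.sqrt(150)
        assert abs(short.overall_accuracy[0] - long.overall_accuracy[0]) \
            < 5 * sem_short + 0.5

    def test_feature_subsets_of_all_orders(self):
        data = make_two_class_features(
            n_per_class=24, means=((0, 0, 0, 0), (3, 3, 3, 3)),
            covariances=(np.eye(4), np.eye(4)), seed=8)
        for subset in (["f1"], ["f1", "f2"], ["f1", "f2", "f3"],
                       ["f1", "f2", "f3", "f4"]):
            report = grouped_kfold_cv(data, subset, n_resamplings=10, seed=0)
            assert 0 <= report.overall_accuracy[0] <= 100
            assert -1 <= report.mcc[0] <= 1
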