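"""Confusion metrics, LOOCV, tuning, forward selection, ROC, summed rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn import metrics as skmetrics

from msfgait.errors import InputError
from msfgait.features import FeatureTable
from msfgait.model_eval import (
    ConfusionCounts,
    MetricSet,
    ModelSpec,
    confusion_metrics,
    forward_select,
    loocv_evaluate,
    mean_roc,
    roc_and_auc,
    summed_rank,
    tune_hyperparameters,
)


def _make_table(X: np.ndarray, y01: np.ndarray, prefix="f") -> FeatureTable:
    cols = [f"{prefix}{i}" for i in range(X.shape[1])]
    data = pd.DataFrame(X, columns=cols,
                        index=[f"P{i}" for i in range(len(X))])
    labels = pd.Series(np.where(y01 == 1, "autism", "control"), index=data.index)
    return FeatureTable(data, labels, {c: "G" for c in cols})


def _cluster_table(n1=19, n0=21, d=4, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(sep, 1.0, (n1, d)), rng.normal(0.0, 1.0, (n0, d))]
    )
    y = np.array([1] * n1 + [0] * n0)
    return _make_table(X, y), y


class TestConfusionMetrics:
    def test_all_control_classifier_worked_example(self):
        ms = confusion_metrics(ConfusionCounts(TP=0, FN=19, TN=21, FP=0))
        assert ms.accuracy == pytest.approx(0.525)
        assert ms.sensitivity == 0.0
        assert ms.specificity == 1.0
        assert ms.ppv == 0.0
        assert ms.f1 == 0.0
        assert ms.mcc == 0.0
        # NPV follows TN/(TN+FN) exactly
        assert ms.npv == pytest.approx(21 / 40)

    def test_perfect_classifier(self):
        ms = confusion_metrics(ConfusionCounts(TP=19, TN=21, FP=0, FN=0))
        for v in (ms.accuracy, ms.sensitivity, ms.specificity, ms.ppv, ms.npv,
                  ms.f1, ms.mcc):
            assert v == 1.0

    def test_random_counts_match_sklearn_oracle(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 30, 4)
            if tp + fp + tn + fn == 0:
                continue
            ms = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            assert ms.accuracy == pytest.approx(
                skmetrics.accuracy_score(y_true, y_pred)
            )
            assert ms.f1 == pytest.approx(
                skmetrics.f1_score(y_true, y_pred, zero_division=0)
            )
            assert ms.mcc == pytest.approx(
                skmetrics.matthews_corrcoef(y_true, y_pred), abs=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            ConfusionCounts(-1, 0, 0, 5)


class TestLoocv:
    def test_separable_clusters_perfect_accuracy(self):
        table, _ = _cluster_table()
        ms, scores, counts = loocv_evaluate(
            table, ModelSpec(kernel="linear", C=1.0)
        )
        assert ms.accuracy == 1.0
        assert counts.total == 40
        assert len(scores) == 40

    def test_positive_scores_point_to_autism(self):
        table, y = _cluster_table(seed=3)
        _, scores, _ = loocv_evaluate(table, ModelSpec(kernel="linear"))
        assert np.all(scores[y == 1] > 0) and np.all(scores[y == 0] < 0)

    def test_permuted_labels_mcc_near_zero(self):
        mccs = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 6))
            y = rng.permutation([1] * 19 + [0] * 21)
            ms, _, _ = loocv_evaluate(_make_table(X, y), ModelSpec(kernel="rbf"))
            mccs.append(ms.mcc)
        assert abs(np.mean(mccs)) < 0.15

    def test_one_sample_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(InputError):
            loocv_evaluate(_make_table(X, y), ModelSpec())


class TestTuning:
    def test_singleton_grid_returned(self):
        table, _ = _cluster_table()
        spec = tune_hyperparameters(table, "rbf", c_grid=(3.0,), gamma_grid=(0.01,))
        assert spec.C == 3.0 and spec.gamma == 0.01

    def test_tie_returns_smallest_c(self):
        # constant features: every model predicts the majority class,
        # all grid points score identically
        X = np.ones((20, 3))
        y = np.array([1] * 9 + [0] * 11)
        spec = tune_hyperparameters(_make_table(X, y), "linear",
                                    c_grid=(10.0, 0.1, 1.0))
        assert spec.C == 0.1

    def test_recovers_separating_model_on_clusters(self):
        table, _ = _cluster_table(sep=3.0, seed=5)
        spec = tune_hyperparameters(table, "rbf")
        ms, _, _ = loocv_evaluate(table, spec)
        assert ms.accuracy > 0.9


class TestForwardSelect:
    @staticmethod
    def _informative_table(seed, n_noise=8):
        rng = np.random.default_rng(seed)
        y = np.array([1] * 19 + [0] * 21)
        X = rng.normal(size=(40, n_noise + 1))
        X[:, 0] += y * 4.0  # only feature 0 carries signal
        return _make_table(X, y), "f0"

    def test_informative_feature_chosen_first_majority_of_seeds(self):
        hits = 0
        for seed in range(10):
            table, signal = self._informative_table(seed)
            selected, _ = forward_select(
                table, table.feature_names, ModelSpec(kernel="linear"), seed=seed
            )
            hits += selected[0] == signal
        assert hits >= 8

    def test_identical_features_plateau_after_one(self):
        X = np.tile(np.random.default_rng(0).normal(size=(40, 1)), (1, 5))
        y = np.array([1] * 19 + [0] * 21)
        table = _make_table(X, y)
        selected, _ = forward_select(table, table.feature_names, ModelSpec())
        assert len(selected) == 1

    def test_first_pick_matches_brute_force(self):
        table, _ = self._informative_table(seed=4, n_noise=4)
        spec = ModelSpec(kernel="linear")
        from msfgait.model_eval import _cv_accuracy, _encode

        y = _encode(table.labels)
        singles = {
            f: _cv_accuracy(table.data[[f]].to_numpy(float), y, spec, seed=0)
            for f in table.feature_names
        }
        best_single = max(
            table.feature_names, key=lambda f: (singles[f], -table.feature_names.index(f))
        )
        selected, _ = forward_select(table, table.feature_names, spec, seed=0)
        assert selected[0] == best_single

    def test_empty_candidates_rejected(self, default_table):
        with pytest.raises(InputError):
            forward_select(default_table, [], ModelSpec())


class TestRocAuc:
    def test_scores_equal_labels_auc_one(self):
        y = np.array([1, 0, 1, 0, 1])
        _, _, auc = roc_and_auc(y.astype(float), y)
        assert auc == 1.0

    def test_auc_equals_mann_whitney_statistic(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            s = rng.normal(size=30)
            _, _, auc = roc_and_auc(s, y)
            u = stats.mannwhitneyu(s[y == 1], s[y == 0]).statistic
            assert auc == pytest.approx(u / (np.sum(y == 1) * np.sum(y == 0)))

    def test_uninformative_scores_auc_near_half(self, rng):
        aucs = []
        for _ in range(100):
            y = np.array([1] * 19 + [0] * 21)
            aucs.append(roc_and_auc(rng.normal(size=40), y)[2])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_one_class_rejected(self):
        with pytest.raises(InputError):
            roc_and_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_mean_roc_of_identical_curves(self):
        y = np.array([1] * 10 + [0] * 10)
        s = np.arange(20.0)[::-1] * np.where(y == 1, 1, -1)
        fpr, tpr, _ = roc_and_auc(s, y)
        grid, mtpr, auc = mean_roc([(fpr, tpr), (fpr, tpr)])
        assert len(grid) == 101
        assert auc == pytest.approx(1.0, abs=0.01)


class TestSummedRank:
    @staticmethod
    def _ms(**kw):
        base = dict(accuracy=0.5, sensitivity=0.5, specificity=0.5, ppv=0.5,
                    npv=0.5, f1=0.5, mcc=0.0)
        base.update(kw)
        return MetricSet(**base)

    def test_dominant_model_ranked_first(self):
        models = {
            "A": self._ms(accuracy=0.9, f1=0.9, mcc=0.8),
            "B": self._ms(accuracy=0.6, f1=0.6, mcc=0.2),
        }
        out = summed_rank(models)
        assert out.index[0] == "A" and out["final_rank"]["A"] == 1

    def test_identical_models_share_sr_deterministic_order(self):
        models = {"B": self._ms(), "A": self._ms()}
        out = summed_rank(models)
        assert out["SR"]["A"] == out["SR"]["B"]
        assert list(out.index) == ["A", "B"]  # name breaks the tie

    def test_matches_independent_ranking_oracle(self, rng):
        names = ["M1", "M2", "M3", "M4"]
        models = {
            n: self._ms(
                accuracy=rng.uniform(), sensitivity=rng.uniform(),
                specificity=rng.uniform(), ppv=rng.uniform(), npv=rng.uniform(),
                f1=rng.uniform(), mcc=rng.uniform(-1, 1),
            )
            for n in names
        }
        out = summed_rank(models)
        # independent oracle: midranks computed per metric by sorting
        expected_sr = {n: 0.0 for n in names}
        for metric in ("accuracy", "sensitivity", "specificity", "ppv", "npv",
                       "f1", "mcc"):
            vals = {n: getattr(models[n], metric) for n in names}
            for n in names:
                better = sum(v > vals[n] for v in vals.values())
                equal = sum(v == vals[n] for v in vals.values())
                expected_sr[n] += better + (equal + 1) / 2
        for n in names:
            assert out["SR"][n] == pytest.approx(expected_sr[n])

    def test_invariant_to_metric_order(self):
        models = {
            "A": self._ms(accuracy=0.9, mcc=0.4),
            "B": self._ms(accuracy=0.7, mcc=0.6),
            "C": self._ms(accuracy=0.8, mcc=0.5),
        }
        a = summed_rank(models, metrics=("accuracy", "mcc", "f1"))
        b = summed_rank(models, metrics=("f1", "mcc", "accuracy"))
        pd.testing.assert_series_equal(a["SR"], b["SR"])

    def test_single_model_rejected(self):
        with pytest.raises(InputError):
            summed_rank({"A": self._ms()})
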