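"""Logistic fits, stepwise selection, and diagnostic performance metrics."""

import numpy as np
import pandas as pd
import pytest

from inkcog.classify import (
    StepwiseLogisticModel,
    classify_metrics,
    delong_auc_ci,
    fit_logistic,
    forward_stepwise,
    task_average_performance,
)
from inkcog.errors import UndefinedMetricError


def binary_table_data(tp, fn, tn, fp):
    """Single binary predictor x, outcome y realizing the 2x2 counts."""
    x = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp, dtype=float)
    y = np.array([1] * (tp + fn) + [0] * (tn + fp), dtype=float)
    return x, y


class TestLogisticFit:
    def test_two_by_two_odds_ratio_closed_form(self):
        # OR = (30*25)/(10*15) = 5.0 for tp/fn/tn/fp = 30/10/25/15
        x, y = binary_table_data(30, 10, 25, 15)
        fit = fit_logistic(x, y)
        assert np.exp(fit.params[1]) == pytest.approx(5.0, rel=1e-6)

    def test_duplicating_rows_leaves_coefficients_unchanged(self, rng):
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + rng.normal(size=60) > 0).astype(float)
        a = fit_logistic(X, y)
        b = fit_logistic(np.vstack([X, X]), np.concatenate([y, y]))
        assert a.params == pytest.approx(b.params, rel=1e-6)

    def test_null_features_rarely_significant(self, rng):
        """Labels independent of the feature: Wald p > .05 in >= 90% of reps."""
        quiet = 0
        for _ in range(200):
            x = rng.normal(size=100)
            y = rng.integers(0, 2, 100).astype(float)
            fit = fit_logistic(x, y)
            quiet += fit.pvalues[1] > 0.05
        assert quiet >= 180

    def test_perfect_separation_is_flagged_not_fatal(self):
        x = np.array([0.0, 0.1, 0.2, 0.3, 2.0, 2.1, 2.2, 2.3])
        y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        fit = fit_logistic(x, y)
        assert fit.separation


class TestStepwiseSelection:
    def _one_signal_data(self, rng, n=400, noise_features=9):
        signal = rng.normal(0, 1, n)
        y = np.where(signal + rng.normal(0, 0.55, n) > 0, "MCI", "HC")
        X = pd.DataFrame(
            rng.normal(size=(n, noise_features)),
            columns=[f"noise_{j}" for j in range(noise_features)],
        )
        X.insert(3, "signal", signal)
        return X, y

    def test_predictive_feature_selected_first(self, rng):
        """One strongly predictive feature among 9 noise features is the
        first entry in every one of 20 replicates."""
        first = 0
        for _ in range(20):
            X, y = self._one_signal_data(rng)
            model = forward_stepwise(X, y)
            first += model.fit_log_[0]["feature"] == "signal"
        assert first == 20

    def test_all_noise_often_selects_nothing(self, rng):
        """With a single noise candidate, selection is empty in about 95%
        of replicates (per-candidate entry at alpha=.05)."""
        empty = 0
        for _ in range(100):
            X = pd.DataFrame({"noise": rng.normal(size=120)})
            y = np.array(["MCI", "HC"])[rng.integers(0, 2, 120)]
            empty += len(forward_stepwise(X, y).selected_) == 0
        assert empty >= 85

    def test_zero_entry_threshold_selects_nothing(self, rng):
        X, y = self._one_signal_data(rng, n=100)
        model = StepwiseLogisticModel(entry_p=0.0).fit(X, y)
        assert model.selected_ == []
        # intercept-only model predicts the base rate for everyone
        proba = model.predict_proba(X)[:, 1]
        assert np.allclose(proba, proba[0])

    def test_unit_thresholds_reduce_to_greedy_full_inclusion(self, rng):
        X, y = self._one_signal_data(rng, n=150, noise_features=3)
        model = StepwiseLogisticModel(entry_p=1.0, removal_p=1.0).fit(X, y)
        assert set(model.selected_) == set(X.columns)

    def test_deterministic_given_identical_input(self, rng):
        X, y = self._one_signal_data(rng, n=200)
        a = forward_stepwise(X, y)
        b = forward_stepwise(X, y)
        assert a.selected_ == b.selected_
        assert a.coef_ == pytest.approx(b.coef_)

    def test_or_equals_exp_beta_with_ordered_ci(self, rng):
        X, y = self._one_signal_data(rng, n=300)
        t = forward_stepwise(X, y).params_table_
        assert np.allclose(t["or"], np.exp(t["beta"]))
        assert (t["or_ci_low"] <= t["or"]).all() and (t["or"] <= t["or_ci_high"]).all()

    def test_sklearn_estimator_contract(self, rng):
        from sklearn.base import clone

        X, y = self._one_signal_data(rng, n=150)
        model = StepwiseLogisticModel(entry_p=0.01)
        cloned = clone(model)
        assert cloned.get_params()["entry_p"] == 0.01
        model.fit(X, y)
        pred = model.predict(X)
        assert set(pred) <= {"HC", "MCI"}
        assert model.classes_[1] == "MCI"  # MCI is the positive class


class TestMetrics:
    def test_printed_confusion_count_arithmetic(self):
        # 95 of 108 MCI detected, 82 of 99 HC correct
        prob = np.array([0.9] * 95 + [0.1] * 13 + [0.1] * 82 + [0.9] * 17)
        labels = np.array(["MCI"] * 108 + ["HC"] * 99)
        perf = classify_metrics(prob, labels)
        assert perf.sensitivity == pytest.approx(95 / 108)
        assert perf.confusion == (95, 13, 82, 17)
        assert perf.accuracy == pytest.approx((95 + 82) / 207)

    def test_perfect_separation_gives_unit_auc_through_corner(self):
        prob = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array(["MCI", "MCI", "HC", "HC"])
        perf = classify_metrics(prob, labels)
        assert perf.auc == pytest.approx(1.0)
        assert (0.0, 1.0) in perf.roc
        assert perf.roc[0] == (0.0, 0.0) and perf.roc[-1] == (1.0, 1.0)

    def test_random_scores_have_half_auc(self, rng):
        prob = rng.random(2000)
        labels = np.where(rng.random(2000) < 0.5, "MCI", "HC")
        perf = classify_metrics(prob, labels)
        assert abs(perf.auc - 0.5) < 0.03

    def test_auc_matches_concordant_pair_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 40))
            prob = np.round(rng.random(n), 2)  # ties likely
            labels = np.where(rng.random(n) < 0.5, "MCI", "HC")
            if len(set(labels)) < 2:
                continue
            perf = classify_metrics(prob, labels)
            pos = prob[labels == "MCI"]
            neg = prob[labels == "HC"]
            pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
            assert perf.auc == pytest.approx(float(np.mean(pairs)), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        prob = rng.random(200)
        labels = np.where(rng.random(200) < 0.5, "MCI", "HC")
        a = classify_metrics(prob, labels).auc
        b = classify_metrics(prob**3, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_confusion_identities_hold_exactly(self, rng):
        prob = rng.random(150)
        labels = np.where(rng.random(150) < 0.4, "MCI", "HC")
        perf = classify_metrics(prob, labels, threshold=0.35)
        tp, fn, tn, fp = perf.confusion
        assert perf.accuracy == (tp + tn) / (tp + fn + tn + fp)
        assert perf.sensitivity == tp / (tp + fn)
        assert perf.specificity == tn / (tn + fp)

    def test_single_class_labels_undefined(self):
        with pytest.raises(UndefinedMetricError):
            classify_metrics([0.2, 0.8], ["MCI", "MCI"])

    def test_delong_interval_consistent_with_bootstrap(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 60)])
        y = np.array([True] * 60 + [False] * 60)
        auc, lo, hi = delong_auc_ci(scores, y)
        boots = []
        for _ in range(400):
            idx_p = rng.integers(0, 60, 60)
            idx_n = 60 + rng.integers(0, 60, 60)
            b_scores = np.concatenate([scores[idx_p], scores[idx_n]])
            boots.append(delong_auc_ci(b_scores, y)[0])
        b_lo, b_hi = np.percentile(boots, [2.5, 97.5])
        assert lo == pytest.approx(b_lo, abs=0.05)
        assert hi == pytest.approx(b_hi, abs=0.05)


class TestTaskAverages:
    def _perfs(self, table):
        class P:  # minimal stand-in with the two averaged fields
            def __init__(self, sens, spec):
                self.sensitivity = sens
                self.specificity = spec

        return {k: P(*v) for k, v in table.items()}

    def test_drawing_task_averages_reproduce_printed_row(self):
        perfs = self._perfs(
            {
                "T1": (0.861, 0.828),
                "T2": (0.880, 0.828),
                "T5": (0.843, 0.788),
                "T6": (0.861, 0.909),
            }
        )
        sens, spec = task_average_performance(perfs, ["T1", "T2", "T5", "T6"])
        assert sens == 0.861
        assert spec == 0.838

    def test_single_task_average_is_itself(self):
        perfs = self._perfs({"T7": (0.7, 0.8)})
        assert task_average_performance(perfs, ["T7"]) == (0.7, 0.8)

    def test_unknown_task_id_rejected(self):
        with pytest.raises(KeyError):
            task_average_performance(self._perfs({"T1": (0.5, 0.5)}), ["T1", "T9"])
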