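"""Severity models, metrics, and the bootstrap x LOPO protocol."""

import math

import numpy as np
import pandas as pd
import pytest

from mobisense import (RegularizationConfig, bootstrap_lopo_evaluate,
                       classification_metrics, fit_score_regression,
                       fit_symptom_classifier, nrmsd)
from mobisense.models import _loo_predictions, _standardize

from _oracles import (confusion_rates, irls_logistic, nrmsd_direct,
                      ridge_normal_equations)


class TestScoreRegression:
    def test_noiseless_exact_interpolation(self):
        x = np.arange(10.0)[:, None]
        y = 3.0 * x.ravel() + 1.0
        model = fit_score_regression(x, y)
        assert model.coef[0] == pytest.approx(3.0, abs=1e-8)
        assert model.intercept == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(model.predict(x), y, atol=1e-8)

    def test_ridge_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (10, 2))
        y = X @ [1.5, -2.0] + rng.normal(0, 0.3, 10)
        reg = RegularizationConfig(l1=0.0, l2=0.1)
        model = fit_score_regression(X, y, reg=reg)
        Z, _, _ = _standardize(X)
        w_o, b0_o = ridge_normal_equations(Z, y, 0.1)
        assert np.allclose(model.coef_std, w_o, atol=1e-8)
        assert model.intercept_std == pytest.approx(b0_o, abs=1e-8)

    def test_huge_l1_shrinks_slopes_to_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (20, 3))
        y = X @ [1.0, 2.0, -1.0] + rng.normal(0, 0.1, 20)
        model = fit_score_regression(
            X, y, reg=RegularizationConfig(l1=1e6, l2=0.0))
        assert np.allclose(model.coef_std, 0.0, atol=1e-8)
        assert model.intercept == pytest.approx(y.mean(), abs=1e-6)

    def test_rank_deficient_unpenalized_raises(self):
        X = np.ones((6, 2))
        X[:, 1] = 2.0  # two constant columns, collinear with intercept
        with pytest.raises(ValueError, match="regularization"):
            fit_score_regression(X, np.arange(6.0))

    def test_cv_tuning_uses_training_grid(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (24, 4))
        y = X @ [2.0, 0.0, 0.0, -1.0] + rng.normal(0, 0.5, 24)
        reg = RegularizationConfig(l1_grid=np.array([1e-3, 1.0]),
                                   l2_grid=np.array([1e-3, 1.0]))
        model = fit_score_regression(X, y, reg=reg)
        assert (model.l1, model.l2) in {(a, b) for a in (1e-3, 1.0)
                                        for b in (1e-3, 1.0)}


class TestSymptomClassifier:
    def test_separable_data_with_slight_l2(self):
        x = np.r_[np.linspace(-3, -1, 8), np.linspace(1, 3, 8)][:, None]
        y = np.r_[np.zeros(8), np.ones(8)].astype(int)
        clf = fit_symptom_classifier(x, y,
                                     reg=RegularizationConfig(l1=0.0,
                                                              l2=0.01))
        assert np.array_equal(clf.predict(x), y)

    def test_symmetric_data_zero_intercept(self):
        x = np.r_[-3.0, -2.0, -1.0, 1.0, 2.0, 3.0][:, None]
        y = np.array([0, 0, 1, 0, 1, 1])  # mirror-symmetric labels
        clf = fit_symptom_classifier(x, y)
        assert clf.intercept_std == pytest.approx(0.0, abs=1e-5)

    def test_matches_irls_oracle(self):
        # overlapping 8-point fixture (non-separable, MLE exists)
        x = np.array([-2.0, -1.5, -0.5, 0.3, -0.2, 0.6, 1.4, 2.2])[:, None]
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1])
        clf = fit_symptom_classifier(x, y)
        Z, _, _ = _standardize(x)
        w_o, b0_o = irls_logistic(Z, y)
        assert np.allclose(clf.coef_std, w_o, atol=1e-6)
        assert clf.intercept_std == pytest.approx(b0_o, abs=1e-6)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_symptom_classifier(np.arange(5.0)[:, None], np.ones(5))

    def test_decision_rule_strictly_above_half(self):
        x = np.array([-1.0, -0.5, 0.5, 1.0])[:, None]
        y = np.array([0, 0, 1, 1])
        clf = fit_symptom_classifier(x, y,
                                     reg=RegularizationConfig(l1=0.0, l2=1.0))
        proba = clf.predict_proba(x)
        assert np.array_equal(clf.predict(x), (proba > 0.5).astype(int))


class TestMetrics:
    def test_nrmsd_perfect_and_constant_error(self):
        assert nrmsd([1.0, 2.0], [1.0, 2.0], 17.0) == 0.0
        pred = np.zeros(5) + 1.7
        assert nrmsd(pred, np.zeros(5), 17.0) == pytest.approx(0.1)

    def test_nrmsd_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        p, t = rng.normal(0, 3, 6), rng.normal(0, 3, 6)
        assert nrmsd(p, t, 17.0) == pytest.approx(
            nrmsd_direct(p, t, 17.0), abs=1e-12)

    def test_nrmsd_errors(self):
        with pytest.raises(ValueError):
            nrmsd([1.0], [1.0, 2.0], 17.0)
        with pytest.raises(ValueError):
            nrmsd([1.0], [1.0], 0.0)
        assert math.isnan(nrmsd([], [], 17.0))

    def test_nrmsd_scale_invariance(self):
        rng = np.random.default_rng(8)
        p, t = rng.normal(5, 2, 10), rng.normal(5, 2, 10)
        base = nrmsd(p, t, 17.0)
        assert nrmsd(3 * p + 1, 3 * t + 1, 3 * 17.0) == pytest.approx(base)

    def test_perfect_prediction(self):
        assert classification_metrics([1, 0, 1], [1, 0, 1]) == (1.0, 1.0, 1.0)

    def test_all_positive_prediction(self):
        acc, sens, spec = classification_metrics([1, 1, 1, 1], [1, 0, 1, 0])
        assert (sens, spec) == (1.0, 0.0)

    def test_hand_counted_confusion_table(self):
        # TP=3, FN=1, FP=2, TN=4
        true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        got = classification_metrics(pred, true)
        assert got == pytest.approx(confusion_rates(pred, true))
        assert got == pytest.approx((0.7, 0.75, 2 / 3))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            classification_metrics([1, 0], [1])


def _toy_cohort(n=16, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.uniform(0, 1, n)
    f1 = u + rng.normal(0, 0.15, n)
    f2 = rng.normal(0, 1, n)
    scores = np.clip(np.round(17 * u + rng.normal(0, 1, n)), 0, 27)
    idx = pd.Index([f"p{i}" for i in range(n)], name="participant_id")
    return (pd.DataFrame({"f1": f1, "f2": f2}, index=idx),
            pd.Series(scores, index=idx))


class TestBootstrapLopo:
    def test_b1_equals_plain_lopo_with_physical_refits(self):
        """B=1 is the identity resample; predictions must equal a manual
        leave-one-out loop that physically removes the held-out row before
        any standardization or fitting (no leakage)."""
        features, scores = _toy_cohort()
        X = features.to_numpy()
        y = scores.to_numpy(float)
        labels = (y >= 5).astype(int)
        rep = bootstrap_lopo_evaluate(features, scores, ["f1", "f2"], B=1)

        pred_s = np.empty(len(y))
        pred_l = np.empty(len(y), dtype=int)
        for i in range(len(y)):
            mask = np.ones(len(y), bool)
            mask[i] = False
            m = fit_score_regression(X[mask], y[mask])
            pred_s[i] = m.predict(X[i:i + 1])[0]
            c = fit_symptom_classifier(X[mask], labels[mask])
            pred_l[i] = c.predict(X[i:i + 1])[0]
        rng_val = y.max() - y.min()
        assert rep.nrmsd_mean == pytest.approx(nrmsd(pred_s, y, rng_val),
                                               abs=1e-9)
        acc, sens, spec = classification_metrics(pred_l, labels)
        assert rep.accuracy_mean == pytest.approx(acc, abs=1e-12)
        assert rep.sensitivity_mean == pytest.approx(sens, abs=1e-12)
        assert rep.specificity_mean == pytest.approx(spec, abs=1e-12)

    def test_b1_report_sds_are_zero(self):
        features, scores = _toy_cohort()
        rep = bootstrap_lopo_evaluate(features, scores, ["f1"], B=1)
        assert rep.accuracy_sd == 0.0
        assert rep.nrmsd_sd == 0.0

    def test_metrics_bounded_and_deterministic(self):
        features, scores = _toy_cohort()
        r1 = bootstrap_lopo_evaluate(features, scores, ["f1"], B=8, seed=9)
        r2 = bootstrap_lopo_evaluate(features, scores, ["f1"], B=8, seed=9)
        for rep in (r1, r2):
            for v in (rep.accuracy_mean, rep.sensitivity_mean,
                      rep.specificity_mean):
                assert 0.0 <= v <= 1.0
            assert rep.nrmsd_mean >= 0.0
        assert r1.accuracy_mean == r2.accuracy_mean
        assert r1.nrmsd_mean == r2.nrmsd_mean

    def test_unit_level_holds_out_duplicates_together(self):
        features, scores = _toy_cohort()
        rep = bootstrap_lopo_evaluate(features, scores, ["f1"], B=5, seed=1,
                                      unit_level=True)
        assert rep.duplicate_leak_rate == 0.0

    def test_single_class_cohort_rejected(self):
        features, scores = _toy_cohort()
        with pytest.raises(ValueError, match="single symptom class"):
            bootstrap_lopo_evaluate(features, scores * 0, ["f1"], B=2)

    def test_na_participants_dropped(self):
        features, scores = _toy_cohort()
        features.iloc[0, 0] = np.nan
        rep = bootstrap_lopo_evaluate(features, scores, ["f1"], B=1)
        assert rep.n_participants == len(features) - 1

    def test_feature_ranking_tracks_correlation_strength(self):
        """Single-feature LOPO NRMSD orders features like their absolute
        correlation with the outcome (the qualitative table pattern)."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(11)
        agree = []
        for rep in range(10):
            n = 28
            u = rng.uniform(0, 1, n)
            noise_sd = [0.05, 0.3, 0.8, 2.0]
            cols = {f"f{j}": u + rng.normal(0, sd, n)
                    for j, sd in enumerate(noise_sd)}
            idx = pd.Index([f"p{i}" for i in range(n)])
            features = pd.DataFrame(cols, index=idx)
            scores = pd.Series(np.clip(np.round(17 * u), 0, 27), index=idx)
            abs_r = [abs(np.corrcoef(features[c], scores)[0, 1])
                     for c in features]
            nr = [bootstrap_lopo_evaluate(features, scores, [c], B=1)
                  .nrmsd_mean for c in features]
            rho = spearmanr(abs_r, [-v for v in nr]).statistic
            agree.append(rho)
        assert np.mean(agree) >= 0.8
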