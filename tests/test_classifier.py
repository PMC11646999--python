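"""Classifier tests: feature building, logistic fit against statsmodels,
ROC/Youden against exhaustive oracles, CV behaviour, frozen-model external
validation and score-stratified survival."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ctdx import (
    FeatureSpec,
    ValidationError,
    build_features,
    confusion_stats,
    external_validate,
    fit_logistic,
    predict_scores,
    repeated_cv,
    roc_auc,
    stratify_by_score,
    train_model,
    youden_point,
)


def _pairwise_auc(scores, labels):
    """Tie-corrected concordance oracle: P(score_pos > score_neg) + P(tie)/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


class TestBuildFeatures:
    def _metrics(self):
        return pd.DataFrame({
            "normalized_btmb": [0.5, 0.05, 0.2, 0.0],
            "delta_ctdna": [0.2, 0.0, 1.5, 0.4],
            "recist_first": ["PR", "SD", "PD", "NA"],
        })

    def test_log10_floor_transform(self):
        X, y = build_features(
            self._metrics(), ["DCB", "DCB", "NDB", "NDB"],
            FeatureSpec(features=("delta_ctdna",)))
        assert X["delta_ctdna"].iloc[0] == pytest.approx(np.log10(0.2))
        assert X["delta_ctdna"].iloc[1] == pytest.approx(-4.0)  # floored zero

    def test_recist_coding_and_na_drop(self):
        X, y = build_features(
            self._metrics(), ["DCB", "DCB", "NDB", "NDB"],
            FeatureSpec(features=("recist_responder",)))
        assert list(X["recist_responder"]) == [1.0, 0.0, 0.0]  # NA row dropped
        assert list(y) == [1, 1, 0]

    def test_indeterminate_rows_dropped(self):
        X, y = build_features(
            self._metrics(), ["DCB", "indeterminate", "NDB", "NDB"],
            FeatureSpec(features=("delta_ctdna",)))
        assert len(X) == 3

    def test_missing_feature_column_errors(self):
        with pytest.raises(ValidationError):
            build_features(pd.DataFrame({"delta_ctdna": [0.1]}), ["DCB"],
                           FeatureSpec(features=("normalized_btmb",)))


class TestFitLogistic:
    def test_matches_statsmodels(self, rng):
        n = 500
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        eta = -0.5 + 1.2 * X["a"] - 0.8 * X["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        mine = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert mine.coef == pytest.approx(ref.params.to_numpy(), abs=1e-6)
        assert mine.converged

    def test_parameter_recovery_within_3_se(self, rng):
        n = 5000
        x = rng.normal(size=n)
        eta = -1.0 + 2.0 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        se = np.asarray(ref.bse)
        assert abs(m.coef[0] - (-1.0)) < 3 * se[0]
        assert abs(m.coef[1] - 2.0) < 3 * se[1]

    def test_gradient_vanishes_at_optimum(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.5).astype(int)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        A = np.hstack([np.ones((n, 1)), x.reshape(-1, 1)])
        p = 1 / (1 + np.exp(-(A @ m.coef)))
        grad = A.T @ (y - p)
        assert np.max(np.abs(grad)) < 1e-6

    def test_class_symmetric_data_zero_intercept(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert abs(m.coef[0]) < 1e-4

    def test_separation_triggers_ridge(self):
        x = np.linspace(-1, 1, 30)
        y = (x > 0).astype(int)
        with pytest.warns(RuntimeWarning, match="separation"):
            m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.ridge > 0
        assert np.isfinite(m.coef).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(pd.DataFrame({"x": [0.1, 0.2, 0.3, 0.4]}), [1, 1, 1, 1])

    def test_affine_rescaling_leaves_auc_invariant(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        m1 = fit_logistic(pd.DataFrame({"x": x}), y)
        m2 = fit_logistic(pd.DataFrame({"x": 10 * x + 3}), y)
        s1 = predict_scores(m1, pd.DataFrame({"x": x}))
        s2 = predict_scores(m2, pd.DataFrame({"x": 10 * x + 3}))
        assert roc_auc(s1, y).auc == pytest.approx(roc_auc(s2, y).auc, abs=1e-9)
        assert m2.coef[1] == pytest.approx(m1.coef[1] / 10, rel=1e-4)


class TestRoc:
    def test_worked_example(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_trapezoid_equals_pairwise_concordance(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            s = np.round(rng.random(n), 2)  # deliberate ties
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            assert roc_auc(s, y).auc == pytest.approx(_pairwise_auc(s, y), abs=1e-12)

    def test_endpoints_and_monotonicity(self, rng):
        s = rng.random(30)
        y = (rng.random(30) < 0.5).astype(int)
        y[0], y[1] = 0, 1
        roc = roc_auc(s, y)
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()


class TestYouden:
    def test_worked_example(self):
        roc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        op = youden_point(roc)
        assert op.threshold == pytest.approx(0.6)
        assert op.sensitivity == pytest.approx(0.5)
        assert op.specificity == pytest.approx(1.0)
        assert op.youden_j == pytest.approx(0.5)

    def test_perfect_separation_j_one(self):
        op = youden_point(roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]))
        assert op.youden_j == pytest.approx(1.0)

    def test_equals_exhaustive_scan(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 40))
            s = np.round(rng.random(n), 2)
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            op = youden_point(roc_auc(s, y))
            best = max(
                confusion_stats(s, y, th)["sensitivity"]
                + confusion_stats(s, y, th)["specificity"] - 1
                for th in np.concatenate([[-1e9], (np.unique(s)[:-1] + np.unique(s)[1:]) / 2])
            )
            assert op.youden_j == pytest.approx(best, abs=1e-12)


class TestConfusionStats:
    def test_constructed_counts(self):
        # 45 TP, 11 FN, 19 TN, 8 FP at threshold 0.5
        scores = [0.9] * 45 + [0.1] * 11 + [0.1] * 19 + [0.9] * 8
        labels = [1] * 56 + [0] * 27
        cs = confusion_stats(scores, labels, 0.5)
        assert cs["sensitivity"] == pytest.approx(45 / 56, abs=1e-4)
        assert cs["specificity"] == pytest.approx(19 / 27, abs=1e-4)
        assert cs["accuracy"] == pytest.approx(64 / 83, abs=1e-4)

    def test_extreme_thresholds(self):
        s = [0.2, 0.4, 0.6, 0.8]
        y = [0, 1, 0, 1]
        lo = confusion_stats(s, y, 0.0)
        hi = confusion_stats(s, y, 1.0)
        assert lo["sensitivity"] == 1.0 and lo["specificity"] == 0.0
        assert hi["sensitivity"] == 0.0 and hi["specificity"] == 1.0


class TestRepeatedCv:
    def test_determinism(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=60)})
        y = (rng.random(60) < 0.5).astype(int)
        while np.bincount(y, minlength=2).min() < 5:
            y = (rng.random(60) < 0.5).astype(int)
        a = repeated_cv(X, y, repeats=3, seed=11)
        b = repeated_cv(X, y, repeats=3, seed=11)
        assert np.array_equal(a.aucs, b.aucs)

    def test_class_smaller_than_k_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValidationError):
            repeated_cv(X, y, k=5)


class TestExternalValidation:
    def test_identity_validation_reproduces_operating_point(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        X = pd.DataFrame({"x": x})
        model = train_model(X, y)
        op, roc = external_validate(model, X, y)
        assert roc.auc == pytest.approx(model.roc.auc)
        assert op.sensitivity == pytest.approx(model.operating_point.sensitivity)
        assert op.specificity == pytest.approx(model.operating_point.specificity)

    def test_permuted_labels_give_null_auc(self, rng):
        n = 600
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        X = pd.DataFrame({"x": x})
        model = train_model(X, y)
        yp = rng.permutation(y)
        op, roc = external_validate(model, X, yp)
        assert 0.45 < roc.auc < 0.55

    def test_feature_mismatch_errors(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = (rng.random(50) < 0.5).astype(int)
        y[:5], y[-5:] = 1, 0
        model = train_model(X, y)
        with pytest.raises(ValidationError):
            external_validate(model, pd.DataFrame({"z": X["x"]}), y)


class TestStratifyByScore:
    def test_ordered_scores_give_protective_hr(self, rng):
        n = 200
        score = rng.random(n)
        # higher score -> longer survival by construction
        t = np.exp(2 * score) * rng.exponential(1.0, n) + 0.01
        e = np.ones(n, dtype=bool)
        strata = stratify_by_score(score, 0.5, t, e)
        assert strata.hazard_ratio < 1.0
        assert strata.logrank.p_value < 0.05

    def test_threshold_outside_range_errors(self, rng):
        with pytest.raises(ValidationError):
            stratify_by_score(rng.random(20), 2.0, np.ones(20), np.ones(20, dtype=bool))
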