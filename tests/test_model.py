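"""LASSO conventions, stability selection, fusion, CV and statistics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from microzone.features import FeatureMatrix
from microzone.model import (
    LateFusionClassifier,
    StabilityConfig,
    StabilitySelection,
    auroc,
    lambda_max,
    lasso_fit,
    mann_whitney,
    monte_carlo_cv,
    univariate_screen,
)


class TestLasso:
    def test_soft_threshold_on_orthonormal_design(self, rng):
        n, p = 40, 8
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        y = rng.normal(size=n)
        ols = Q.T @ y
        for lam in (0.05, 0.3, 1.0):
            beta = lasso_fit(Q, y, lam)
            soft = np.sign(ols) * np.maximum(np.abs(ols) - lam / 2, 0)
            assert np.abs(beta - soft).max() < 1e-6

    def test_full_shrinkage_at_lambda_max(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        assert np.all(lasso_fit(X, y, lambda_max(X, y)) == 0)
        assert np.any(lasso_fit(X, y, 0.99 * lambda_max(X, y)) != 0)

    def test_ols_limit_small_lambda(self, rng):
        X = rng.normal(size=(5, 3)) + np.eye(5, 3) * 3  # well-conditioned
        y = rng.normal(size=5)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        beta = lasso_fit(X, y, 1e-10)
        assert np.abs(beta - ols).max() < 1e-4

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            lasso_fit(np.array([[1.0, np.nan]]), np.array([1.0]), 0.1)


class TestStabilitySelection:
    def test_perfect_predictor_has_frequency_one(self, rng):
        n = 40
        y = np.tile([0.0, 1.0], n // 2)
        X = rng.normal(size=(n, 20))
        X[:, 3] = y * 2 - 1
        sel = StabilitySelection(n_bootstrap=100, random_state=0).fit(X, y)
        assert sel.frequencies_[3] == 1.0
        assert sel.support_[3]

    def test_null_features_rarely_selected(self, rng):
        n, p = 60, 40
        y = np.tile([0.0, 1.0], n // 2)
        rates = []
        for seed in range(3):
            X = np.random.default_rng(seed).normal(size=(n, p))
            sel = StabilitySelection(n_bootstrap=200, random_state=seed).fit(X, y)
            rates.append(sel.support_.mean())
        assert np.mean(rates) <= 0.05

    def test_planted_recovery(self):
        rng = np.random.default_rng(5)
        n, p = 72, 100
        y = np.tile([0.0, 1.0], n // 2)
        X = rng.normal(size=(n, p))
        X[:, :10] += (y * 1.2)[:, None]
        sel = StabilitySelection(random_state=1).fit(X, y)
        assert sel.support_[:10].sum() >= 7
        assert sel.support_[10:].mean() <= 0.05

    def test_reproducible_given_seed(self, rng):
        X = rng.normal(size=(30, 15))
        y = np.tile([0.0, 1.0], 15)
        a = StabilitySelection(n_bootstrap=50, random_state=7).fit(X, y)
        b = StabilitySelection(n_bootstrap=50, random_state=7).fit(X, y)
        assert np.array_equal(a.frequencies_, b.frequencies_)
        assert (a.frequencies_ >= 0).all() and (a.frequencies_ <= 1).all()

    @pytest.mark.parametrize("mode", ["inner_cv", "fixed"])
    def test_alternative_lambda_modes(self, mode, rng):
        X = rng.normal(size=(40, 12))
        y = np.tile([0.0, 1.0], 20)
        X[:, 0] += y * 3
        kw = {"fixed_lambda": 2.0} if mode == "fixed" else {}
        sel = StabilitySelection(
            n_bootstrap=25, lambda_mode=mode, random_state=3, **kw
        ).fit(X, y)
        assert sel.frequencies_[0] > 0.5

    def test_guards(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="binary"):
            StabilitySelection().fit(X, np.arange(10))
        with pytest.raises(ValueError, match="impute"):
            StabilitySelection().fit(
                np.full((10, 3), np.nan), np.tile([0, 1], 5)
            )


class TestLateFusion:
    def test_zero_selected_gives_prevalence_model(self, rng):
        X = rng.normal(size=(40, 10))
        y = np.array([0] * 30 + [1] * 10)
        clf = LateFusionClassifier(n_bootstrap=50, random_state=0).fit(X, y)
        if clf.support_.sum() == 0:
            p = clf.predict_proba(rng.normal(size=(5, 10)))[:, 1]
            assert np.allclose(p, 0.25, atol=1e-6)

    def test_separating_feature_training_auc_one(self, rng):
        n = 40
        y = np.tile([0, 1], n // 2)
        X = rng.normal(size=(n, 8))
        X[:, 2] = y * 4 - 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LateFusionClassifier(n_bootstrap=100, random_state=0).fit(X, y)
        s = clf.decision_function(X)
        assert auroc(s, y)["auc"] == 1.0

    def test_logistic_coefficient_recovery(self):
        """With known log-odds and n = 10,000 the fused fit recovers the
        generating coefficients."""
        rng = np.random.default_rng(12)
        n = 10_000
        X = rng.normal(size=(n, 2))
        logits = 0.8 * X[:, 0] - 1.5 * X[:, 1] + 0.3
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        clf = LateFusionClassifier(n_bootstrap=20, random_state=0).fit(X, y)
        assert clf.support_.all()
        # coefficients are on standardized columns; undo the scaling
        raw = clf.coef_[0] / clf.scales_
        assert raw[0] == pytest.approx(0.8, abs=0.12)
        assert raw[1] == pytest.approx(-1.5, abs=0.12)

    def test_sklearn_protocol(self):
        clf = LateFusionClassifier(n_bootstrap=10)
        params = clf.get_params()
        assert params["n_bootstrap"] == 10
        clf.set_params(n_bootstrap=20)
        assert clf.n_bootstrap == 20


class TestAUROC:
    def test_trivial_cases(self):
        assert auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])["auc"] == 1.0
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1])["auc"] == 0.5

    def test_hand_enumerated(self):
        rep = auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert rep["auc"] == pytest.approx(0.75)
        assert rep["ci_low"] <= rep["auc"] <= rep["ci_high"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_enumeration_value(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_power_at_large_shift(self):
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(200):
            x = rng.normal(0, 1, 30)
            y = rng.normal(2, 1, 30)
            _, p = mann_whitney(x, y)
            rejections += p < 0.05
        assert rejections / 200 >= 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestUnivariateScreen:
    def test_constant_feature_p_one(self):
        X = pd.DataFrame({"c": np.ones(20), "s": np.r_[np.zeros(10), np.ones(10)]})
        out = univariate_screen(X, np.r_[np.zeros(10), np.ones(10)].astype(int))
        assert out.loc["c", "p"] == 1.0
        assert out.loc["s", "significant"]

    def test_null_calibration(self, rng):
        n = 40
        labels = np.tile([0, 1], n // 2)
        X = pd.DataFrame(rng.normal(size=(n, 300)))
        X.columns = [f"f{i}" for i in range(300)]
        out = univariate_screen(X, labels)
        assert out["significant"].mean() == pytest.approx(0.05, abs=0.035)

    def test_planted_outcome_effect_flagged(self, rng):
        labels = np.tile([0, 1], 20)
        X = pd.DataFrame({"hit": rng.normal(size=40) + labels * 1.5})
        assert univariate_screen(X, labels).loc["hit", "significant"]


def _toy_feature_matrix(rng, n_pat=12, n_roi=3, p=30, d=0.0):
    n = n_pat * n_roi
    pats = np.repeat([f"p{i}" for i in range(n_pat)], n_roi)
    grade = np.repeat([i % 2 for i in range(n_pat)], n_roi)
    X = rng.normal(size=(n, p))
    X[:, :3] += grade[:, None] * d
    cols = [f"f{i}" for i in range(p)]
    fclass = ["density"] * (p // 2) + ["function"] * (p - p // 2)
    data = pd.DataFrame(X, columns=cols,
                        index=pd.Index([f"r{i}" for i in range(n)], name="roi_id"))
    col_info = pd.DataFrame(
        {"feature_class": fclass, "zone": "stroma", "population": "cd8_t"},
        index=pd.Index(cols, name="feature"),
    )
    row_info = pd.DataFrame(
        {"patient_id": pats, "grade": grade}, index=data.index
    )
    return FeatureMatrix(data=data, col_info=col_info, row_info=row_info)


class TestMonteCarloCV:
    def test_deterministic_given_seed(self, rng):
        fm = _toy_feature_matrix(rng, d=1.5)
        cfg = StabilityConfig(n_bootstrap=40, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = monte_carlo_cv(fm, config=cfg)
            b = monte_carlo_cv(fm, config=cfg)
        assert a.auc_report == b.auc_report
        pd.testing.assert_frame_equal(a.oof_scores, b.oof_scores)
        assert a.frequencies.equals(b.frequencies)

    def test_patient_grouping_never_straddles(self, rng):
        fm = _toy_feature_matrix(rng, d=1.0)
        cfg = StabilityConfig(n_bootstrap=30, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = monte_carlo_cv(fm, config=cfg)
        pats = fm.row_info["patient_id"]
        for fold in res.oof_scores["fold"].unique():
            test_rois = res.oof_scores.loc[
                res.oof_scores["fold"] == fold, "roi_id"
            ]
            test_pats = set(pats.loc[test_rois])
            # every ROI of a held-out patient is held out
            for p in test_pats:
                assert set(pats.index[pats == p]) <= set(test_rois)

    def test_leakage_canary(self, rng):
        """A feature that copies the labels of (future) test ROIs only —
        noise on training ROIs — must not inflate out-of-fold AUC."""
        fm = _toy_feature_matrix(rng, d=0.0, p=10)
        grade = fm.row_info["grade"].to_numpy().astype(float)
        # the canary equals the label exactly, but only for one patient's
        # ROIs; elsewhere pure noise. Grouped CV must not learn from it.
        canary = rng.normal(size=len(grade))
        canary[:3] = grade[:3] * 10
        fm.data["f0"] = canary
        cfg = StabilityConfig(n_bootstrap=40, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = monte_carlo_cv(fm, config=cfg)
        assert res.auc_report["auc"] < 0.75

    def test_infeasible_split_raises(self, rng):
        fm = _toy_feature_matrix(rng, n_pat=2, n_roi=2)
        with pytest.raises(ValueError, match="groups per class"):
            monte_carlo_cv(fm, config=StabilityConfig(n_bootstrap=5))
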