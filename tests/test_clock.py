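"""Clock training: splits, features, nested LOOCV, permutation, stability."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

import methclock as mc
from methclock.clock import (
    CLOCK_MIXING,
    ClockSpec,
    EpigeneticClock,
    _coef_path,
    lambda_grid,
)
from tests.conftest import build_channel_matrix


def _manifest_3x5():
    return [
        mc.Sample(f"W{w}_r{r}", 7.0 * w, f"W{w}")
        for w in (1, 3, 5) for r in range(1, 6)
    ]


class TestSplit:
    def test_stratified_quotas(self):
        train, test = mc.split_train_test(_manifest_3x5(), 10, seed=0)
        assert len(train) == 10 and len(test) == 5
        for w in (1, 3, 5):
            in_train = sum(1 for s in train if s.startswith(f"W{w}"))
            assert in_train in (3, 4)

    def test_deterministic(self):
        assert mc.split_train_test(_manifest_3x5(), 10, 42) == \
            mc.split_train_test(_manifest_3x5(), 10, 42)

    def test_full_train_rejected(self):
        with pytest.raises(ValueError):
            mc.split_train_test(_manifest_3x5(), 15, 0)


class TestAssembleFeatures:
    def test_entropy_of_half_is_one(self, small_matrix):
        flat = mc.MethylationMatrix(
            sites=small_matrix.sites[:4],
            samples=small_matrix.samples,
            fractions=np.full((4, small_matrix.n_samples), 0.5),
            coverages=np.full((4, small_matrix.n_samples), 30),
        )
        feats = mc.assemble_features(flat, "elasticnet_entropy", dms=flat.sites)
        assert np.all(feats.to_numpy() == 1.0)

    def test_dms_feature_count(self, small_matrix):
        dms = small_matrix.sites[:7]
        feats = mc.assemble_features(small_matrix, "ridge_dms", dms=dms)
        assert feats.shape == (small_matrix.n_samples, 7)

    def test_entropy_composition(self, small_matrix):
        dms = small_matrix.sites[:5]
        levels = mc.assemble_features(small_matrix, "ridge_dms", dms=dms)
        ent = mc.assemble_features(small_matrix, "elasticnet_entropy", dms=dms)
        assert ent.to_numpy() == pytest.approx(mc.site_entropy(levels.to_numpy()))

    def test_missing_dms_fatal(self, small_matrix):
        with pytest.raises(ValueError):
            mc.assemble_features(small_matrix, "ridge_dms", dms=[])


class TestRidgePathOracle:
    def test_svd_path_matches_sklearn_ridge(self, rng):
        n, p = 12, 30
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.standard_normal(n)
        y -= y.mean()
        lambdas = np.geomspace(10, 0.001, 12)
        coefs = _coef_path(X, y, lambdas, l1_ratio=0.0)
        for j, lam in enumerate(lambdas):
            ref = Ridge(alpha=lam * n, fit_intercept=False).fit(X, y).coef_
            assert coefs[:, j] == pytest.approx(ref, abs=1e-8)

    def test_lambda_max_zeroes_elastic_net(self, rng):
        X = rng.standard_normal((10, 40))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.standard_normal(10)
        y -= y.mean()
        grid = lambda_grid(X, y, 0.5, n_lambda=5)
        coefs = _coef_path(X, y, grid, 0.5)
        assert np.allclose(coefs[:, 0], 0.0, atol=1e-10)


class TestFitPredict:
    def test_perfect_single_feature(self):
        ages = np.array([7.0, 7, 7, 21, 21, 21, 35, 35, 35, 21])
        X = pd.DataFrame({"site": ages / 10.0})
        est = EpigeneticClock("elasticnet_levels").fit(X, ages)
        assert est.cv_r_ >= 0.999
        assert est.coef_[0] != 0.0

    def test_constant_age_fatal(self):
        X = pd.DataFrame(np.random.default_rng(0).random((5, 3)))
        with pytest.raises(ValueError):
            EpigeneticClock().fit(X, np.full(5, 21.0))

    def test_zero_variance_columns_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        ages = np.tile([7.0, 21.0, 35.0], 3)
        X = pd.DataFrame({"good": ages + rng.normal(0, 1, 9), "flat": np.ones(9)})
        with pytest.warns(UserWarning, match="zero-variance"):
            est = EpigeneticClock().fit(X, ages)
        assert est.coef_[1] == 0.0

    def test_predict_linear_combination(self, small_matrix):
        feats = mc.assemble_features(small_matrix, "elasticnet_levels")
        ages = small_matrix.ages_days
        est = EpigeneticClock().fit(feats, ages)
        f1, f2 = feats.iloc[[0]], feats.iloc[[5]]
        for alpha in (0.0, 0.3, 1.0):
            blend = alpha * f1.to_numpy() + (1 - alpha) * f2.to_numpy()
            expected = alpha * est.predict(f1)[0] + (1 - alpha) * est.predict(f2)[0]
            assert est.predict(blend)[0] == pytest.approx(expected, abs=1e-8)

    def test_training_refit_consistency(self, small_matrix):
        feats = mc.assemble_features(small_matrix, "elasticnet_levels")
        ages = small_matrix.ages_days
        model = mc.train_clock(feats, ages, "elasticnet_levels")
        manual = model.intercept + feats.loc[:, model.feature_names].to_numpy() @ model.coefficients
        assert mc.predict_age(model, feats) == pytest.approx(manual, abs=1e-8)

    def test_predict_missing_features_fatal(self, small_matrix):
        feats = mc.assemble_features(small_matrix, "elasticnet_levels")
        model = mc.train_clock(feats, small_matrix.ages_days, "elasticnet_levels")
        with pytest.raises(ValueError, match="missing"):
            mc.predict_age(model, feats.iloc[:, : feats.shape[1] // 2])

    def test_trivial_predictions(self):
        model = mc.ClockModel(
            spec=ClockSpec("elasticnet_levels"), feature_names=["s1", "s2"],
            coefficients=np.array([0.0, 0.0]), intercept=21.0, chosen_lambda=1.0,
            per_fold_feature_counts=[1, 1], per_fold_lambdas=[1.0, 1.0],
            training_metrics={},
        )
        feats = pd.DataFrame([[0.1, 0.9], [0.5, 0.5]], columns=["s1", "s2"])
        assert mc.predict_age(model, feats) == pytest.approx([21.0, 21.0])
        model.coefficients = np.array([1.0, 0.0])
        model.intercept = 0.0
        feats.iloc[0, 0] = 21.0
        assert mc.predict_age(model, feats)[0] == pytest.approx(21.0)

    def test_determinism_and_serialization(self, small_matrix):
        feats = mc.assemble_features(small_matrix, "elasticnet_levels")
        ages = small_matrix.ages_days
        m1 = mc.train_clock(feats, ages, "elasticnet_levels")
        m2 = mc.train_clock(feats, ages, "elasticnet_levels")
        assert m1.to_json() == m2.to_json()
        restored = mc.ClockModel.from_json(m1.to_json())
        assert mc.predict_age(restored, feats) == pytest.approx(
            mc.predict_age(m1, feats)
        )

    def test_cv_predictions_invariant_to_sample_order(self, null_matrix):
        feats = mc.assemble_features(null_matrix, "elasticnet_levels")
        ages = null_matrix.ages_days
        est = EpigeneticClock().fit(feats, ages)
        perm = np.random.default_rng(3).permutation(len(ages))
        est_p = EpigeneticClock().fit(feats.iloc[perm], ages[perm])
        assert est_p.cv_predictions_ == pytest.approx(
            est.cv_predictions_[perm], abs=1e-6
        )
        assert est_p.coef_ == pytest.approx(est.coef_, abs=1e-6)

    def test_unknown_clock_type_rejected(self):
        with pytest.raises(ValueError):
            EpigeneticClock("lasso").fit(pd.DataFrame([[1.0], [2.0], [3.0]]),
                                         np.array([7.0, 21.0, 35.0]))


class TestEvaluate:
    def test_perfect(self):
        assert mc.evaluate_predictions([7, 21, 35], [7, 21, 35]) == (0.0, 0.0, 1.0)

    def test_one_day_off(self):
        mae, mre, r = mc.evaluate_predictions([8, 22, 36], [7, 21, 35])
        assert mae == pytest.approx(1.0)
        assert mre == pytest.approx(100 * (1 / 7 + 1 / 21 + 1 / 35) / 3, abs=0.05)

    def test_anticorrelated(self):
        _, _, r = mc.evaluate_predictions([35, 21, 7], [7, 21, 35])
        assert r == pytest.approx(-1.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            mc.evaluate_predictions([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            mc.evaluate_predictions([1, 2], [0, 2])


class TestPermutation:
    def test_add_one_estimator_and_determinism(self, null_matrix):
        feats = mc.assemble_features(null_matrix, "elasticnet_levels").iloc[:, :40]
        ages = null_matrix.ages_days
        r1 = mc.permutation_test(feats, ages, "elasticnet_levels", n_perm=5, seed=9)
        r2 = mc.permutation_test(feats, ages, "elasticnet_levels", n_perm=5, seed=9)
        assert r1.p_value == r2.p_value
        assert r1.null_values == pytest.approx(r2.null_values)
        k = int((r1.null_values <= r1.observed).sum())
        assert r1.p_value == (1 + k) / 6

    def test_zero_permutations_rejected(self, null_matrix):
        feats = mc.assemble_features(null_matrix, "elasticnet_levels")
        with pytest.raises(ValueError):
            mc.permutation_test(feats, null_matrix.ages_days,
                                "elasticnet_levels", n_perm=0)

    def test_null_signal_shows_no_positive_cv_skill(self):
        """Permuted ages: cross-validated r shows no positive apparent skill.

        Under the null, LOOCV r is typically strongly negative rather than
        near zero: when the penalty zeroes every coefficient the fold
        prediction is the leave-one-out training mean, which is an exactly
        decreasing function of the held-out age.  The meaningful null
        property is therefore the absence of positive correlation.
        """
        no_skill = 0
        n_rep = 20
        rng = np.random.default_rng(17)
        cfg = mc.SimulationConfig(seed=23, n_sites=150, mod_codes=("a",))
        mat = build_channel_matrix(mc.simulate_cohort(cfg))
        feats = mc.assemble_features(mat, "elasticnet_levels")
        ages = mat.ages_days
        for _ in range(n_rep):
            est = EpigeneticClock().fit(feats, rng.permutation(ages))
            r = est.cv_r_
            no_skill += (np.isnan(r) or r < 0.5)
        assert no_skill >= 0.9 * n_rep


class TestStability:
    def model(self, counts, ctype="elasticnet_levels"):
        return mc.ClockModel(
            spec=ClockSpec(ctype), feature_names=["x"],
            coefficients=np.array([1.0]), intercept=0.0, chosen_lambda=1.0,
            per_fold_feature_counts=counts, per_fold_lambdas=[1.0] * len(counts),
            training_metrics={},
        )

    def test_equal_counts_zero_cv(self):
        res = mc.feature_stability(self.model([50, 50, 50]))
        assert res.cv_percent == 0.0

    def test_both_sd_conventions(self):
        res = mc.feature_stability(self.model([40, 50, 60]))
        assert res.mean_features == 50.0
        assert res.cv_percent == pytest.approx(20.0)
        assert res.cv_percent_population == pytest.approx(16.3, abs=0.05)

    def test_ridge_flagged_without_cv(self):
        res = mc.feature_stability(self.model([120, 120], "ridge_dms"))
        assert res.is_ridge and res.cv_percent == 0.0
        assert "feature selection" in res.note

    def test_single_fold_undefined(self):
        with pytest.raises(ValueError):
            mc.feature_stability(self.model([50]))


class TestDeceleration:
    def test_identical_arms_not_significant(self, small_matrix):
        feats = mc.assemble_features(small_matrix, "elasticnet_levels")
        model = mc.train_clock(feats, small_matrix.ages_days, "elasticnet_levels")
        old = feats.iloc[-5:]
        res = mc.age_deceleration_test(model, old, {"sham": old.copy()}, 35.0)
        assert res.arms[0].p_vs_control > 0.05

    def test_small_arm_rejected(self, small_matrix):
        feats = mc.assemble_features(small_matrix, "elasticnet_levels")
        model = mc.train_clock(feats, small_matrix.ages_days, "elasticnet_levels")
        with pytest.raises(ValueError):
            mc.age_deceleration_test(model, feats.iloc[:2], {}, 35.0)


def test_clock_mixing_values():
    assert CLOCK_MIXING == {
        "elasticnet_levels": 0.5, "ridge_dms": 0.0, "elasticnet_entropy": 0.5,
    }
    assert ClockSpec("ridge_dms").mixing == 0.0
    with pytest.raises(ValueError):
        ClockSpec("ols")
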