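"""Logistic model suite: fits, bases, LRT, LOOCV, search, thresholds, ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2, hypergeom

from hemonet.models import (
    Categorical,
    Covariate,
    ModelSpec,
    NaturalSpline,
    Poly,
    calibrate_threshold,
    cohort_univariate_table,
    exhaustive_model_search,
    fit_logistic,
    likelihood_ratio_test,
    loocv_classification,
    loocv_error,
    natural_spline_basis,
    polynomial_basis,
    roc_auc,
)


def outcome_frame(n_pos, n_neg):
    return pd.DataFrame({"improved": [1.0] * n_pos + [0.0] * n_neg})


def quadratic_data(rng, n=200, b=(0.2, 0.8, -1.0)):
    x = rng.normal(90, 10, n)
    z = (x - x.mean()) / x.std()
    y = (rng.random(n) < expit(b[0] + b[1] * z + b[2] * z * z)).astype(float)
    return pd.DataFrame({"improved": y, "amap_mmHg": x})


def independent_logistic_mle(X, y):
    """Logistic MLE by direct likelihood optimization (oracle fit)."""

    def nll(beta):
        eta = X @ beta
        return np.sum(np.log1p(np.exp(eta)) - y * eta)

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS", tol=1e-12)
    return res.x


class TestFit:
    def test_intercept_only_closed_form(self):
        """Null deviance equals the binomial saturated-vs-mean closed form."""
        data = outcome_frame(42, 61)
        fit = fit_logistic(ModelSpec("improved", ()), data)
        p = 42 / 103
        expected = -2 * (42 * np.log(p) + 61 * np.log(1 - p))
        assert fit.deviance == pytest.approx(expected, abs=1e-8)
        assert fit.aic == pytest.approx(expected + 2, abs=1e-8)
        assert fit.params.loc["Intercept", "coef"] == pytest.approx(
            np.log(p / (1 - p)), abs=1e-6
        )

    def test_binary_predictor_is_log_odds_ratio(self):
        data = pd.DataFrame(
            {
                "improved": [0.0] * 36 + [1.0] * 33 + [0.0] * 25 + [1.0] * 9,
                "nli": ["cervical"] * 69 + ["non-cervical"] * 34,
            }
        )
        fit = fit_logistic(
            ModelSpec("improved", (Categorical("nli", "cervical"),)), data
        )
        expected = np.log((9 / 25) / (33 / 36))
        assert fit.params.loc["nli[non-cervical]", "coef"] == pytest.approx(
            expected, abs=1e-6
        )

    def test_constant_predictor_rejected(self):
        data = outcome_frame(10, 10)
        data["flat"] = 1.0
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic(ModelSpec("improved", (Covariate("flat"),)), data)

    def test_missing_rows_dropped_and_counted(self, rng):
        data = quadratic_data(rng, 50)
        data.loc[:4, "amap_mmHg"] = np.nan
        fit = fit_logistic(ModelSpec("improved", (Poly("amap_mmHg", 1),)), data)
        assert fit.n == 45 and fit.n_dropped == 5

    def test_separation_flagged(self):
        data = pd.DataFrame(
            {"improved": [0.0] * 10 + [1.0] * 10, "x": list(range(20))}
        )
        fit = fit_logistic(ModelSpec("improved", (Covariate("x"),)), data)
        assert fit.separation


class TestBases:
    def test_degree_one_raw_is_identity(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_array_equal(polynomial_basis(x, 1, "raw")[:, 0], x)

    def test_orthonormal_columns(self, rng):
        x = rng.normal(size=50)
        B = polynomial_basis(x, 3)
        G = B.T @ B
        np.testing.assert_allclose(G, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(B.sum(axis=0), 0.0, atol=1e-10)

    def test_coding_invariant_deviance(self, rng):
        data = quadratic_data(rng)
        dev = {}
        for coding in ("raw", "orthonormal"):
            spec = ModelSpec("improved", (Poly("amap_mmHg", 2, coding),))
            dev[coding] = fit_logistic(spec, data).deviance
        assert dev["raw"] == pytest.approx(dev["orthonormal"], abs=1e-6)

    def test_affine_rescaling_invariant_deviance(self, rng):
        data = quadratic_data(rng)
        rescaled = data.assign(amap_mmHg=(data["amap_mmHg"] - 90) / 10)
        spec = ModelSpec("improved", (Poly("amap_mmHg", 2),))
        assert fit_logistic(spec, data).deviance == pytest.approx(
            fit_logistic(spec, rescaled).deviance, abs=1e-6
        )

    def test_constant_predictor_basis_rejected(self):
        with pytest.raises(ValueError):
            polynomial_basis(np.ones(10), 2)

    def test_spline_column_count(self, rng):
        x = rng.normal(size=40)
        assert natural_spline_basis(x, 2).shape == (40, 2)
        assert natural_spline_basis(x, 3).shape == (40, 3)

    def test_spline_linear_beyond_boundaries(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 30), [2.0, 3.0, 4.0]])
        B = natural_spline_basis(x, 2, knots=np.array([0.0, 0.5, 1.0]))
        outside = B[-3:]  # evaluated at 2, 3, 4: equally spaced
        second_diff = outside[0] - 2 * outside[1] + outside[2]
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-9)

    def test_spline_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            natural_spline_basis(np.array([1.0, 1.0, 2.0]), 3)


class TestLrt:
    def test_identical_models(self, rng):
        data = quadratic_data(rng)
        fit = fit_logistic(ModelSpec("improved", (Poly("amap_mmHg", 1),)), data)
        res = likelihood_ratio_test(fit, fit)
        assert res["deviance_diff"] == 0.0 and res["p"] == 1.0

    def test_non_nested_rejected(self, rng):
        data = quadratic_data(rng)
        data["other"] = rng.normal(size=len(data))
        a = fit_logistic(ModelSpec("improved", (Covariate("amap_mmHg"),)), data)
        b = fit_logistic(ModelSpec("improved", (Covariate("other"),)), data)
        with pytest.raises(ValueError):
            likelihood_ratio_test(a, b)

    def test_p_equals_chi2_tail(self, rng):
        data = quadratic_data(rng)
        lin = fit_logistic(ModelSpec("improved", (Poly("amap_mmHg", 1),)), data)
        quad = fit_logistic(ModelSpec("improved", (Poly("amap_mmHg", 2),)), data)
        res = likelihood_ratio_test(lin, quad)
        assert res["df_diff"] == 1
        assert res["p"] == pytest.approx(
            chi2.sf(lin.deviance - quad.deviance, 1), abs=1e-12
        )

    def test_null_calibration_at_small_n(self):
        """Under the null the 1-df LRT rejects at ~alpha."""
        rejections = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame(
                {
                    "improved": (rng.random(60) < 0.5).astype(float),
                    "amap_mmHg": rng.normal(90, 10, 60),
                }
            )
            lin = fit_logistic(ModelSpec("improved", (Poly("amap_mmHg", 1),)), data)
            quad = fit_logistic(ModelSpec("improved", (Poly("amap_mmHg", 2),)), data)
            rejections += likelihood_ratio_test(lin, quad)["p"] < 0.05
        # binomial(200, 0.05): 3 sd ~ 0.046
        assert abs(rejections / reps - 0.05) < 0.05


class TestLoocv:
    def test_null_model_closed_form(self):
        """LOO Brier of the intercept model from held-out class proportions."""
        data = outcome_frame(42, 61)
        err = loocv_error(ModelSpec("improved", ()), data)
        expected = (42 * (61 / 102) ** 2 + 61 * (42 / 102) ** 2) / 103
        assert err == pytest.approx(expected, abs=1e-8)
        assert round(err, 3) == 0.246

    def test_four_row_null_matches_manual_folds(self):
        data = outcome_frame(2, 2)
        # each fold predicts mean of the other 3 labels
        manual = np.mean([(1 - 1 / 3) ** 2, (1 - 1 / 3) ** 2, (2 / 3) ** 2, (2 / 3) ** 2])
        assert loocv_error(ModelSpec("improved", ()), data) == pytest.approx(
            manual, abs=1e-10
        )

    def test_covariate_model_matches_independent_mle_folds(self, rng):
        data = quadratic_data(rng, 12, b=(0.1, 0.7, 0.0))
        spec = ModelSpec("improved", (Covariate("amap_mmHg"),))
        y = data["improved"].to_numpy()
        X = np.column_stack([np.ones(12), data["amap_mmHg"].to_numpy()])
        manual = []
        for i in range(12):
            mask = np.arange(12) != i
            beta = independent_logistic_mle(X[mask], y[mask])
            manual.append((y[i] - expit(X[i] @ beta)) ** 2)
        assert loocv_error(spec, data) == pytest.approx(np.mean(manual), abs=1e-6)

    def test_separable_predictor_classified_perfectly(self):
        data = pd.DataFrame(
            {"improved": [0.0] * 8 + [1.0] * 8, "x": list(range(16))}
        )
        res = loocv_classification(ModelSpec("improved", (Covariate("x"),)), data)
        assert res["accuracy"] == 1.0 and res["kappa"] == pytest.approx(1.0)

    def test_chance_probabilities_give_zero_kappa(self):
        from hemonet.models import _cohen_kappa

        y = np.array([0.0, 0.0, 1.0, 1.0])
        pred = np.array([1.0, 1.0, 1.0, 1.0])
        assert _cohen_kappa(y, pred) == pytest.approx(0.0)

    def test_toy_confusion_kappa_hand_formula(self):
        from hemonet.models import _cohen_kappa

        y = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        pred = np.array([1, 1, 0, 0, 0, 0, 1, 0], dtype=float)
        po = 6 / 8
        pe = (3 / 8) * (3 / 8) + (5 / 8) * (5 / 8)
        assert _cohen_kappa(y, pred) == pytest.approx((po - pe) / (1 - pe))


class TestSearch:
    def test_single_term_pool(self, rng):
        data = quadratic_data(rng, 60)
        best, board = exhaustive_model_search(
            [Poly("amap_mmHg", 2)], "improved", data
        )
        assert len(board) == 1 and best.terms == (Poly("amap_mmHg", 2),)

    def test_aicc_arithmetic(self, rng):
        data = quadratic_data(rng, 103)
        fit = fit_logistic(ModelSpec("improved", (Poly("amap_mmHg", 2),)), data)
        assert fit.n_params == 3
        assert fit.aicc == pytest.approx(fit.aic + 24 / 99, abs=1e-10)

    def test_planted_term_recovered(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = quadratic_data(rng, 500, b=(0.2, 0.6, -1.2))
            data["age"] = rng.normal(48, 19, 500)
            data["ahr_bpm"] = rng.normal(80, 12, 500)
            pool = [Poly("amap_mmHg", 2), Covariate("age"), Covariate("ahr_bpm")]
            best, _ = exhaustive_model_search(pool, "improved", data)
            wins += Poly("amap_mmHg", 2) in best.terms
        assert wins >= 18


class TestThresholdAndRoc:
    def test_perfect_probs_return_half(self):
        labels = np.array([0.0, 0.0, 1.0, 1.0])
        assert calibrate_threshold(labels, labels) == 0.5

    def test_matches_exhaustive_scan(self, rng):
        probs = rng.uniform(size=40)
        labels = (rng.random(40) < 1 - probs).astype(float)  # anti-correlated
        t = calibrate_threshold(probs, labels)
        gaps = {}
        for c in np.append(np.unique(probs), 0.5):
            pred = probs >= c
            gaps[c] = abs(
                np.mean(pred[labels == 1]) - np.mean(~pred[labels == 0])
            )
        assert gaps[t] == pytest.approx(min(gaps.values()), abs=1e-12)

    def test_symmetric_scores_near_half(self, rng):
        labels = np.repeat([0.0, 1.0], 100)
        probs = np.concatenate(
            [rng.normal(0.4, 0.1, 100), rng.normal(0.6, 0.1, 100)]
        ).clip(0, 1)
        assert abs(calibrate_threshold(probs, labels) - 0.5) < 0.07

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(np.array([0.2, 0.8]), np.array([1.0, 1.0]))

    def test_perfect_separation_auc_one(self):
        res = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert res["auc"] == 1.0

    def test_independent_probs_auc_half(self, rng):
        probs = rng.uniform(size=2000)
        labels = (rng.random(2000) < 0.5).astype(float)
        assert roc_auc(probs, labels)["auc"] == pytest.approx(0.5, abs=0.05)

    def test_matches_pair_counting(self, rng):
        probs = np.array([0.1, 0.4, 0.35, 0.8, 0.8, 0.7])
        labels = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        pos, neg = probs[labels == 1], probs[labels == 0]
        pairs = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert roc_auc(probs, labels)["auc"] == pytest.approx(
            pairs / (len(pos) * len(neg)), abs=1e-12
        )


class TestUnivariateTable:
    def test_identical_groups_t_p_one(self):
        data = pd.DataFrame(
            {
                "improved": [0, 0, 0, 1, 1, 1],
                "age": [40.0, 50.0, 60.0, 40.0, 50.0, 60.0],
            }
        )
        table = cohort_univariate_table(data)
        assert table.loc[table["variable"] == "age", "p"].iloc[0] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        data = pd.DataFrame(
            {
                "improved": [0] * 36 + [1] * 33 + [0] * 25 + [1] * 9,
                "nli": ["cervical"] * 69 + ["non-cervical"] * 34,
            }
        )
        table = cohort_univariate_table(data)
        p_pkg = table.loc[table["variable"] == "nli", "p"].iloc[0]
        # two-sided Fisher by enumerating hypergeometric tables at least as
        # extreme as the observed one
        M, n, N, k = 103, 69, 42, 33  # total, cervical, improvers, observed
        p_obs = hypergeom.pmf(k, M, n, N)
        p_exact = sum(
            hypergeom.pmf(x, M, n, N)
            for x in range(max(0, N + n - M), min(n, N) + 1)
            if hypergeom.pmf(x, M, n, N) <= p_obs + 1e-12
        )
        assert p_pkg == pytest.approx(p_exact, abs=1e-8)

    def test_layout_covers_expected_variables(self, small_cohort):
        _, _, clinical, _ = small_cohort
        table = cohort_univariate_table(clinical)
        assert {"age", "ais_admission", "nli"} <= set(table["variable"])
        assert {"no_improve", "improve", "missing", "p"} <= set(table.columns)
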