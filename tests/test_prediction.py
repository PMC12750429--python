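import numpy as np
import pandas as pd
import pytest

from slrwalk.features import FEATURE_COLUMNS
from slrwalk.prediction import (
    CandidateModelFit,
    _l1_logistic,
    build_prediction_model,
    confusion_metrics,
    enumerate_candidates,
    evaluate,
    fit_candidate,
    impute_overall_median,
    lasso_screen,
    null_model_aic,
    select_best,
    standardize,
)
from slrwalk.stats import correlation_screen
from slrwalk.synthetic import GENERATING_PAIR, CohortConfig, generate_feature_table


def _toy_table(n=80, seed=0, beta=(1.2, -0.8), n_noise=2):
    """Logistic data with two informative predictors and noise columns."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 2 + n_noise))
    eta = beta[0] * x[:, 0] + beta[1] * x[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    cols = ["p1", "p2"] + [f"noise{i}" for i in range(n_noise)]
    df = pd.DataFrame(x, columns=cols)
    df["group"] = np.where(y == 1, "WD", "WI")
    return df, cols


class TestImputation:
    def test_single_missing_value_gets_overall_median(self):
        df = pd.DataFrame({"v": [1.0, 2.0, np.nan, 4.0], "group": list("WWII")})
        out = impute_overall_median(df, ["v"])
        assert out.v.tolist() == [1.0, 2.0, 2.0, 4.0]

    def test_complete_table_unchanged(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        pd.testing.assert_frame_equal(impute_overall_median(df, ["v"]), df)

    def test_multiple_missing_share_the_same_median(self):
        df = pd.DataFrame({"v": [1.0, np.nan, 3.0, np.nan, 5.0]})
        out = impute_overall_median(df, ["v"])
        assert out.v.tolist() == [1.0, 3.0, 3.0, 3.0, 5.0]

    def test_fully_missing_variable_rejected(self):
        df = pd.DataFrame({"v": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="v"):
            impute_overall_median(df, ["v"])


class TestLassoScreen:
    def test_large_lambda_shrinks_everything_to_zero(self):
        df, cols = _toy_table()
        X, _, _ = standardize(df[cols].to_numpy())
        y = (df.group == "WD").to_numpy(float)
        coef, _ = _l1_logistic(X, y, lam=10.0)
        assert not np.any(coef)

    def test_zero_lambda_matches_unpenalized_glm(self):
        import statsmodels.api as sm

        df, cols = _toy_table(n=200, seed=3)
        X, _, _ = standardize(df[cols].to_numpy())
        y = (df.group == "WD").to_numpy(float)
        coef, icpt = _l1_logistic(X, y, lam=0.0)
        res = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(coef, res.params[1:], atol=1e-4)
        assert icpt == pytest.approx(res.params[0], abs=1e-4)

    def test_penalty_path_is_monotone_in_support_size(self):
        df, cols = _toy_table(n=120, seed=4, n_noise=6)
        X, _, _ = standardize(df[cols].to_numpy())
        y = (df.group == "WD").to_numpy(float)
        sizes = []
        for lam in np.geomspace(1.0, 1e-4, 25):
            coef, _ = _l1_logistic(X, y, lam)
            sizes.append(int(np.count_nonzero(coef)))
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_screen_keeps_true_predictors_on_easy_data(self):
        df, cols = _toy_table(n=200, seed=5)
        res = lasso_screen(df, cols, seed=0)
        assert {"p1", "p2"} <= set(res.nonzero)
        assert res.optimal_lambda > 0
        assert set(res.nonzero) <= set(cols)

    def test_true_pair_selected_across_generator_seeds(self):
        hits = 0
        for s in range(8):
            table = generate_feature_table(CohortConfig(n_per_group=100, seed=3000 + s))
            complete = impute_overall_median(table, list(FEATURE_COLUMNS))
            res = lasso_screen(complete, seed=s)
            hits += set(GENERATING_PAIR) <= set(res.nonzero)
        assert hits >= 7

    def test_incomplete_table_rejected(self):
        df, cols = _toy_table()
        df.loc[0, "p1"] = np.nan
        with pytest.raises(ValueError, match="complete"):
            lasso_screen(df, cols)


class TestEnumerateCandidates:
    def _screen(self, n=40, seed=0, corr_pair=None):
        rng = np.random.default_rng(seed)
        data = {v: rng.standard_normal(n) for v in "ABCD"}
        if corr_pair:  # make the pair strongly correlated
            a, b = corr_pair
            data[b] = data[a] + 0.05 * rng.standard_normal(n)
        return correlation_screen(pd.DataFrame(data))

    def test_four_variables_one_correlated_pair_give_five_models(self):
        screen = self._screen(corr_pair=("A", "B"))
        pairs = enumerate_candidates(["A", "B", "C", "D"], screen)
        assert len(pairs) == 5
        assert ("A", "B") not in pairs

    def test_all_pairs_significant_is_an_error(self, rng):
        base = rng.standard_normal(40)
        df = pd.DataFrame({v: base + 0.01 * rng.standard_normal(40) for v in "ABC"})
        screen = correlation_screen(df)
        with pytest.raises(ValueError, match="correlated"):
            enumerate_candidates(["A", "B", "C"], screen)

    def test_three_uncorrelated_variables_give_three_models(self):
        screen = self._screen()
        assert len(enumerate_candidates(["A", "B", "C"], screen)) == 3

    def test_single_variable_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            enumerate_candidates(["A"], self._screen())


class TestFitCandidate:
    def test_null_model_aic_closed_form(self):
        y = np.concatenate([np.ones(20), np.zeros(20)])
        assert null_model_aic(y) == pytest.approx(2 - 2 * (40 * np.log(0.5)), rel=1e-12)
        assert null_model_aic(y) == pytest.approx(57.45, abs=0.01)

    def test_odds_ratios_are_exp_of_coefficients(self):
        df, _ = _toy_table(n=120, seed=6)
        fit = fit_candidate(df, ("p1", "p2"))
        for name, coef in fit.params.items():
            assert fit.odds_ratios[name] == pytest.approx(np.exp(coef), rel=1e-12)

    def test_matches_independent_newton_irls_oracle(self):
        df, _ = _toy_table(n=150, seed=7)
        fit = fit_candidate(df, ("p1", "p2"))
        Z, _, _ = standardize(df[["p1", "p2"]].to_numpy())
        X = np.column_stack([np.ones(len(df)), Z])
        y = (df.group == "WD").to_numpy(float)
        beta = np.zeros(3)
        for _ in range(50):  # plain Newton-Raphson IRLS
            p = 1 / (1 + np.exp(-X @ beta))
            W = p * (1 - p)
            H = X.T @ (X * W[:, None])
            beta = beta + np.linalg.solve(H, X.T @ (y - p))
        p = np.clip(1 / (1 + np.exp(-X @ beta)), 1e-300, 1 - 1e-16)
        llf = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        np.testing.assert_allclose(list(fit.params.values()), beta, atol=1e-6)
        np.testing.assert_allclose(list(fit.bse.values()), se, atol=1e-6)
        assert fit.aic == pytest.approx(2 * 3 - 2 * llf, abs=1e-6)

    def test_aic_invariant_to_predictor_offset(self):
        df, _ = _toy_table(n=100, seed=8)
        base = fit_candidate(df, ("p1", "p2"))
        shifted = df.copy()
        shifted["p1"] = shifted["p1"] + 1000.0
        assert fit_candidate(shifted, ("p1", "p2")).aic == pytest.approx(base.aic, abs=1e-6)

    def test_perfect_separation_flagged_with_limit_aic(self):
        n = 30
        x = np.linspace(-2, 2, n)
        df = pd.DataFrame({"p1": x, "p2": np.random.default_rng(0).standard_normal(n),
                           "group": np.where(x > 0, "WD", "WI")})
        fit = fit_candidate(df, ("p1", "p2"))
        assert fit.separated
        assert fit.aic == pytest.approx(6.0, abs=0.1)
        preds = fit.predict_proba(df)
        assert np.all(np.isfinite(preds))

    def test_single_class_rejected(self):
        df, _ = _toy_table(n=40)
        df["group"] = "WD"
        with pytest.raises(ValueError, match="single class"):
            fit_candidate(df, ("p1", "p2"))


class TestSelectBest:
    @staticmethod
    def _stub(pair, aic):
        return CandidateModelFit(pair=pair, params={}, bse={}, p_values={}, aic=aic,
                                 odds_ratios={}, or_ci={}, separated=False, n=40)

    def test_published_style_aic_list_selects_minimum(self):
        aics = [47.67, 40.27, 31.65, 46.71, 22.24]
        cands = [self._stub(("a", str(i)), a) for i, a in enumerate(aics)]
        assert select_best(cands).aic == 22.24

    def test_single_candidate_returned(self):
        c = self._stub(("a", "b"), 10.0)
        assert select_best([c]) is c

    def test_tie_breaks_to_earlier_candidate_order(self):
        c1, c2 = self._stub(("a", "b"), 5.0), self._stub(("a", "c"), 5.0)
        assert select_best([c1, c2]) is c1


class TestEvaluate:
    def test_confusion_metrics_from_counts(self):
        m = confusion_metrics(tp=17, fn=3, fp=2, tn=18)
        assert m["accuracy"] == pytest.approx(0.875)
        assert m["sensitivity"] == pytest.approx(0.850)
        assert m["specificity"] == pytest.approx(0.900)

    def test_perfectly_separated_scores_have_auc_one(self):
        n = 30
        x = np.linspace(-2, 2, n)
        df = pd.DataFrame({"p1": x, "p2": 0.1 * x,
                           "group": np.where(x > 0, "WD", "WI")})
        fit = fit_candidate(df, ("p1", "p2"))
        report = evaluate(fit, df, n_bootstrap=200, seed=1)
        assert report.auc == pytest.approx(1.0)
        assert report.auc_ci[1] == pytest.approx(1.0)
        assert report.accuracy == pytest.approx(1.0)

    def test_uninformative_scores_give_chance_auc(self):
        rng = np.random.default_rng(5)
        n = 600
        df = pd.DataFrame({"p1": rng.standard_normal(n), "p2": rng.standard_normal(n),
                           "group": np.where(rng.random(n) < 0.5, "WD", "WI")})
        fit = fit_candidate(df, ("p1", "p2"))
        report = evaluate(fit, df, n_bootstrap=100, seed=2)
        assert abs(report.auc - 0.5) < 0.1

    def test_auc_equals_mann_whitney_formulation(self):
        df, _ = _toy_table(n=150, seed=10)
        fit = fit_candidate(df, ("p1", "p2"))
        report = evaluate(fit, df, n_bootstrap=100, seed=3)
        scores = fit.predict_proba(df)
        y = (df.group == "WD").to_numpy(float)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((pos_i > neg).sum() + 0.5 * (pos_i == neg).sum() for pos_i in pos)
        assert report.auc == pytest.approx(wins / (len(pos) * len(neg)), rel=1e-12)

    def test_cross_validated_mode_scores_held_out_patients(self):
        df, _ = _toy_table(n=120, seed=11)
        fit = fit_candidate(df, ("p1", "p2"))
        rep_in = evaluate(fit, df, n_bootstrap=50, seed=4)
        rep_cv = evaluate(fit, df, n_bootstrap=50, seed=4, mode="cross_validated")
        assert rep_cv.mode == "cross_validated"
        # held-out performance cannot systematically beat in-sample by much
        assert rep_cv.auc <= rep_in.auc + 0.05


class TestEndToEnd:
    def test_generating_pair_recovered_on_most_seeds(self):
        hits = 0
        n_seeds = 10
        for s in range(n_seeds):
            table = generate_feature_table(CohortConfig(n_per_group=100, seed=4000 + s))
            report = build_prediction_model(table, seed=s, n_bootstrap=50)
            if report.best is not None and \
                    tuple(sorted(report.best.pair)) == tuple(sorted(GENERATING_PAIR)):
                hits += 1
        assert hits >= 7

    def test_eo_coefficient_positive_for_walking_dependent(self):
        table = generate_feature_table(CohortConfig(n_per_group=100, seed=4100))
        report = build_prediction_model(table, seed=0, n_bootstrap=50)
        assert report.best is not None
        if "rms_eo_con" in report.best.pair:
            assert report.best.params["rms_eo_con"] > 0

    def test_missing_values_are_counted_and_imputed(self):
        from slrwalk.synthetic import PAPER_MISSINGNESS

        table = generate_feature_table(
            CohortConfig(n_per_group=20, seed=77, missingness=PAPER_MISSINGNESS))
        n_missing = int(table[list(FEATURE_COLUMNS)].isna().to_numpy().sum())
        report = build_prediction_model(table, seed=0, n_bootstrap=50)
        assert report.n_imputed == n_missing
        assert report.evaluation is not None
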