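import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from painequity.cohort import GeneratorParams, generate_cohort
from painequity.survival import (
    CoxPH,
    SeparationError,
    adjusted_pain_hr,
    forest_frame,
    km_estimator,
    logrank_test,
    stratified_fits,
    survival_design,
)


class TestKaplanMeier:
    def test_three_record_product_limit(self):
        km = km_estimator([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_allclose(km.times, [1.0, 3.0])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        np.testing.assert_allclose(km.at_risk, [3, 1])

    def test_no_events_gives_unit_survival(self):
        km = km_estimator([1.0, 2.0], [0, 0])
        assert km.times.size == 0
        np.testing.assert_allclose(km.survival_at([0.5, 5.0]), [1.0, 1.0])

    def test_uncensored_distinct_times_equal_empirical_survival(self, rng):
        t = rng.permutation(np.arange(1.0, 11.0))
        km = km_estimator(t, np.ones(10, int))
        np.testing.assert_allclose(km.survival, (10 - np.arange(1, 11)) / 10, atol=1e-12)

    def test_no_censoring_matches_one_minus_ecdf(self, rng):
        t = rng.exponential(size=200)
        km = km_estimator(t, np.ones(200, int))
        ecdf = np.searchsorted(np.sort(t), km.times, side="right") / 200
        np.testing.assert_allclose(1 - km.survival, ecdf, atol=1e-12)

    def test_censored_at_event_time_counted_at_risk(self):
        km = km_estimator([1.0, 1.0, 2.0], [1, 0, 1])
        np.testing.assert_allclose(km.at_risk, [3, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])

    def test_grouped_curves(self):
        out = km_estimator([1, 2, 1, 2.0], [1, 1, 0, 0], group=["a", "a", "b", "b"])
        assert set(out) == {"a", "b"}
        assert out["b"].times.size == 0


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.r_[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = np.r_[1, 0, 1, 1, 0, 1]
        g = np.r_[0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_small_worked_example_against_enumeration(self, rng):
        """O, E, V sums recomputed independently per event time."""
        t = rng.integers(1, 6, 40).astype(float)
        e = (rng.random(40) < 0.7).astype(int)
        g = (rng.random(40) < 0.5).astype(int)
        o1 = e1 = v = 0.0
        in1 = g == 1
        for tau in np.unique(t[e == 1]):
            n_tau = (t >= tau).sum()
            n1 = ((t >= tau) & in1).sum()
            d_tau = ((t == tau) & (e == 1)).sum()
            o1 += ((t == tau) & (e == 1) & in1).sum()
            e1 += d_tau * n1 / n_tau
            if n_tau > 1:
                v += d_tau * (n1 / n_tau) * (1 - n1 / n_tau) * (n_tau - d_tau) / (n_tau - 1)
        res = logrank_test(t, e, np.where(in1, "one", "zero"))
        assert res.statistic == pytest.approx((o1 - e1) ** 2 / v, abs=1e-10)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        g = (rng.random(150) < 0.5).astype(int)
        t = rng.exponential(1 + 0.7 * g)
        e = (rng.random(150) < 0.8).astype(int)
        res = logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1.0, 2.0], [0, 0], ["a", "b"])


class TestCoxFit:
    def test_two_group_fit_matches_brute_force_maximiser(self, rng):
        x = np.r_[np.zeros(30), np.ones(30)]
        t = rng.exponential(1 / np.exp(0.7 * x))
        model = CoxPH(t, np.ones(60, int), x[:, None])
        res = model.fit()
        brute = optimize.minimize_scalar(
            lambda b: -model.partial_loglik([b]), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert res.params.iloc[0] == pytest.approx(brute.x, abs=1e-6)

    def test_efron_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 250
        X = rng.normal(size=(n, 3))
        t = np.ceil(rng.exponential(1 / np.exp(X @ [0.5, -0.3, 0.2])) * 4)
        e = (rng.random(n) < 0.8).astype(int)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = t, e
        ref = CoxPHFitter().fit(df, "T", "E")
        mine = CoxPH(t, e, X, ties="efron").fit()
        np.testing.assert_allclose(mine.params.values, ref.params_.values, atol=1e-6)
        np.testing.assert_allclose(mine.bse.values, ref.standard_errors_.values, atol=1e-6)

    def test_breslow_equals_efron_on_distinct_times(self, rng):
        X = rng.normal(size=(120, 2))
        t = rng.exponential(1 / np.exp(X @ [0.4, -0.2]))
        e = (rng.random(120) < 0.7).astype(int)
        b = CoxPH(t, e, X, ties="breslow").fit()
        f = CoxPH(t, e, X, ties="efron").fit()
        np.testing.assert_allclose(b.params.values, f.params.values, atol=1e-10)
        np.testing.assert_allclose(b.loglik, f.loglik, atol=1e-10)

    def test_estimate_is_local_maximum(self, rng):
        X = rng.normal(size=(150, 2))
        t = rng.exponential(1 / np.exp(X @ [0.3, 0.5]))
        e = (rng.random(150) < 0.8).astype(int)
        model = CoxPH(t, e, X)
        res = model.fit()
        best = model.partial_loglik(res.params.values)
        for _ in range(1000):
            pert = res.params.values + rng.normal(scale=0.05, size=2)
            assert model.partial_loglik(pert) <= best + 1e-10

    def test_time_scaling_leaves_estimates_unchanged(self, rng):
        X = rng.normal(size=(100, 2))
        t = rng.exponential(1 / np.exp(X @ [0.4, -0.6]))
        e = (rng.random(100) < 0.7).astype(int)
        r1 = CoxPH(t, e, X).fit()
        r2 = CoxPH(t * 365.25, e, X).fit()
        np.testing.assert_allclose(r1.params.values, r2.params.values, atol=1e-8)
        km1 = km_estimator(t, e)
        km2 = km_estimator(t * 365.25, e)
        np.testing.assert_allclose(km1.survival, km2.survival, atol=1e-12)
        lr1 = logrank_test(t, e, X[:, 0] > 0)
        lr2 = logrank_test(t * 365.25, e, X[:, 0] > 0)
        assert lr1.statistic == pytest.approx(lr2.statistic, abs=1e-10)

    def test_null_covariate_interval_covers_one(self, rng):
        """Independent covariate: HR ~ 1 and the Wald CI covers 1 at about
        the nominal rate."""
        covered = 0
        for _ in range(60):
            x = (rng.random(400) < 0.5).astype(float)
            t = rng.exponential(1.0, 400)
            e = (rng.random(400) < 0.6).astype(int)
            res = CoxPH(t, e, x[:, None]).fit()
            lo, hi = res.conf_int().iloc[0]
            covered += lo <= 1.0 <= hi
        assert covered >= 50

    def test_separation_detected(self):
        # covariate perfectly orders the uncensored survival times
        t = np.arange(1.0, 21.0)
        x = (t <= 10).astype(float)
        with pytest.raises(SeparationError):
            CoxPH(t, np.ones(20, int), x[:, None]).fit()

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least one event"):
            CoxPH([1.0, 2.0], [0, 0], np.ones((2, 1)))
        with pytest.raises(ValueError, match="ties"):
            CoxPH([1.0], [1], np.ones((1, 1)), ties="exact")

    def test_results_surface(self, rng):
        x = (rng.random(200) < 0.4).astype(float)
        t = rng.exponential(1 / np.exp(0.5 * x))
        e = (rng.random(200) < 0.8).astype(int)
        res = CoxPH(t, e, pd.DataFrame({"pain": x})).fit()
        assert res.converged
        assert (res.hazard_ratios > 0).all()
        ci = res.conf_int()
        assert ci.loc["pain", "hr_low"] < res.hazard_ratios["pain"] < ci.loc["pain", "hr_high"]
        assert np.all(np.diff(res.loglik_trace) >= -1e-9)
        assert "pain" in res.summary()


class TestCohortFits:
    def test_adjusted_fit_reports_pain_first(self, small_cohort):
        res = adjusted_pain_hr(small_cohort)
        assert res.params.index[0] == "pain"
        assert res.converged

    def test_adjusted_and_crude_agree_without_confounding(self):
        """Covariates carry no hazard effect here, so adjustment changes the
        pain HR only within Monte-Carlo error."""
        params = GeneratorParams(n=40_000, seed=30, covariate_log_hrs={},
                                 baseline_hazard=0.02)
        c = generate_cohort(params)
        crude = CoxPH(c["time"], c["dead"], c[["pain"]]).fit()
        adj = adjusted_pain_hr(c)
        assert adj.params["pain"] == pytest.approx(crude.params["pain"], abs=0.1)
        assert np.exp(adj.params["pain"]) == pytest.approx(1.30, abs=0.25)

    def test_event_aware_reference_coding(self):
        """A covariate category with no deaths is merged into the reference
        instead of producing a divergent coefficient."""
        rng = np.random.default_rng(5)
        n = 400
        c = generate_cohort(GeneratorParams(n=n, seed=31, baseline_hazard=0.05))
        # force a deathless category
        c.loc[c["marital"] == "never_married", "dead"] = 0
        with pytest.warns(UserWarning, match="never_married"):
            X = survival_design(c)
        assert "marital[never_married]" not in X.columns

    def test_stratified_fits_and_skip_rule(self):
        c = generate_cohort(GeneratorParams(n=12_000, seed=32, baseline_hazard=0.02))
        fits, skipped = stratified_fits(c, "gender")
        assert set(fits) == {"male", "female"}
        frame = forest_frame(fits)
        assert list(frame.columns) == ["stratum", "hr", "hr_low", "hr_high", "n", "events"]
        # a tiny stratum is skipped with a reason
        c2 = c.copy()
        c2.loc[c2.index[:30], "gender"] = "other"
        fits2, skipped2 = stratified_fits(c2, "gender")
        assert "other" in skipped2

    def test_pooled_estimate_between_balanced_stratum_estimates(self):
        c = generate_cohort(GeneratorParams(n=30_000, seed=33, baseline_hazard=0.02))
        fits, _ = stratified_fits(c, "gender")
        pooled = adjusted_pain_hr(c).params["pain"]
        betas = sorted(f.params["pain"] for f in fits.values())
        assert betas[0] - 0.15 < pooled < betas[1] + 0.15
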