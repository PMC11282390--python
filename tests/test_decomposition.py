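import numpy as np
import pandas as pd
import pytest

from painequity.cohort import GeneratorParams, generate_cohort
from painequity.decomposition import (
    ConcentrationDecomposition,
    FactorSpec,
    build_design,
    default_factor_specs,
    economic_tertiles,
    fit_linear_probability,
)


@pytest.fixture()
def toy_cohort():
    return pd.DataFrame({
        "education": ["illiterate", "primary", "secondary", "university"],
        "gender": ["male", "female", "female", "male"],
    })


class TestFactorSpec:
    def test_reference_must_be_a_category(self):
        with pytest.raises(ValueError):
            FactorSpec("x", ("a", "b"), "c")

    def test_indicator_categories_exclude_reference(self):
        spec = FactorSpec("education", ("illiterate", "primary", "secondary", "university"),
                          "university")
        assert spec.indicator_categories == ("illiterate", "primary", "secondary")


class TestBuildDesign:
    def test_four_level_factor_yields_three_columns(self, toy_cohort):
        spec = FactorSpec("education", ("illiterate", "primary", "secondary", "university"),
                          "university")
        X, xbar = build_design(toy_cohort, [spec])
        assert list(X.columns) == [
            "education[illiterate]", "education[primary]", "education[secondary]"]
        np.testing.assert_allclose(xbar.to_numpy(), [0.25, 0.25, 0.25])

    def test_empty_category_dropped_with_warning(self):
        df = pd.DataFrame({"education": ["illiterate", "primary", "primary"]})
        spec = FactorSpec("education", ("illiterate", "primary", "secondary", "university"),
                          "university")
        with pytest.warns(UserWarning, match="secondary"):
            X, _ = build_design(df, [spec])
        assert list(X.columns) == ["education[illiterate]", "education[primary]"]

    def test_single_observed_category_skipped_with_warning(self):
        df = pd.DataFrame({"gender": ["male", "male", "male"]})
        spec = FactorSpec("gender", ("male", "female"), "male")
        with pytest.warns(UserWarning, match="single observed category"):
            X, _ = build_design(df, [spec])
        assert X.shape[1] == 0

    def test_unseen_category_raises(self, toy_cohort):
        spec = FactorSpec("gender", ("male",), "male")
        with pytest.raises(ValueError, match="unseen"):
            build_design(toy_cohort, [spec])

    def test_weighted_means(self):
        df = pd.DataFrame({"gender": ["male", "female", "female"]})
        spec = FactorSpec("gender", ("male", "female"), "male")
        _, xbar = build_design(df, [spec], weights=[1, 1, 2])
        assert xbar["gender[female]"] == pytest.approx(0.75)


class TestLinearProbabilityModel:
    def test_outcome_equal_to_indicator_recovers_unit_slope(self):
        X = pd.DataFrame({"a": [0, 1, 0, 1.0], "b": [0, 0, 1, 0.0]})
        beta = fit_linear_probability(X["a"].to_numpy(), X)
        np.testing.assert_allclose(beta, [0.0, 1.0, 0.0], atol=1e-12)

    def test_matches_normal_equations_on_toy_data(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0]})
        y = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
        A = np.column_stack([np.ones(5), X["x"]])
        expected = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fit_linear_probability(y, X), expected, atol=1e-12)

    def test_rank_deficiency_names_offenders(self):
        X = pd.DataFrame({"a": [0, 1, 0, 1.0], "dup": [0, 1, 0, 1.0]})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_linear_probability(np.array([0, 1, 1, 0.0]), X)


class TestEconomicTertiles:
    def test_unweighted_split_is_even(self, rng):
        pce = rng.lognormal(9, 1, 900)
        labels, counts = np.unique(economic_tertiles(pce), return_counts=True)
        assert set(labels) == {"tertile1", "tertile2", "tertile3"}
        np.testing.assert_allclose(counts, 300, atol=1)

    def test_tertiles_are_monotone_in_pce(self, rng):
        pce = rng.lognormal(9, 1, 300)
        lab = economic_tertiles(pce)
        assert pce[lab == "tertile1"].max() < pce[lab == "tertile3"].min()


class TestDecomposition:
    def test_exact_identity_and_permutation_invariance(self):
        cohort = generate_cohort(GeneratorParams(n=3000, seed=5))
        res = ConcentrationDecomposition.from_dataframe(cohort).fit()
        assert res.total_index == pytest.approx(res.explained + res.residual, abs=1e-8)
        assert res.table["rate_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        # row-level identity
        prod = res.table["elasticity"] * res.table["category_index"]
        np.testing.assert_allclose(prod, res.table["contribution"], atol=1e-12)

        perm = cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = ConcentrationDecomposition.from_dataframe(perm).fit()
        assert res2.total_index == pytest.approx(res.total_index, abs=1e-10)
        merged = res.table.merge(res2.table, on=["variable", "category"])
        np.testing.assert_allclose(merged["contribution_x"], merged["contribution_y"], atol=1e-10)

    def test_weighted_identity(self, rng):
        cohort = generate_cohort(GeneratorParams(n=2500, seed=9))
        w = rng.uniform(0.5, 3.0, len(cohort))
        res = ConcentrationDecomposition(
            cohort["pain"].to_numpy(float), cohort["pce"].to_numpy(float), cohort,
            weights=w).fit()
        assert res.total_index == pytest.approx(res.explained + res.residual, abs=1e-8)

    def test_single_factor_rate_is_100(self, rng):
        n = 800
        ses = rng.normal(size=n)
        g = np.where(rng.random(n) < 0.5, "rural", "urban")
        y = ((g == "rural") & (rng.random(n) < 0.6)).astype(float)
        y[rng.random(n) < 0.1] = 1.0
        cohort = pd.DataFrame({"location": g})
        res = ConcentrationDecomposition(
            y, ses, cohort, factors=[FactorSpec("location", ("rural", "urban"), "urban")]).fit()
        assert res.contribution_rates()["location"] == pytest.approx(100.0, abs=1e-9)

    def test_location_only_coupling_dominates_explained_share(self):
        """When only location is coupled to SES and location is the only pain
        covariate, its contribution dominates the explained part."""
        params = GeneratorParams(
            n=40_000, seed=21,
            ses_coupling={"location": 3.4},
            pain_rank_slope=0.0,
            pain_covariate_effects={"location[urban]": -0.8},
        )
        cohort = generate_cohort(params)
        res = ConcentrationDecomposition.from_dataframe(cohort).fit()
        rates = res.contribution_rates()
        assert rates["location"] > 80.0

    def test_margeff_mode_closes_decomposition(self):
        cohort = generate_cohort(GeneratorParams(n=2000, seed=13))
        res = ConcentrationDecomposition.from_dataframe(cohort, model="margeff").fit()
        assert res.total_index == pytest.approx(res.explained + res.residual, abs=1e-12)
        assert np.isfinite(res.table["contribution"]).all()

    def test_sign_recovery_of_generating_gradient(self, default_cohort):
        """Education below the reference level and rural location carry
        negative contributions when generated with a pro-poor pain gradient."""
        res = ConcentrationDecomposition.from_dataframe(default_cohort).fit()
        t = res.table.set_index(["variable", "category"])
        assert t.loc[("education", "illiterate"), "contribution"] < 0
        assert t.loc[("location", "rural"), "contribution"] < 0
        assert t.loc[("econ", "tertile1"), "contribution"] < 0

    def test_summary_lists_all_factors(self, small_cohort):
        res = ConcentrationDecomposition.from_dataframe(small_cohort).fit()
        text = res.summary()
        for var in ("education", "location", "econ", "residual"):
            assert var in text


def test_default_specs_cover_nine_variables():
    specs = default_factor_specs()
    assert [s.variable for s in specs] == [
        "age_group", "gender", "education", "marital", "smoking",
        "drinking", "bmi_class", "econ", "location"]
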