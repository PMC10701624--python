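"""Year regressions, sequential ANCOVA and the between-country ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from accipiter.io import make_records
from accipiter.temporal import (
    ancova_sequential,
    country_anova,
    fit_group_regression,
    percent_change_over_interval,
)


from oracles import design_to_records as _design_to_records
from oracles import random_design, sequential_ss_oracle


class TestGroupRegression:
    def test_exact_line_recovered(self):
        years = np.array([1900, 1925, 1950, 1975, 2000], dtype=float)
        fit = fit_group_regression(years, -0.05 * years + 200)
        assert fit.slope == pytest.approx(-0.05)
        assert fit.intercept == pytest.approx(200)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_normal_equations(self):
        years = np.array([1900.0, 1910.0, 1930.0, 1960.0, 1990.0])
        values = np.array([105.2, 104.8, 105.9, 103.1, 102.4])
        fit = fit_group_regression(years, values)
        xbar, ybar = years.mean(), values.mean()
        slope = ((years - xbar) * (values - ybar)).sum() / ((years - xbar) ** 2).sum()
        intercept = ybar - slope * xbar
        rss = ((values - (slope * years + intercept)) ** 2).sum()
        tss = ((values - ybar) ** 2).sum()
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        assert fit.r_squared == pytest.approx(1 - rss / tss, rel=1e-12)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            fit_group_regression([1900, 1901], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_group_regression([1900] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_r_squared_invariant_to_year_shift_slope_scales(self):
        rng = np.random.default_rng(5)
        years = rng.integers(1861, 2016, 50).astype(float)
        values = 105 - 0.02 * years + rng.normal(0, 1, 50)
        base = fit_group_regression(years, values)
        shifted = fit_group_regression(years - 1900, values)
        assert shifted.r_squared == pytest.approx(base.r_squared, rel=1e-10)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-10)
        scaled = fit_group_regression(years / 10, values)
        assert scaled.slope == pytest.approx(10 * base.slope, rel=1e-10)


class TestPercentChange:
    def test_zero_slope_zero_change(self):
        from accipiter.temporal import RegressionFit

        fit = RegressionFit(slope=0.0, intercept=90.0, r_squared=0.0, n=10)
        assert percent_change_over_interval(fit, 1900, 2000) == 0.0

    def test_published_equation_century_decline(self):
        # NS female femur trend: about a 2.4% decline over 1900-2000
        from accipiter.temporal import RegressionFit

        fit = RegressionFit(slope=-0.022, intercept=132.29, r_squared=0.07, n=28)
        assert percent_change_over_interval(fit, 1900, 2000) == pytest.approx(2.4, abs=0.05)

    def test_sign_flips_with_slope(self):
        from accipiter.temporal import RegressionFit

        up = RegressionFit(slope=0.022, intercept=40.0, r_squared=0.1, n=10)
        down = RegressionFit(slope=-0.022, intercept=132.0, r_squared=0.1, n=10)
        assert percent_change_over_interval(up, 1900, 2000) < 0
        assert percent_change_over_interval(down, 1900, 2000) > 0


class TestAncova:
    def test_sequential_ss_equal_nested_rss_differences(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            df = random_design(rng)
            res = ancova_sequential(_design_to_records(df))
            oracle = sequential_ss_oracle(df)
            for term, expected in oracle.items():
                got = res.table.loc[term, "sum_sq"]
                assert got == pytest.approx(expected, rel=1e-8, abs=1e-8), term

    def test_decomposition_sums_to_total_corrected_ss(self):
        rng = np.random.default_rng(12)
        df = random_design(rng, n=60)
        res = ancova_sequential(_design_to_records(df))
        tss = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(tss, rel=1e-10)
        assert res.table["df"].sum() == len(df) - 1

    def test_orthogonal_design_order_independent(self):
        # balanced 2x2 with years symmetric within each cell: factors are
        # orthogonal, so sequential SS for Sex/Country match their marginal SS
        rows = []
        for sex in ("F", "M"):
            for group in ("NS", "DK"):
                for year in (1900.0, 1950.0, 2000.0):
                    value = 90 + 10 * (sex == "F") + 2 * (group == "DK") + 0.01 * year
                    rows.append({"group": group, "sex": sex, "year": year, "value": value})
        df = pd.DataFrame(rows)
        res = ancova_sequential(_design_to_records(df))
        swapped = df.copy()  # refit with Sex and Country roles exchanged
        swapped[["sex", "group"]] = swapped[["sex", "group"]].to_numpy()
        oracle = sequential_ss_oracle(df)
        # under orthogonality, each factor's SS is its marginal SS no matter
        # what was fitted before it: compare against last-position fits
        y = df["value"].to_numpy()

        def rss(cols):
            X = np.column_stack([np.ones(len(df))] + cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(((y - X @ beta) ** 2).sum())

        sex_d = (df["sex"] == "F").to_numpy(float)
        grp_d = (df["group"] == "DK").to_numpy(float)
        year = df["year"].to_numpy()
        marginal_sex = rss([year, grp_d]) - rss([year, grp_d, sex_d])
        assert res.table.loc["Sex", "sum_sq"] == pytest.approx(marginal_sex, rel=1e-8)
        assert res.table.loc["Sex", "sum_sq"] == pytest.approx(oracle["Sex"], rel=1e-8)

    def test_agrees_with_statsmodels_anova_lm(self):
        """Cross-check against statsmodels' Type I table.

        patsy orders same-degree terms with categoricals first, so the
        comparable term order is Sex, Country, Year + interactions.
        """
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        from accipiter.temporal import sequential_anova

        rng = np.random.default_rng(21)
        df = random_design(rng, n=50)
        data = pd.DataFrame(
            {
                "value": df["value"],
                "year": df["year"],
                "sex": pd.Categorical(df["sex"]),
                "country": pd.Categorical(df["group"]),
            }
        )
        mine = sequential_anova(
            data, terms=("Sex", "Country", "Year", "Year:Sex", "Year:Country")
        )
        ref = anova_lm(
            smf.ols(
                "value ~ year + C(sex) + C(country) + year:C(sex) + year:C(country)", data
            ).fit(),
            typ=1,
        )
        order = ["C(sex)", "C(country)", "year", "year:C(sex)", "year:C(country)", "Residual"]
        ref = ref.loc[order]
        assert np.allclose(mine["sum_sq"], ref["sum_sq"], rtol=1e-10)
        assert np.allclose(mine["df"], ref["df"])
        assert np.allclose(
            mine["f_value"].iloc[:-1], ref["F"].iloc[:-1], rtol=1e-10
        )

    def test_rank_deficient_design_names_term(self):
        rng = np.random.default_rng(13)
        df = random_design(rng)
        df["sex"] = "F"
        with pytest.raises(ValueError, match="Sex"):
            ancova_sequential(_design_to_records(df))

    def test_permuted_response_yields_uniform_year_pvalues(self):
        rng = np.random.default_rng(14)
        df = random_design(rng, n=80)
        pvals = []
        for _ in range(200):
            shuffled = df.copy()
            shuffled["value"] = rng.permutation(df["value"].to_numpy())
            res = ancova_sequential(_design_to_records(shuffled))
            pvals.append(res.table.loc["Year", "p_value"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestCountryAnova:
    def _records(self, means, n=12, sd=1.0, seed=0, sex="M"):
        rng = np.random.default_rng(seed)
        rows = []
        for country, mean in means.items():
            for i in range(n):
                rows.append(
                    {
                        "specimen_id": f"{country}{i}",
                        "country": country,
                        "period": "modern",
                        "element": "humerus",
                        "measurement_code": "GL",
                        "value_mm": rng.normal(mean, sd) if sd else mean,
                        "sex_recorded": sex,
                    }
                )
        return make_records(rows)

    def test_two_groups_f_equals_squared_t(self):
        records = self._records({"NO": 93.0, "DK": 91.0}, seed=3)
        res = country_anova(records, "humerus")
        a = records[records["country"] == "NO"]["value_mm"]
        b = records[records["country"] == "DK"]["value_mm"]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        row = res.anova.iloc[0]
        assert row["f_value"] == pytest.approx(t**2, rel=1e-10)
        assert row["p_value"] == pytest.approx(p, rel=1e-10)

    def test_degenerate_zero_variance_reported_not_raised(self):
        records = self._records({"NO": 93.0, "SE": 93.0}, sd=0.0)
        res = country_anova(records, "humerus")
        assert np.isnan(res.anova.iloc[0]["f_value"])

    def test_pooling_decision_pattern(self):
        # Norway and Sweden alike, Denmark smaller: NO-SE not significant,
        # Denmark pairs significant
        records = self._records({"NO": 93.3, "SE": 93.3, "DK": 90.0}, n=25, seed=4)
        res = country_anova(records, "humerus")
        pw = res.pairwise.set_index(["country_a", "country_b"])["p_value"]
        assert pw[("NO", "SE")] > 0.05
        assert pw[("DK", "NO")] < 0.001
        assert pw[("DK", "SE")] < 0.001

    def test_insufficient_groups_rejected(self):
        records = self._records({"NO": 93.0})
        with pytest.raises(ValueError):
            country_anova(records, "humerus")
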