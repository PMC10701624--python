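"""Temporal trend models: per-group OLS on collection year, sequential ANCOVA,
and the between-country one-way ANOVA.

The ANCOVA is the fixed-term-order model

    GL ~ Year + Sex + Country + Year:Sex + Year:Country

with sequential (Type I) sums of squares: each term's SS is the drop in
residual SS when it is added after all preceding terms, so the decomposition
sums exactly to the total corrected SS.  The published table uses this order,
and with unbalanced museum data the decomposition is order-dependent.  Year is
calendar year as-is (trend intercepts are at year 0, matching published
equations); categorical factors use treatment coding with the alphabetically
first level as reference — sequential SS and F are invariant to that choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import resolve_paired_elements

ANCOVA_TERMS = ("Year", "Sex", "Country", "Year:Sex", "Year:Country")


@dataclass
class RegressionFit:
    """OLS fit of measurement (mm) on calendar year for one group."""

    slope: float  # mm per year
    intercept: float  # mm at year 0
    r_squared: float
    n: int

    def predict(self, year) -> np.ndarray | float:
        return self.slope * np.asarray(year, dtype=float) + self.intercept

    def summary(self) -> str:
        return (
            f"y = {self.slope:+.4f} x + {self.intercept:.2f}   "
            f"R^2 = {self.r_squared:.3f}   n = {self.n}"
        )


@dataclass
class AncovaResult:
    """Sequential ANCOVA table plus fit metadata.

    ``table`` has one row per term (df, sum_sq, mean_sq, f_value, p_value) and
    a Residuals row (df, sum_sq, mean_sq).
    """

    table: pd.DataFrame
    n: int
    element: str
    code: str

    def summary(self) -> str:
        out = self.table.copy()
        lines = [f"Sequential ANCOVA — {self.element} {self.code} (n = {self.n})"]
        lines.append(out.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


@dataclass
class CountryAnovaResult:
    """One-way ANOVA of measurement by country, per sex, with pairwise t-tests."""

    anova: pd.DataFrame
    pairwise: pd.DataFrame


def fit_group_regression(years, values) -> RegressionFit:
    """Ordinary least squares of a measurement on calendar year."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(years) == 0:
        raise ValueError("degenerate design: all years equal")
    model = sm.OLS(values, sm.add_constant(years)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(years.size),
    )


def percent_change_over_interval(fit: RegressionFit, y0: float, y1: float) -> float:
    """Predicted percentage decline between two years, relative to the start.

    100 * (prediction(y0) - prediction(y1)) / prediction(y0); positive when
    the trait shrinks over [y0, y1].
    """
    if y1 <= y0:
        raise ValueError("need y1 > y0")
    p0 = float(fit.predict(y0))
    p1 = float(fit.predict(y1))
    if p0 <= 0:
        raise ValueError("prediction at y0 is non-positive")
    return 100.0 * (p0 - p1) / p0


def fit_all_regressions(
    records: pd.DataFrame,
    elements,
    code: str = "GL",
    side_policy: str = "prefer_left",
    group_column: str = "group",
    sex_column: str = "sex_assigned",
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-(group, sex, element) year regressions over dated modern records."""
    df = resolve_paired_elements(records, policy=side_policy)
    df = df[
        (df["measurement_code"] == code)
        & (df["period"] == "modern")
        & df["year"].notna()
        & df["element"].isin(elements)
        & df[sex_column].isin(["F", "M"])
    ]
    rows = []
    for (group, sex, element), sub in df.groupby([group_column, sex_column, "element"], sort=True):
        years = sub["year"].astype(float).to_numpy()
        if len(sub) < min_n or np.ptp(years) == 0:
            continue
        fit = fit_group_regression(years, sub["value_mm"].to_numpy())
        rows.append(
            {
                "population": group,
                "sex": sex,
                "element": element,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)


def _ancova_frame(
    records: pd.DataFrame,
    element: str,
    code: str,
    side_policy: str,
    groups: tuple[str, str],
    group_column: str,
    sex_column: str,
) -> pd.DataFrame:
    df = resolve_paired_elements(records, policy=side_policy)
    df = df[
        (df["measurement_code"] == code)
        & (df["element"] == element)
        & (df["period"] == "modern")
        & df[group_column].isin(groups)
        & df[sex_column].isin(["F", "M"])
        & df["year"].notna()
        & df["value_mm"].notna()
    ]
    return pd.DataFrame(
        {
            "value": df["value_mm"].to_numpy(dtype=float),
            "year": df["year"].to_numpy(dtype=float),
            "sex": pd.Categorical(df[sex_column]),
            "country": pd.Categorical(df[group_column]),
        }
    )


def _term_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    """Treatment-coded design columns for one model term.

    The alphabetically first factor level is the reference; sequential SS and
    F are invariant to that choice (only coefficient signs change).
    """
    year = data["year"].to_numpy(dtype=float)
    dummies = {
        "Sex": pd.get_dummies(data["sex"], drop_first=True, dtype=float).to_numpy(),
        "Country": pd.get_dummies(data["country"], drop_first=True, dtype=float).to_numpy(),
    }
    if term == "Year":
        return year[:, None]
    if term in dummies:
        return dummies[term]
    if term.startswith("Year:"):
        return year[:, None] * dummies[term.split(":", 1)[1]]
    raise KeyError(term)


def sequential_anova(data: pd.DataFrame, terms=ANCOVA_TERMS) -> pd.DataFrame:
    """Type I ANOVA table via nested OLS fits in the given term order.

    Each term's sum of squares is the drop in residual SS when its columns are
    appended to the design; this guarantees the decomposition sums to the
    total corrected SS.  Raises ``ValueError`` naming any term whose columns
    add no rank (aliased term).
    """
    y = data["value"].to_numpy(dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    rank = 1
    prev_rss = float(((y - y.mean()) ** 2).sum())
    rows = []
    for term in terms:
        cols = _term_columns(data, term)
        if cols.shape[1] == 0:
            raise ValueError(f"rank-deficient design: term {term} has a single level")
        X = np.hstack([X, cols])
        new_rank = np.linalg.matrix_rank(X)
        df_term = new_rank - rank
        if df_term < cols.shape[1]:
            raise ValueError(f"rank-deficient design: term {term} is aliased")
        rank = new_rank
        rss = float(sm.OLS(y, X).fit().ssr)
        rows.append({"term": term, "df": float(df_term), "sum_sq": prev_rss - rss})
        prev_rss = rss
    df_resid = n - rank
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    table = pd.DataFrame(rows).set_index("term")
    table["mean_sq"] = table["sum_sq"] / table["df"]
    ms_resid = prev_rss / df_resid
    table["f_value"] = table["mean_sq"] / ms_resid
    table["p_value"] = stats.f.sf(table["f_value"], table["df"], df_resid)
    table.loc["Residuals"] = [float(df_resid), prev_rss, ms_resid, np.nan, np.nan]
    table.index.name = None
    return table


def ancova_sequential(
    records: pd.DataFrame,
    element: str = "humerus",
    code: str = "GL",
    side_policy: str = "prefer_left",
    groups: tuple[str, str] = ("NS", "DK"),
    group_column: str = "group",
    sex_column: str = "sex_assigned",
) -> AncovaResult:
    """Sequential (Type I) ANCOVA of GL on Year, Sex, Country and interactions.

    Complete cases on (year, value) among modern records of the two analysis
    groups, fitted in the fixed order Year, Sex, Country, Year:Sex,
    Year:Country.  Raises ``ValueError`` naming the aliased term if the
    design is rank deficient (e.g. a factor with a single observed level).
    """
    data = _ancova_frame(records, element, code, side_policy, groups, group_column, sex_column)
    n = len(data)
    if n < 7:
        raise ValueError(f"too few complete cases for ANCOVA: n={n}")
    if np.ptp(data["year"].to_numpy()) == 0:
        raise ValueError("rank-deficient design: term Year is constant")
    table = sequential_anova(data, ANCOVA_TERMS)
    return AncovaResult(table=table, n=n, element=element, code=code)


def country_anova(
    records: pd.DataFrame,
    element: str,
    code: str = "GL",
    side_policy: str = "prefer_left",
    sex_column: str = "sex_assigned",
    min_per_group: int = 2,
) -> CountryAnovaResult:
    """One-way ANOVA of measurement by country within each sex.

    Used to decide which modern national populations may be pooled.  Includes
    pooled-variance pairwise t-tests per sex (uncorrected p-values).  A sex
    needs at least two countries with ``min_per_group`` records each; a
    degenerate stratum (zero within-group variance) is reported with NaN F.
    """
    df = resolve_paired_elements(records, policy=side_policy)
    df = df[
        (df["measurement_code"] == code)
        & (df["element"] == element)
        & (df["period"] == "modern")
        & df[sex_column].isin(["F", "M"])
    ]
    anova_rows, pair_rows = [], []
    for sex, sub in df.groupby(sex_column, sort=True):
        by_country = {
            c: g["value_mm"].to_numpy(dtype=float)
            for c, g in sub.groupby("country")
            if len(g) >= min_per_group
        }
        if len(by_country) < 2:
            continue
        samples = list(by_country.values())
        n_tot = sum(len(s) for s in samples)
        dfb, dfw = len(samples) - 1, n_tot - len(samples)
        if all(np.ptp(s) == 0 for s in samples):
            f_val, p_val = np.nan, np.nan
        else:
            f_val, p_val = stats.f_oneway(*samples)
        anova_rows.append(
            {
                "sex": sex,
                "element": element,
                "df_between": dfb,
                "df_within": dfw,
                "f_value": float(f_val),
                "p_value": float(p_val),
            }
        )
        countries = sorted(by_country)
        for i, a in enumerate(countries):
            for b in countries[i + 1:]:
                t, p = stats.ttest_ind(by_country[a], by_country[b], equal_var=True)
                pair_rows.append(
                    {
                        "sex": sex,
                        "element": element,
                        "country_a": a,
                        "country_b": b,
                        "t": float(t),
                        "p_value": float(p),
                    }
                )
    if not anova_rows:
        raise ValueError("need at least 2 countries with enough records in some sex")
    return CountryAnovaResult(anova=pd.DataFrame(anova_rows), pairwise=pd.DataFrame(pair_rows))
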