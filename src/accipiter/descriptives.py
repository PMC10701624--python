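"""Group summaries, normality checks, dimorphism and temporal-shift indices.

Conventions (chosen to reproduce published values):

* the standard error of a cell mean uses the n-1 sample standard deviation,
  so a two-specimen cell has se = (max - min) / 2 exactly;
* the sexual-dimorphism index uses the FEMALE mean as denominator,
  100 * (mean_F - mean_M) / mean_F — goshawk females are the larger sex;
* the Medieval-vs-modern shift uses the MODERN mean as denominator,
  100 * (mean_old - mean_new) / mean_new, so "Medieval females x% larger"
  reads directly.
Both indices are invariant under unit rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import resolve_paired_elements


@dataclass
class GroupSummary:
    """n, observed range, mean and standard error of one measurement cell."""

    n: int
    min_mm: float
    max_mm: float
    mean_mm: float
    se_mm: float | None  # None when n == 1


def summarize_group(values) -> GroupSummary:
    """Summary statistics for one (population, sex, element) cell.

    se is the n-1 sample standard deviation over sqrt(n); for a singleton
    cell it is undefined and reported as None.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty cell")
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
    return GroupSummary(
        n=int(arr.size),
        min_mm=float(arr.min()),
        max_mm=float(arr.max()),
        mean_mm=float(arr.mean()),
        se_mm=se,
    )


def summarize_all(
    records: pd.DataFrame,
    code: str = "GL",
    side_policy: str = "prefer_left",
    group_column: str = "group",
    sex_column: str = "sex_assigned",
) -> pd.DataFrame:
    """One summary row per non-empty (group, period, sex, element) cell.

    Sides are collapsed first so each skeleton counts once per cell.  Cells
    with no specimens are simply absent (there are, for instance, no Medieval
    male tibiotarsi to summarise).
    """
    df = resolve_paired_elements(records, policy=side_policy)
    df = df[df["measurement_code"] == code]
    rows = []
    for (group, period, sex, element), sub in df.groupby(
        [group_column, "period", sex_column, "element"], sort=True
    ):
        s = summarize_group(sub["value_mm"].to_numpy())
        rows.append(
            {
                "population": group,
                "period": period,
                "sex": sex,
                "element": element,
                "code": code,
                "n": s.n,
                "min_mm": s.min_mm,
                "max_mm": s.max_mm,
                "mean_mm": s.mean_mm,
                "se_mm": s.se_mm,
            }
        )
    return pd.DataFrame(rows)


def dimorphism_index(mean_f: float, mean_m: float) -> float:
    """Sexual size dimorphism as a percentage of the female mean.

    Positive when females are larger (the goshawk norm: reversed dimorphism).
    """
    if mean_f <= 0 or mean_m <= 0:
        raise ValueError("means must be positive")
    return 100.0 * (mean_f - mean_m) / mean_f


def temporal_size_shift(mean_old: float, mean_new: float) -> float:
    """Percentage by which an older group's mean exceeds a newer group's.

    Denominator is the newer (modern) mean, so +3 means "the Medieval group
    is 3% larger than the modern one".
    """
    if mean_old <= 0 or mean_new <= 0:
        raise ValueError("means must be positive")
    return 100.0 * (mean_old - mean_new) / mean_new


def dimorphism_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Dimorphism index per (population, period, element) from a summary table.

    Cells missing either sex are skipped.
    """
    rows = []
    for (population, period, element), sub in summaries.groupby(
        ["population", "period", "element"], sort=True
    ):
        by_sex = sub.set_index("sex")["mean_mm"]
        if "F" in by_sex.index and "M" in by_sex.index:
            rows.append(
                {
                    "population": population,
                    "period": period,
                    "element": element,
                    "percent": dimorphism_index(by_sex["F"], by_sex["M"]),
                }
            )
    return pd.DataFrame(rows)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for one cell's values.

    Supported for 3 <= n <= 5000; a constant sample has no defined W and
    raises ValueError.
    """
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro-Wilk supported for 3 <= n <= 5000, got n={arr.size}")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)
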