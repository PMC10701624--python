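"""Published greatest-length (GL) reference statistics for Scandinavian goshawks.

These are the printed group summaries (n, observed range, mean, standard
error, all in mm) and linear trend equations for modern *Accipiter gentilis
gentilis* from Norway + Sweden (NS), Denmark (DK) and Finland (FI), plus the
Norwegian Medieval (MED) stratum.  They serve two purposes:

* desk checks — e.g. verifying that :func:`accipiter.descriptives.summarize_group`
  reproduces a printed n = 2 cell exactly from its two range endpoints;
* anchors for the synthetic generator — per-cell means, noise levels
  (SE x sqrt(n)) and sample-size patterns that make simulated tables
  statistically comparable to the real museum material.

Trend slopes are in mm per calendar year; intercepts are at year 0, so a
prediction for year ``x`` is ``slope * x + intercept``.
"""

from __future__ import annotations

import pandas as pd

ELEMENTS = (
    "humerus",
    "ulna",
    "carpometacarpus",
    "femur",
    "tibiotarsus",
    "tarsometatarsus",
)

MODERN_POPULATIONS = ("NS", "DK", "FI")

# (population, period, sex, element, n, min_mm, max_mm, mean_mm, se_mm)
_GL_ROWS = [
    # humerus
    ("NS", "modern", "M", "humerus", 44, 88.49, 98.67, 93.28, 0.30),
    ("NS", "modern", "F", "humerus", 15, 101.92, 110.83, 105.92, 0.55),
    ("DK", "modern", "M", "humerus", 46, 86.73, 97.28, 91.03, 0.38),
    ("DK", "modern", "F", "humerus", 29, 99.13, 110.98, 104.01, 0.59),
    ("FI", "modern", "M", "humerus", 22, 89.69, 97.84, 93.95, 0.48),
    ("FI", "modern", "F", "humerus", 30, 103.11, 111.41, 106.44, 0.33),
    ("MED", "medieval", "M", "humerus", 2, 90.00, 96.46, 93.23, 3.23),
    ("MED", "medieval", "F", "humerus", 5, 106.10, 111.92, 108.31, 1.05),
    # ulna
    ("NS", "modern", "M", "ulna", 21, 98.60, 109.40, 103.94, 0.51),
    ("NS", "modern", "F", "ulna", 7, 113.50, 121.15, 116.43, 1.03),
    ("DK", "modern", "M", "ulna", 23, 96.48, 106.94, 100.95, 0.58),
    ("DK", "modern", "F", "ulna", 21, 110.66, 121.41, 115.24, 0.73),
    ("FI", "modern", "M", "ulna", 22, 98.97, 108.73, 104.90, 0.51),
    ("FI", "modern", "F", "ulna", 30, 112.61, 121.94, 117.49, 0.38),
    ("MED", "medieval", "M", "ulna", 3, 102.55, 103.05, 102.83, 0.15),
    ("MED", "medieval", "F", "ulna", 4, 117.89, 122.04, 120.23, 0.88),
    # carpometacarpus
    ("NS", "modern", "M", "carpometacarpus", 21, 53.93, 60.97, 57.30, 0.33),
    ("NS", "modern", "F", "carpometacarpus", 8, 62.56, 67.11, 63.92, 0.52),
    ("DK", "modern", "M", "carpometacarpus", 26, 52.81, 58.94, 55.37, 0.31),
    ("DK", "modern", "F", "carpometacarpus", 19, 60.60, 67.21, 63.16, 0.45),
    ("FI", "modern", "M", "carpometacarpus", 22, 55.62, 60.59, 57.83, 0.28),
    ("FI", "modern", "F", "carpometacarpus", 30, 62.22, 67.10, 65.22, 0.23),
    ("MED", "medieval", "M", "carpometacarpus", 2, 56.21, 57.99, 57.10, 0.89),
    ("MED", "medieval", "F", "carpometacarpus", 3, 64.71, 67.48, 65.97, 0.81),
    # femur
    ("NS", "modern", "M", "femur", 57, 73.30, 82.13, 78.40, 0.23),
    ("NS", "modern", "F", "femur", 29, 84.93, 94.78, 89.41, 0.40),
    ("DK", "modern", "M", "femur", 49, 71.88, 82.63, 76.83, 0.36),
    ("DK", "modern", "F", "femur", 40, 83.81, 95.30, 87.91, 0.42),
    ("FI", "modern", "M", "femur", 22, 75.48, 82.35, 78.81, 0.38),
    ("FI", "modern", "F", "femur", 30, 86.31, 92.95, 89.68, 0.30),
    ("MED", "medieval", "M", "femur", 2, 78.27, 78.50, 78.39, 0.12),
    ("MED", "medieval", "F", "femur", 8, 90.60, 94.89, 92.26, 0.49),
    # tibiotarsus (no Medieval males are known)
    ("NS", "modern", "M", "tibiotarsus", 23, 97.48, 107.22, 103.42, 0.46),
    ("NS", "modern", "F", "tibiotarsus", 9, 113.13, 121.22, 116.14, 0.86),
    ("DK", "modern", "M", "tibiotarsus", 25, 96.70, 106.07, 101.31, 0.48),
    ("DK", "modern", "F", "tibiotarsus", 23, 111.63, 122.31, 116.29, 0.62),
    ("FI", "modern", "M", "tibiotarsus", 22, 98.34, 107.41, 103.89, 0.49),
    ("FI", "modern", "F", "tibiotarsus", 30, 113.15, 120.94, 117.69, 0.36),
    ("MED", "medieval", "F", "tibiotarsus", 10, 115.29, 123.28, 119.72, 0.81),
    # tarsometatarsus
    ("NS", "modern", "M", "tarsometatarsus", 21, 71.91, 79.06, 76.48, 0.46),
    ("NS", "modern", "F", "tarsometatarsus", 10, 82.50, 88.34, 84.42, 0.60),
    ("DK", "modern", "M", "tarsometatarsus", 25, 70.37, 79.32, 74.95, 0.43),
    ("DK", "modern", "F", "tarsometatarsus", 21, 81.22, 89.02, 84.57, 0.47),
    ("FI", "modern", "M", "tarsometatarsus", 22, 73.13, 80.37, 77.27, 0.39),
    ("FI", "modern", "F", "tarsometatarsus", 30, 81.63, 89.92, 86.29, 0.31),
    ("MED", "medieval", "M", "tarsometatarsus", 3, 73.08, 79.01, 75.20, 1.91),
    ("MED", "medieval", "F", "tarsometatarsus", 8, 84.43, 89.50, 87.12, 0.57),
]


def gl_summaries() -> pd.DataFrame:
    """Published GL summaries as a DataFrame, one row per non-empty cell."""
    return pd.DataFrame(
        _GL_ROWS,
        columns=[
            "population",
            "period",
            "sex",
            "element",
            "n",
            "min_mm",
            "max_mm",
            "mean_mm",
            "se_mm",
        ],
    )


# Published GL ~ calendar-year regressions for the humerus and femur:
# (population, sex, element) -> (slope mm/yr, intercept mm at year 0, r_squared)
TREND_EQUATIONS = {
    ("NS", "F", "humerus"): (-0.0118, 128.28, 0.029),
    ("DK", "F", "humerus"): (-0.0477, 196.32, 0.398),
    ("NS", "M", "humerus"): (0.0046, 84.378, 0.0048),
    ("DK", "M", "humerus"): (-0.0179, 125.74, 0.0784),
    ("NS", "F", "femur"): (-0.022, 132.29, 0.07),
    ("DK", "F", "femur"): (-0.0385, 162.38, 0.3733),
    ("NS", "M", "femur"): (-0.0005, 79.359, 6e-05),
    ("DK", "M", "femur"): (-0.024, 123.38, 0.1532),
}


def default_slope(population: str, sex: str, element: str) -> float:
    """Default mm/yr trend for a cell.

    Uses the published equation where one exists; other wing/leg elements of
    the same population x sex fall back to the mean of that group's published
    humerus and femur slopes.  Finnish material has no published trend (too
    few pre-2000 specimens) and defaults to zero.
    """
    key = (population, sex, element)
    if key in TREND_EQUATIONS:
        return TREND_EQUATIONS[key][0]
    known = [
        v[0] for (pop, sx, _el), v in TREND_EQUATIONS.items() if pop == population and sx == sex
    ]
    if known:
        return sum(known) / len(known)
    return 0.0
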