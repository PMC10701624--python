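"""Independent oracles and design builders shared across test modules."""

import numpy as np
import pandas as pd

from accipiter.io import make_records


def design_to_records(df):
    """Long-format records from an (group, sex, year, value) design frame."""
    country = {"NS": "NO", "DK": "DK"}
    rows = [
        {
            "specimen_id": f"S{i:03d}",
            "country": country[r.group],
            "period": "modern",
            "element": "humerus",
            "measurement_code": "GL",
            "value_mm": r.value,
            "sex_recorded": r.sex,
            "year": r.year,
        }
        for i, r in enumerate(df.itertuples())
    ]
    records = make_records(rows)
    records["group"] = df["group"].to_numpy()
    return records


def random_design(rng, n=40):
    df = pd.DataFrame(
        {
            "group": rng.choice(["NS", "DK"], n),
            "sex": rng.choice(["F", "M"], n),
            "year": rng.integers(1861, 2016, n).astype(float),
        }
    )
    # guarantee both levels of each factor
    df.loc[0, ["group", "sex"]] = ["NS", "F"]
    df.loc[1, ["group", "sex"]] = ["DK", "M"]
    df["value"] = 90 + rng.normal(0, 3, n) + 5 * (df["sex"] == "F")
    return df


def sequential_ss_oracle(df):
    """Type I SS via explicit nested least-squares fits (no statsmodels).

    Design columns are added one term at a time in the fixed order
    Year, Sex, Country, Year:Sex, Year:Country; each term's SS is the drop in
    residual SS.
    """
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    sex = (df["sex"] == df["sex"].min()).to_numpy(dtype=float)  # dummy coding
    country = (df["group"] == df["group"].min()).to_numpy(dtype=float)
    year = df["year"].to_numpy(dtype=float)
    blocks = [
        ("Year", [year]),
        ("Sex", [sex]),
        ("Country", [country]),
        ("Year:Sex", [year * sex]),
        ("Year:Country", [year * country]),
    ]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    X = np.ones((n, 1))
    prev = rss(X)
    out = {}
    for name, cols in blocks:
        X = np.column_stack([X] + cols)
        cur = rss(X)
        out[name] = prev - cur
        prev = cur
    out["Residuals"] = prev
    return out
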