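"""Read, validate and write long-format osteometric measurement tables.

The canonical container is a pandas DataFrame with one measurement per row
(long format — partial skeletons and multiple measurement codes per element
make wide, per-specimen matrices sparse).  Canonical columns:

========================  =====================================================
specimen_id               opaque string identifying one skeleton
museum_code               accession string, e.g. ``"B 4462"`` (may be empty)
country                   ``NO | SE | DK | FI``
region                    ``south | north | unknown``
period                    ``modern | medieval | viking``
site                      archaeological site name (empty for modern birds)
year                      collection year CE (nullable int; modern only)
sex_recorded              ``F | M | unknown`` — sex on the museum label
sex_assigned              ``F | M | ambiguous`` — analysis sex, set by
                          cohort assembly; defaults to the recorded sex
element                   skeletal element (``humerus`` ... ``other``)
measurement_code          osteometric code (``GL``, ``Bp``, ``KB``, ...)
side                      ``left | right | unknown``
value_mm                  the measurement, millimetres, > 0
========================  =====================================================

Measurement codes follow the standard archaeozoological conventions
(Von den Driesch), with the additional codes KB (smallest depth of the distal
humerus shaft), Tp (depth of the proximal ulna) and HS (height of the
carpometacarpus symphysis) used for goshawk wing elements.

All mm quantities are reported to 2 decimals, the precision of digital
callipers and of the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = [
    "specimen_id",
    "museum_code",
    "country",
    "region",
    "period",
    "site",
    "year",
    "sex_recorded",
    "sex_assigned",
    "element",
    "measurement_code",
    "side",
    "value_mm",
]

MANDATORY_COLUMNS = ["specimen_id", "country", "period", "element", "measurement_code", "value_mm"]

COUNTRIES = frozenset({"NO", "SE", "DK", "FI"})
REGIONS = frozenset({"south", "north", "unknown"})
PERIODS = frozenset({"modern", "medieval", "viking"})
SEX_RECORDED = frozenset({"F", "M", "unknown"})
SEX_ASSIGNED = frozenset({"F", "M", "ambiguous"})
SIDES = frozenset({"left", "right", "unknown"})
ELEMENTS = frozenset(
    {"humerus", "ulna", "carpometacarpus", "femur", "tibiotarsus", "tarsometatarsus", "other"}
)
#: Registry of accepted measurement codes.
MEASUREMENT_CODES = frozenset(
    {"GL", "Bp", "Bd", "Dp", "Dd", "SC", "Did", "KB", "Tp", "HS", "L", "BF"}
)

#: Plausibility windows (mm) per (element, code); a catch-all default applies
#: to combinations not listed.  Deliberately generous — they catch unit errors
#: and typos, not biological outliers.
DEFAULT_PLAUSIBILITY: dict[tuple[str, str], tuple[float, float]] = {
    ("humerus", "GL"): (60.0, 140.0),
    ("ulna", "GL"): (70.0, 160.0),
    ("carpometacarpus", "GL"): (35.0, 95.0),
    ("femur", "GL"): (50.0, 120.0),
    ("tibiotarsus", "GL"): (70.0, 160.0),
    ("tarsometatarsus", "GL"): (45.0, 110.0),
}
_PLAUSIBILITY_FALLBACK = (0.5, 300.0)

_DUPLICATE_KEY = ["specimen_id", "element", "measurement_code", "side"]


class MissingColumnError(ValueError):
    """A mandatory column is absent from the input table."""


@dataclass
class ValidationReport:
    """Outcome of validating a record table.

    ``issues`` holds ``(row label, rule violated)`` pairs; a row with several
    violations appears once per rule.  The valid subset is retrievable via
    :meth:`valid`.
    """

    n_records: int
    n_rejected: int
    issues: list[tuple[Any, str]] = field(default_factory=list)
    valid_index: pd.Index = field(default_factory=lambda: pd.Index([]))

    def valid(self, records: pd.DataFrame) -> pd.DataFrame:
        """Return the subset of ``records`` with no reported issues."""
        return records.loc[records.index.intersection(self.valid_index)]

    def summary(self) -> str:
        lines = [f"records: {self.n_records}  rejected: {self.n_rejected}"]
        for locator, rule in self.issues:
            lines.append(f"  row {locator}: {rule}")
        return "\n".join(lines)


def _normalise(records: pd.DataFrame) -> pd.DataFrame:
    """Fill optional columns with defaults and coerce dtypes."""
    df = records.copy()
    defaults = {
        "museum_code": "",
        "region": "unknown",
        "site": "",
        "sex_recorded": "unknown",
        "side": "unknown",
    }
    for col, default in defaults.items():
        if col not in df.columns:
            df[col] = default
        else:
            df[col] = df[col].fillna(default)
    if "year" not in df.columns:
        df["year"] = pd.array([pd.NA] * len(df), dtype="Int64")
    else:
        df["year"] = pd.array(pd.to_numeric(df["year"], errors="coerce").round(), dtype="Int64")
    if "sex_assigned" not in df.columns:
        df["sex_assigned"] = df["sex_recorded"].map({"F": "F", "M": "M"}).fillna("ambiguous")
    else:
        df["sex_assigned"] = df["sex_assigned"].fillna("ambiguous")
    df["element"] = df["element"].astype(str).str.strip().str.lower()
    for col in ("specimen_id", "museum_code", "country", "region", "period", "site",
                "sex_recorded", "sex_assigned", "measurement_code", "side"):
        df[col] = df[col].astype(str).str.strip()
    df["value_mm"] = pd.to_numeric(df["value_mm"], errors="coerce")
    return df[CANONICAL_COLUMNS]


def read_measurements(
    path, dialect: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, list[tuple[Any, str]]]:
    """Read a long-format measurement CSV.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8, comma separated).
    dialect
        Optional mapping ``{source column name: canonical column name}`` for
        tables whose headers differ from the canonical schema.

    Returns
    -------
    (records, issues)
        ``records`` is a canonical DataFrame; ``issues`` lists
        ``(row label, description)`` for rows that could not be parsed into a
        record (e.g. an unparseable measurement value).  No row is silently
        dropped: every input row is either a record or an issue.

    Raises
    ------
    MissingColumnError
        If a mandatory column is missing after applying the dialect mapping.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if dialect:
        raw = raw.rename(columns=dict(dialect))
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise MissingColumnError(f"mandatory column(s) missing: {', '.join(missing)}")

    issues: list[tuple[Any, str]] = []
    value = pd.to_numeric(raw["value_mm"], errors="coerce")
    for idx in raw.index[value.isna()]:
        cell = raw.at[idx, "value_mm"]
        if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
            issues.append((idx, "missing value_mm"))
        else:
            issues.append((idx, f"unparseable value_mm: {cell!r}"))
    if "year" in raw.columns:
        year_num = pd.to_numeric(raw["year"], errors="coerce")
        bad_year = raw["year"].notna() & (raw["year"].str.strip() != "") & year_num.isna()
        for idx in raw.index[bad_year]:
            issues.append((idx, f"unparseable year: {raw.at[idx, 'year']!r}"))
            raw.at[idx, "year"] = None

    records = _normalise(raw.loc[value.notna()])
    return records, issues


def validate_records(
    records: pd.DataFrame,
    plausibility: Mapping[tuple[str, str], tuple[float, float]] | None = None,
) -> ValidationReport:
    """Check every record against the schema invariants.

    Violations are reported, never raised; the clean subset is available via
    :meth:`ValidationReport.valid`.  Validation is idempotent: validating the
    valid subset yields zero issues.

    Rules enforced
    --------------
    * ``value_mm`` positive and inside the (element, code) plausibility window;
    * enum membership for country, region, period, sexes, element, code, side;
    * medieval/viking records carry no collection year; modern years, when
      present, lie in [1800, 2100];
    * (specimen_id, element, measurement_code, side) unique — later duplicates
      are flagged.
    """
    windows = dict(DEFAULT_PLAUSIBILITY)
    if plausibility:
        windows.update(plausibility)
    df = records
    issues: list[tuple[Any, str]] = []

    def flag(mask: pd.Series, rule: str) -> None:
        for idx in df.index[mask]:
            issues.append((idx, rule))

    flag(df["value_mm"].isna() | (df["value_mm"] <= 0), "non-positive value")
    lo = df.apply(
        lambda r: windows.get((r["element"], r["measurement_code"]), _PLAUSIBILITY_FALLBACK)[0],
        axis=1,
    ) if len(df) else pd.Series(dtype=float)
    hi = df.apply(
        lambda r: windows.get((r["element"], r["measurement_code"]), _PLAUSIBILITY_FALLBACK)[1],
        axis=1,
    ) if len(df) else pd.Series(dtype=float)
    if len(df):
        plaus = df["value_mm"].notna() & (df["value_mm"] > 0) & (
            (df["value_mm"] < lo) | (df["value_mm"] > hi)
        )
        flag(plaus, "value outside plausibility window")

    enum_rules = [
        ("country", COUNTRIES),
        ("region", REGIONS),
        ("period", PERIODS),
        ("sex_recorded", SEX_RECORDED),
        ("sex_assigned", SEX_ASSIGNED),
        ("element", ELEMENTS),
        ("measurement_code", MEASUREMENT_CODES),
        ("side", SIDES),
    ]
    for col, allowed in enum_rules:
        flag(~df[col].isin(allowed), f"invalid {col}")

    non_modern = df["period"].isin({"medieval", "viking"})
    flag(non_modern & df["year"].notna(), "year on non-modern record")
    modern_year = (df["period"] == "modern") & df["year"].notna()
    flag(modern_year & ~df["year"].between(1800, 2100), "year outside [1800, 2100]")

    flag(df.duplicated(subset=_DUPLICATE_KEY, keep="first"),
         "duplicate (specimen, element, code, side)")

    rejected = pd.Index(sorted({idx for idx, _ in issues}, key=list(df.index).index)) \
        if issues else pd.Index([])
    valid_index = df.index.difference(rejected, sort=False)
    return ValidationReport(
        n_records=len(df),
        n_rejected=len(rejected),
        issues=issues,
        valid_index=valid_index,
    )


def write_measurements(records: pd.DataFrame, path) -> None:
    """Write records as canonical CSV; mm values rounded to 2 decimals."""
    out = records[CANONICAL_COLUMNS].copy()
    out["value_mm"] = out["value_mm"].round(2)
    out.to_csv(path, index=False)


def write_summaries(summaries: pd.DataFrame, path) -> None:
    """Write group summaries as CSV with 2-decimal mm columns.

    Expects the output of ``descriptives.summarize_all`` (columns
    population, period, sex, element, n, min_mm, max_mm, mean_mm, se_mm);
    written under the headers (population, period, sex, element, n, min, max,
    mean, se).
    """
    if summaries.empty:
        raise ValueError("no summaries to write")
    out = summaries.copy()
    renames = {"min_mm": "min", "max_mm": "max", "mean_mm": "mean", "se_mm": "se"}
    out = out.rename(columns=renames)
    cols = ["population", "period", "sex", "element", "n", "min", "max", "mean", "se"]
    out = out[[c for c in cols if c in out.columns]]
    for col in ("min", "max", "mean", "se"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce").round(2)
    out.to_csv(path, index=False)


def resolve_paired_elements(
    records: pd.DataFrame, policy: str = "prefer_left"
) -> pd.DataFrame:
    """Collapse left/right duplicates to one value per (specimen, element, code).

    Policies: ``prefer_left`` (left, else right, else unknown-side value),
    ``prefer_right`` (mirror image) and ``mean`` (average all sides).  The
    source material does not state how paired elements were handled; prefer-left
    is the default and the choice only matters for the minority of skeletons
    measured on both sides.
    """
    if policy in ("prefer_left", "prefer_right"):
        order = ["left", "right", "unknown"] if policy == "prefer_left" else [
            "right", "left", "unknown"]
        priority = {side: i for i, side in enumerate(order)}
        df = records.copy()
        df["_prio"] = df["side"].map(priority).fillna(len(order)).astype(int)
        df = df.sort_values("_prio", kind="stable")
        df = df.drop_duplicates(subset=["specimen_id", "element", "measurement_code"],
                                keep="first")
        return df.drop(columns="_prio").sort_index()
    if policy == "mean":
        keys = ["specimen_id", "element", "measurement_code"]
        meta = records.drop(columns=["value_mm", "side"]).drop_duplicates(subset=keys[:1] + keys[1:])
        grouped = records.groupby(keys, as_index=False)["value_mm"].mean()
        merged = grouped.merge(meta.drop_duplicates(subset=keys), on=keys, how="left")
        merged["side"] = "unknown"
        return merged[CANONICAL_COLUMNS]
    raise ValueError(f"unknown side policy: {policy!r}")


def make_records(rows: Iterable[Mapping[str, Any]] | Sequence[Mapping[str, Any]]) -> pd.DataFrame:
    """Build a canonical record table from dicts, filling optional fields.

    Convenience constructor for tests and examples; only ``specimen_id``,
    ``country``, ``period``, ``element``, ``measurement_code`` and
    ``value_mm`` are required per row.
    """
    df = pd.DataFrame(list(rows))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"mandatory column(s) missing: {', '.join(missing)}")
    return _normalise(df)
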