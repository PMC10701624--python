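"""Cohort assembly: subspecies filtering, population grouping, sex reclassification.

Northern Goshawks show reversed sexual size dimorphism with essentially
non-overlapping male and female size ranges, which makes skeletal size a
reliable sex diagnostic.  Museum labels are occasionally wrong (paired ovaries
mistaken for testes at preparation), so the cohort step re-checks every
specimen's recorded sex against per-element size ranges and reassigns it when
the measurements unanimously disagree with the label.

Birds from northern Fennoscandia likely belong to the larger subspecies
*A. g. buteoides*; the nominate-subspecies filter drops northern-region
records so modern comparisons are not inflated by subspecies mixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import resolve_paired_elements

#: Region exclusions applied by default: (country, region) pairs dropped from
#: the modern material.  Northern Norwegian, Swedish and Finnish records are
#: excluded because wintering/resident birds there may represent the larger
#: northern subspecies.
DEFAULT_REGION_EXCLUSIONS = frozenset({("NO", "north"), ("SE", "north"), ("FI", "north")})

#: Modern country -> analysis group.  Norway and Sweden are pooled (one-way
#: ANOVA finds no difference between them); Denmark and Finland stay separate.
DEFAULT_GROUP_MAPPING = {"NO": "NS", "SE": "NS", "DK": "DK", "FI": "FI"}


@dataclass
class FilterResult:
    """Records retained by the nominate-subspecies filter, with the count removed."""

    records: pd.DataFrame
    n_excluded: int


@dataclass
class SexRanges:
    """Observed per-sex size ranges for (element, measurement code) cells.

    ``ranges`` maps ``(element, code, sex)`` to ``(min_mm, max_mm, n)``;
    cells backed by fewer than two reference values are omitted.
    """

    ranges: dict[tuple[str, str, str], tuple[float, float, int]] = field(default_factory=dict)

    def get(self, element: str, code: str, sex: str):
        return self.ranges.get((element, code, sex))

    def vote(self, element: str, code: str, value: float) -> str:
        """Classify one measurement as 'F', 'M' or 'ambiguous'.

        A value votes for a sex when it lies inside that sex's observed range
        and outside the other sex's; anything else (inside both, outside both,
        or a missing range) is ambiguous.
        """
        in_sex = {}
        for sex in ("F", "M"):
            r = self.get(element, code, sex)
            in_sex[sex] = None if r is None else (r[0] <= value <= r[1])
        if in_sex["F"] and not in_sex["M"]:
            return "F"
        if in_sex["M"] and not in_sex["F"]:
            return "M"
        return "ambiguous"


@dataclass
class ReclassificationResult:
    """Per-specimen outcome of the size-based sex check."""

    specimen_id: str
    sex_recorded: str
    sex_assigned: str
    votes: dict[str, str]  # element -> vote
    n_elements_used: int

    @property
    def changed(self) -> bool:
        return self.sex_recorded in ("F", "M") and self.sex_assigned not in (
            self.sex_recorded,
            "ambiguous",
        )


def filter_nominate(
    records: pd.DataFrame,
    region_exclusions: Iterable[tuple[str, str]] | None = None,
) -> FilterResult:
    """Drop modern records from excluded (country, region) combinations.

    Archaeological records are never dropped (the Medieval sites all lie in
    the nominate subspecies' range).
    """
    exclusions = (
        DEFAULT_REGION_EXCLUSIONS if region_exclusions is None else set(region_exclusions)
    )
    key = list(zip(records["country"], records["region"]))
    excluded = pd.Series([k in exclusions for k in key], index=records.index) & (
        records["period"] == "modern"
    )
    return FilterResult(records=records.loc[~excluded].copy(), n_excluded=int(excluded.sum()))


def assign_population_groups(
    records: pd.DataFrame, mapping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Add a ``group`` column: NS / DK / FI for modern records, period label otherwise.

    Medieval and Viking records are grouped by period, not country (the
    archaeological assemblages are pooled strata, e.g. ``MEDIEVAL``).

    Raises ``ValueError`` for a modern country missing from the mapping.
    """
    mapping = DEFAULT_GROUP_MAPPING if mapping is None else dict(mapping)
    df = records.copy()
    modern = df["period"] == "modern"
    unmapped = sorted(set(df.loc[modern, "country"]) - set(mapping))
    if unmapped:
        raise ValueError(f"no group mapping for country: {', '.join(unmapped)}")
    df["group"] = np.where(
        modern,
        df["country"].map(mapping),
        df["period"].str.upper(),
    )
    return df


def compute_sex_ranges(
    reference: pd.DataFrame,
    code: str = "GL",
    min_n: int = 2,
    side_policy: str = "prefer_left",
    sex_column: str = "sex_recorded",
) -> SexRanges:
    """Observed min/max per (element, sex) from a reference record set.

    Sides are collapsed to one value per specimen first, so a skeleton
    measured on both sides contributes once.  Cells with fewer than ``min_n``
    specimens are omitted with a warning.
    """
    df = resolve_paired_elements(reference, policy=side_policy)
    df = df[(df["measurement_code"] == code) & df[sex_column].isin(["F", "M"])]
    out = SexRanges()
    for (element, sex), sub in df.groupby(["element", sex_column]):
        if len(sub) < min_n:
            warnings.warn(
                f"sex range omitted for ({element}, {code}, {sex}): only {len(sub)} value(s)",
                stacklevel=2,
            )
            continue
        vals = sub["value_mm"].to_numpy()
        out.ranges[(element, code, sex)] = (float(vals.min()), float(vals.max()), len(vals))
    return out


class _CellStats:
    """Order statistics of one (element, sex) reference cell.

    Keeps the two smallest and two largest values with their specimen ids so
    a leave-one-out range is an O(1) lookup.
    """

    def __init__(self, pairs: list[tuple[str, float]]):
        ordered = sorted(pairs, key=lambda t: t[1])
        self.n = len(ordered)
        self.lo = ordered[:2]
        self.hi = ordered[-2:]
        self.members = {s for s, _ in ordered}

    def range_excluding(self, specimen: str, min_n: int = 2):
        n = self.n - (1 if specimen in self.members else 0)
        if n < min_n:
            return None
        mn = self.lo[1][1] if self.lo[0][0] == specimen else self.lo[0][1]
        mx = self.hi[-2][1] if self.hi[-1][0] == specimen else self.hi[-1][1]
        return (mn, mx, n)


def _loo_ranges(
    cell_stats: dict[tuple[str, str], _CellStats], specimen: str, code: str
) -> SexRanges:
    """Ranges with the evaluated specimen held out of its own cells."""
    out = SexRanges()
    for (element, sex), stat in cell_stats.items():
        r = stat.range_excluding(specimen)
        if r is not None:
            out.ranges[(element, code, sex)] = r
    return out


def reclassify_sex(
    records: pd.DataFrame,
    ranges: SexRanges | None = None,
    code: str = "GL",
    min_elements: int = 1,
    side_policy: str = "prefer_left",
) -> tuple[pd.DataFrame, list[ReclassificationResult]]:
    """Check each specimen's recorded sex against per-element size ranges.

    Each measured element casts a vote (female range only, male range only, or
    ambiguous).  A specimen is assigned the sex its definite votes unanimously
    support, provided at least ``min_elements`` elements voted; disagreeing or
    absent votes leave it ``ambiguous``.  Reassignments (a definite vote
    against the recorded sex) are flagged via ``ReclassificationResult.changed``.

    When ``ranges`` is None, reference ranges are computed from ``records``
    themselves using recorded sex, leave-one-out per evaluated specimen, and
    the vote/flag cycle is iterated to a fixed point: specimens whose votes
    contradict their recorded sex are removed from the reference set and
    everyone is re-voted, so one mislabeled skeleton can widen neither its own
    recorded-sex range nor anyone else's.

    Returns the records with ``sex_assigned`` updated, plus per-specimen results.
    """
    resolved = resolve_paired_elements(records, policy=side_policy)
    resolved = resolved[resolved["measurement_code"] == code]

    loo = ranges is None
    cell_values: dict[tuple[str, str], list[tuple[str, float]]] = {}
    if loo:
        ref = resolved[resolved["sex_recorded"].isin(["F", "M"])]
        for (element, sex), sub in ref.groupby(["element", "sex_recorded"]):
            cell_values[(element, sex)] = list(zip(sub["specimen_id"], sub["value_mm"]))

    spec_rows: dict[str, tuple[str, list[tuple[str, float]]]] = {}
    for specimen, sub in resolved.groupby("specimen_id", sort=True):
        spec_rows[specimen] = (
            sub["sex_recorded"].iloc[0],
            list(zip(sub["element"], sub["value_mm"])),
        )

    def _vote_all(excluded: set[str]) -> dict[str, tuple[str, dict[str, str], int, str]]:
        if loo:
            cell_stats = {
                cell: _CellStats([(s, v) for s, v in pairs if s not in excluded])
                for cell, pairs in cell_values.items()
            }
        out = {}
        for specimen, (recorded, measured) in spec_rows.items():
            rng = _loo_ranges(cell_stats, specimen, code) if loo else ranges
            votes = {
                element: rng.vote(element, code, value) for element, value in measured
            }
            definite = [v for v in votes.values() if v != "ambiguous"]
            if definite and len(set(definite)) == 1 and len(definite) >= min_elements:
                assigned = definite[0]
            else:
                assigned = "ambiguous"
            out[specimen] = (assigned, votes, len(definite), recorded)
        return out

    flagged: set[str] = set()
    for _ in range(len(resolved["specimen_id"].unique()) + 1):
        voted = _vote_all(flagged)
        new_flagged = {
            s
            for s, (assigned, _v, _n, recorded) in voted.items()
            if recorded in ("F", "M") and assigned in ("F", "M") and assigned != recorded
        }
        if not loo or new_flagged == flagged:
            break
        flagged = new_flagged

    results: list[ReclassificationResult] = []
    assignment: dict[str, str] = {}
    for specimen, (assigned, votes, n_used, recorded) in voted.items():
        results.append(
            ReclassificationResult(
                specimen_id=specimen,
                sex_recorded=recorded,
                sex_assigned=assigned,
                votes=votes,
                n_elements_used=n_used,
            )
        )
        assignment[specimen] = assigned

    out = records.copy()
    mapped = out["specimen_id"].map(assignment)
    out["sex_assigned"] = mapped.where(
        mapped.isin(["F", "M"]),
        out["sex_recorded"].map({"F": "F", "M": "M"}).fillna("ambiguous"),
    )
    return out, results
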