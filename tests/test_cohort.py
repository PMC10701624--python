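"""Cohort assembly: subspecies filter, grouping, sex ranges and reclassification."""

import numpy as np
import pytest

from accipiter.cohort import (
    SexRanges,
    assign_population_groups,
    compute_sex_ranges,
    filter_nominate,
    reclassify_sex,
)
from accipiter.io import make_records

# Observed modern Norway+Sweden humerus greatest-length ranges (mm): the sexes
# do not overlap, which is what makes size-based sex checks possible.
NS_HUMERUS_RANGES = SexRanges(
    ranges={
        ("humerus", "GL", "M"): (88.49, 98.67, 44),
        ("humerus", "GL", "F"): (101.92, 110.83, 15),
    }
)


def _record(specimen, value, sex="M", country="NO", region="south", period="modern",
            element="humerus", **kw):
    return {
        "specimen_id": specimen,
        "country": country,
        "region": region,
        "period": period,
        "element": element,
        "measurement_code": "GL",
        "value_mm": value,
        "sex_recorded": sex,
        **kw,
    }


class TestFilterNominate:
    def test_northern_records_excluded_southern_retained(self):
        records = make_records(
            [
                _record("A", 95.0, country="FI", region="north"),
                _record("B", 95.0, country="NO", region="south"),
                _record("C", 95.0, country="SE", region="north"),
                _record("D", 95.0, country="DK", region="south"),
            ]
        )
        res = filter_nominate(records)
        assert res.n_excluded == 2
        assert sorted(res.records["specimen_id"]) == ["B", "D"]

    def test_injected_count_recovered(self):
        rows = [_record(f"S{i}", 95.0, country="NO") for i in range(90)]
        rows += [_record(f"N{i}", 95.0, country="FI", region="north") for i in range(10)]
        res = filter_nominate(make_records(rows))
        assert len(res.records) == 90
        assert res.n_excluded == 10

    def test_archaeological_records_never_dropped(self):
        records = make_records(
            [_record("A", 95.0, country="NO", region="north", period="medieval", year=None)]
        )
        res = filter_nominate(records)
        assert res.n_excluded == 0


class TestGrouping:
    @pytest.mark.parametrize(
        "country, period, expected",
        [
            ("SE", "modern", "NS"),
            ("NO", "modern", "NS"),
            ("DK", "modern", "DK"),
            ("FI", "modern", "FI"),
            ("NO", "medieval", "MEDIEVAL"),
            ("NO", "viking", "VIKING"),
        ],
    )
    def test_default_mapping(self, country, period, expected):
        records = make_records([_record("A", 95.0, country=country, period=period)])
        out = assign_population_groups(records)
        assert out.at[0, "group"] == expected

    def test_unmapped_modern_country_errors(self):
        records = make_records([_record("A", 95.0, country="SE")])
        with pytest.raises(ValueError, match="SE"):
            assign_population_groups(records, mapping={"NO": "NS"})


class TestSexRanges:
    def test_ranges_equal_brute_force_scan(self, study_table):
        ranges = compute_sex_ranges(study_table, code="GL", sex_column="sex_recorded")
        gl = study_table[
            (study_table["measurement_code"] == "GL")
            & study_table["sex_recorded"].isin(["F", "M"])
        ]
        for (element, code, sex), (lo, hi, n) in ranges.ranges.items():
            vals = gl.loc[
                (gl["element"] == element) & (gl["sex_recorded"] == sex), "value_mm"
            ].to_numpy()
            assert lo == vals.min() and hi == vals.max()
            assert n == len(vals)

    def test_single_sex_input_gives_only_that_sex(self):
        records = make_records([_record(f"S{i}", 104.0 + i, sex="F") for i in range(5)])
        ranges = compute_sex_ranges(records)
        sexes = {sex for (_, _, sex) in ranges.ranges}
        assert sexes == {"F"}

    def test_sparse_cell_omitted_with_warning(self):
        records = make_records(
            [_record("A", 104.0, sex="F"), _record("B", 93.0, sex="M"),
             _record("C", 94.0, sex="M")]
        )
        with pytest.warns(UserWarning, match="sex range omitted"):
            ranges = compute_sex_ranges(records)
        assert ranges.get("humerus", "GL", "F") is None
        assert ranges.get("humerus", "GL", "M") is not None


class TestReclassify:
    def test_male_label_inside_female_range_reassigned(self):
        # mirrors real museum cases: a skeleton recorded male whose humerus GL
        # sits squarely in the female range
        records = make_records([_record("B4462", 104.0, sex="M")])
        out, results = reclassify_sex(records, ranges=NS_HUMERUS_RANGES)
        (r,) = results
        assert r.sex_assigned == "F" and r.changed
        assert out.at[0, "sex_assigned"] == "F"

    def test_value_in_the_gap_is_ambiguous(self):
        records = make_records([_record("X", 100.0, sex="M")])
        out, results = reclassify_sex(records, ranges=NS_HUMERUS_RANGES)
        (r,) = results
        assert r.sex_assigned == "ambiguous"
        assert not r.changed
        assert out.at[0, "sex_assigned"] == "M"  # recorded sex kept when votes abstain

    def test_consistent_female_unchanged(self):
        records = make_records([_record("F1", 105.0, sex="F")])
        _, results = reclassify_sex(records, ranges=NS_HUMERUS_RANGES)
        assert results[0].sex_assigned == "F" and not results[0].changed

    def test_specimen_without_rangeable_measurement_is_ambiguous(self):
        records = make_records([_record("U1", 110.0, sex="M", element="ulna")])
        _, results = reclassify_sex(records, ranges=NS_HUMERUS_RANGES)
        assert results[0].sex_assigned == "ambiguous"
        assert results[0].n_elements_used == 0

    @pytest.fixture()
    def disjoint_population(self):
        """40 skeletons, two elements each, sexes 12% apart with tight noise."""
        rng = np.random.default_rng(7)
        rows = []
        for i in range(20):
            for element, mean in [("humerus", 106.0), ("femur", 89.0)]:
                rows.append(_record(f"F{i}", rng.normal(mean, 1.0), sex="F", element=element))
        for i in range(20):
            for element, mean in [("humerus", 93.0), ("femur", 78.0)]:
                rows.append(_record(f"M{i}", rng.normal(mean, 1.0), sex="M", element=element))
        return make_records(rows)

    def test_injected_label_swaps_recovered_exactly(self, disjoint_population):
        records = disjoint_population.copy()
        swapped = ["F3", "M7", "M15"]
        for sid in swapped:
            mask = records["specimen_id"] == sid
            records.loc[mask, "sex_recorded"] = "M" if sid.startswith("F") else "F"
        _, results = reclassify_sex(records)
        changed = sorted(r.specimen_id for r in results if r.changed)
        assert changed == sorted(swapped)

    def test_reclassification_is_fixed_point(self, disjoint_population):
        records = disjoint_population.copy()
        records.loc[records["specimen_id"] == "F3", "sex_recorded"] = "M"
        out, results = reclassify_sex(records)
        # feed the corrected labels back in: nothing further changes
        out["sex_recorded"] = out["sex_assigned"]
        _, second = reclassify_sex(out)
        assert not any(r.changed for r in second)
        assert {r.specimen_id: r.sex_assigned for r in second} == {
            r.specimen_id: r.sex_assigned for r in results
        }
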