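"""Unit tests for the leaf-indicator calculators on hand-built tables."""

import math

import numpy as np
import pandas as pd
import pytest

from emrqi import EMRDataset, ModelingPlan, ReferenceSchema, compute_indicator
from emrqi.indicators import (
    CALCULATORS,
    derived_value_consistency,
    mapping_ratio,
    normalized_entropy_balance,
    range_conformance_ratio,
    recording_frequency_ratio,
    recording_timeliness,
    temporal_order_compliance,
    value_completeness_ratio,
)

from conftest import make_mini_dataset


def measurements(rows):
    return pd.DataFrame(rows, columns=["admission_id", "element", "value",
                                       "measured_at", "recorded_at", "unit",
                                       "method"])


class TestValueCompleteness:
    def test_40_of_400_missing(self, mini_schema):
        rec = pd.DataFrame({f"c{i}": np.arange(100.0) for i in range(4)})
        for i in range(40):  # 40 distinct cells across the 4 columns
            rec.iloc[i % 100, i % 4] = np.nan
        ds = EMRDataset(records=rec)
        assert value_completeness_ratio(ds, [f"c{i}" for i in range(4)],
                                        mini_schema) == pytest.approx(0.9)

    def test_all_missing(self, mini_schema):
        rec = pd.DataFrame({"a": [None] * 10, "b": [""] * 10})
        ds = EMRDataset(records=rec)
        assert value_completeness_ratio(ds, ["a", "b"], mini_schema) == 0.0

    def test_absent_column_counts_as_all_missing(self, mini_schema):
        rec = pd.DataFrame({"a": np.arange(10.0)})
        ds = EMRDataset(records=rec)
        assert value_completeness_ratio(ds, ["a", "ghost"],
                                        mini_schema) == pytest.approx(0.5)

    def test_sentinel_codes_count_as_missing(self, mini_schema):
        rec = pd.DataFrame({"a": ["1.0", "9999", "2.0", "-1"]})
        ds = EMRDataset(records=rec)
        assert value_completeness_ratio(ds, ["a"],
                                        mini_schema) == pytest.approx(0.5)

    def test_empty_column_set_rejected(self, mini_dataset, mini_schema):
        with pytest.raises(ValueError):
            value_completeness_ratio(mini_dataset, [], mini_schema)


class TestEntropyBalance:
    @pytest.mark.parametrize("values, expected", [
        (["1"] * 50 + ["0"] * 50, 1.0),                  # 50/50
        (["1"] * 30, 0.0),                               # single class
        (["1"] * 90 + ["0"] * 10, 0.469),                # 90/10 -> 0.469 bits
    ])
    def test_binary_distributions(self, values, expected):
        h = normalized_entropy_balance(pd.Series(values))
        assert h == pytest.approx(expected, abs=5e-4)

    def test_all_missing_is_none(self):
        assert normalized_entropy_balance(pd.Series([None, ""])) is None

    def test_uniform_multiclass_is_one(self):
        h = normalized_entropy_balance(pd.Series(list("abc") * 7))
        assert h == pytest.approx(1.0)


class TestRangeConformance:
    def test_all_in_range(self, mini_schema):
        ds = make_mini_dataset()
        assert range_conformance_ratio(ds, mini_schema) == 1.0

    def test_5_of_200_outside(self, mini_schema):
        hr = np.full(200, 80.0)
        hr[:5] = 400.0
        rec = pd.DataFrame({"hr": hr})
        ds = EMRDataset(records=rec)
        assert range_conformance_ratio(ds, mini_schema) == pytest.approx(0.975)

    def test_unparseable_numeric_nonconforming(self, mini_schema):
        rec = pd.DataFrame({"hr": ["80", "junk", "90", "85"]})
        ds = EMRDataset(records=rec)
        assert range_conformance_ratio(ds, mini_schema) == pytest.approx(0.75)

    def test_no_ranges_not_evaluable(self, mini_plan):
        schema = ReferenceSchema.from_config(
            {"elements": {"x": {"dtype": "float"}}})
        ds = EMRDataset(records=pd.DataFrame({"x": [1.0]}))
        score = compute_indicator(ds, schema, mini_plan, "range_conformance",
                                  policy="exclude")
        assert not score.evaluable


class TestTemporalOrder:
    def test_all_within_stay(self, mini_schema):
        ds = make_mini_dataset()
        assert temporal_order_compliance(ds, mini_schema) == 1.0

    def test_3_of_50_measured_before_admission(self, mini_schema):
        ds = make_mini_dataset(n=50)
        rows = [(f"A{i}", "hr", 80.0, "2019-03-02T00:00:00",
                 "2019-03-02T00:30:00", "bpm", "monitor") for i in range(50)]
        for i in range(3):
            rows[i] = (f"A{i}", "hr", 80.0, "2019-02-28T00:00:00",
                       "2019-02-28T00:30:00", "bpm", "monitor")
        ds = make_mini_dataset(n=50, measurements=measurements(rows))
        assert temporal_order_compliance(ds, mini_schema) == pytest.approx(0.94)

    def test_missing_anchors_noncompliant(self, mini_schema):
        ds = make_mini_dataset(n=10, admit_time=[None] * 5
                               + ["2019-03-01T08:00:00"] * 5)
        assert temporal_order_compliance(ds, mini_schema) == pytest.approx(0.5)

    def test_future_discharge_noncompliant(self, mini_schema):
        ds = make_mini_dataset(n=4, discharge_time="2030-01-01T00:00:00")
        assert temporal_order_compliance(ds, mini_schema) == 0.0


class TestRecordingTimeliness:
    def test_instant_logging(self, mini_schema):
        rows = [(f"A{i}", "hr", 80.0, "2019-03-01T10:00:00",
                 "2019-03-01T10:00:00", "bpm", "monitor") for i in range(10)]
        ds = make_mini_dataset(n=10, measurements=measurements(rows))
        assert recording_timeliness(ds, mini_schema) == 1.0

    def test_half_delayed_beyond_window(self, mini_schema):
        rows = []
        for i in range(10):
            recorded = ("2019-03-03T10:00:00" if i < 5  # 48 h > tau = 24 h
                        else "2019-03-01T11:00:00")
            rows.append((f"A{i}", "hr", 80.0, "2019-03-01T10:00:00",
                         recorded, "bpm", "monitor"))
        ds = make_mini_dataset(n=10, measurements=measurements(rows))
        assert recording_timeliness(ds, mini_schema) == pytest.approx(0.5)

    def test_negative_delay_noncompliant(self, mini_schema):
        rows = [("A0", "hr", 80.0, "2019-03-01T10:00:00",
                 "2019-03-01T09:00:00", "bpm", "monitor")]
        ds = make_mini_dataset(n=1, measurements=measurements(rows))
        assert recording_timeliness(ds, mini_schema) == 0.0

    def test_no_measurements_none(self, mini_schema):
        assert recording_timeliness(make_mini_dataset(), mini_schema) is None


class TestRecordingFrequency:
    def make_cadence_dataset(self, hours_between):
        # stay is 72 h; required interval 4 h -> expected 18 measurements
        n_meas = math.ceil(72 / hours_between)
        rows = []
        for k in range(n_meas):
            t = pd.Timestamp("2019-03-01T08:00:00") + pd.Timedelta(
                hours=k * hours_between)
            rows.append(("A0", "hr", 80.0, t.strftime("%Y-%m-%dT%H:%M:%S"),
                         None, "bpm", "monitor"))
        return make_mini_dataset(n=1, measurements=measurements(rows))

    def test_required_cadence_met(self, mini_schema):
        ds = self.make_cadence_dataset(4)
        assert recording_frequency_ratio(ds, mini_schema) == 1.0

    def test_half_cadence(self, mini_schema):
        ds = self.make_cadence_dataset(8)
        assert recording_frequency_ratio(ds, mini_schema) == pytest.approx(0.5)

    def test_matches_bruteforce_recount(self, mini_schema):
        rng = np.random.default_rng(3)
        n = 30
        keep = rng.uniform(0.2, 1.0, n)
        rows = []
        for i in range(n):
            for k in range(18):  # nominal q4h over the 72 h stay
                if rng.uniform() < keep[i]:
                    t = pd.Timestamp("2019-03-01T08:00:00") + pd.Timedelta(
                        hours=k * 4)
                    rows.append((f"A{i}", "hr", 80.0,
                                 t.strftime("%Y-%m-%dT%H:%M:%S"), None,
                                 "bpm", "monitor"))
        ds = make_mini_dataset(n=n, measurements=measurements(rows))
        got = recording_frequency_ratio(ds, mini_schema)
        # independent recount
        counts = ds.measurements.groupby("admission_id").size()
        expected = np.mean([min(1.0, counts.get(f"A{i}", 0) / 18)
                            for i in range(n)])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_length_stay_expects_one(self, mini_schema):
        rows = [("A0", "hr", 80.0, "2019-03-01T08:00:00", None, "bpm", "m")]
        ds = make_mini_dataset(n=1, measurements=measurements(rows),
                               discharge_time="2019-03-01T08:00:00")
        assert recording_frequency_ratio(ds, mini_schema) == 1.0


class TestDerivedConsistency:
    def test_exact_everywhere(self, mini_schema):
        ds = make_mini_dataset(n=100)
        assert derived_value_consistency(ds, mini_schema) == 1.0

    def test_10_of_100_corrupted(self, mini_schema):
        ds = make_mini_dataset(n=100)
        ds.records.loc[:9, "bmi"] += 5.0
        assert derived_value_consistency(ds, mini_schema) == pytest.approx(0.9)

    def test_rows_with_missing_components_excluded(self, mini_schema):
        ds = make_mini_dataset(n=10)
        ds.records.loc[:4, "ht"] = np.nan
        ds.records.loc[5, "bmi"] += 5.0
        assert derived_value_consistency(ds, mini_schema) == pytest.approx(4 / 5)

    def test_no_definitions_none(self, mini_plan):
        schema = ReferenceSchema.from_config({"elements": {"x": {}}})
        ds = EMRDataset(records=pd.DataFrame({"x": [1.0]}))
        assert derived_value_consistency(ds, schema) is None


class TestMappingRatio:
    def test_primary_keys_present(self, mini_dataset, mini_schema):
        assert mapping_ratio(mini_dataset, mini_schema, "primary-key") == (2, 2)

    def test_27_of_30_elements_resolvable(self):
        schema = ReferenceSchema.from_config({"elements": {
            f"e{i}": {"dtype": "float"} for i in range(30)}})
        rec = pd.DataFrame({f"e{i}": [1.0] for i in range(27)})
        ds = EMRDataset(records=rec)
        num, den = mapping_ratio(ds, schema, "element")
        assert num / den == pytest.approx(0.9)

    def test_element_resolution_via_synonym(self, mini_schema):
        ds = make_mini_dataset(hr=None)
        ds.records["heart_rate"] = 80.0
        num, den = mapping_ratio(ds, mini_schema, "element")
        assert num == den  # hr reachable through its synonym

    def test_unit_convertibility_8_of_10(self):
        schema = ReferenceSchema.from_config({
            "elements": {f"lab{i}": {"dtype": "float", "unit": "mg/dL"}
                         for i in range(10)},
            "unit_conversions": {"mg/dL": {"umol/L": 0.0113}},
        })
        rows = []
        for i in range(10):
            unit = "umol/L" if i < 8 else "furlongs"
            rows.append((f"A{i}", f"lab{i}", 1.0, None, None, unit, None))
        rec = pd.DataFrame({f"lab{i}": [1.0] for i in range(10)})
        ds = EMRDataset(records=rec, measurements=measurements(rows))
        num, den = mapping_ratio(ds, schema, "convertibility")
        assert (num, den) == (8, 10)

    def test_unknown_aspect_rejected(self, mini_dataset, mini_schema):
        with pytest.raises(ValueError):
            mapping_ratio(mini_dataset, mini_schema, "bogus")


class TestDispatch:
    def test_unknown_indicator_rejected(self, mini_dataset, mini_schema,
                                        mini_plan):
        with pytest.raises(KeyError):
            compute_indicator(mini_dataset, mini_schema, mini_plan, "nope")

    def test_all_present_element_integrity_full(self, mini_dataset,
                                                mini_schema, mini_plan):
        s = compute_indicator(mini_dataset, mini_schema, mini_plan,
                              "input_element_integrity")
        assert s.raw == 1.0

    def test_two_of_twenty_required_elements_absent(self, mini_plan):
        schema = ReferenceSchema.from_config({"elements": {
            f"e{i}": {"dtype": "float"} for i in range(20)}})
        rec = pd.DataFrame({f"e{i}": [1.0] for i in range(18)})
        ds = EMRDataset(records=rec)
        s = compute_indicator(ds, schema, mini_plan, "element_mapping")
        assert s.raw == pytest.approx(0.9)

    def test_not_evaluable_policies(self, mini_plan):
        schema = ReferenceSchema.from_config({"elements": {"x": {}}})
        ds = EMRDataset(records=pd.DataFrame({"x": [1.0]}))
        one = compute_indicator(ds, schema, mini_plan,
                                "derived_value_consistency", policy="one")
        zero = compute_indicator(ds, schema, mini_plan,
                                 "derived_value_consistency", policy="zero")
        excl = compute_indicator(ds, schema, mini_plan,
                                 "derived_value_consistency", policy="exclude")
        assert (one.raw, zero.raw) == (1.0, 0.0)
        assert not one.evaluable and math.isnan(excl.raw)

    def test_determinism(self, mini_schema, mini_plan):
        a = make_mini_dataset(seed=5)
        b = make_mini_dataset(seed=5)
        for cid in CALCULATORS:
            sa = compute_indicator(a, mini_schema, mini_plan, cid)
            sb = compute_indicator(b, mini_schema, mini_plan, cid)
            assert (sa.raw == sb.raw) or (math.isnan(sa.raw) and math.isnan(sb.raw))


class TestRecordLevelCalculators:
    def test_state_availability(self, mini_schema, mini_plan):
        ds = make_mini_dataset(n=20, state=["voided"] * 3 + ["available"] * 17)
        s = compute_indicator(ds, mini_schema, mini_plan, "state_availability")
        assert s.raw == pytest.approx(0.85)

    def test_state_column_absent_assumed_available(self, mini_schema, mini_plan):
        ds = make_mini_dataset(state=None)
        s = compute_indicator(ds, mini_schema, mini_plan, "state_availability")
        assert s.raw == 1.0 and s.diagnostics

    def test_sample_adequacy_caps_at_one(self, mini_schema, mini_plan):
        small = make_mini_dataset(n=5)
        s = compute_indicator(small, mini_schema, mini_plan, "sample_adequacy")
        assert s.raw == pytest.approx(0.5)  # 5 / required 10
        s = compute_indicator(make_mini_dataset(n=50), mini_schema, mini_plan,
                              "sample_adequacy")
        assert s.raw == 1.0

    def test_format_accuracy(self, mini_schema, mini_plan):
        ds = make_mini_dataset(n=10, icd=["A41"] * 7 + ["bad!"] * 3)
        s = compute_indicator(ds, mini_schema, mini_plan, "format_accuracy")
        assert s.raw == pytest.approx(0.7)

    def test_type_accuracy_counts_unparseable(self, mini_schema, mini_plan):
        ds = make_mini_dataset(n=10, hr=["80"] * 8 + ["eighty", "90x"])
        s = compute_indicator(ds, mini_schema, mini_plan, "type_accuracy")
        assert s.numerator == s.denominator - 2

    def test_granularity_detects_coarsening(self, mini_schema, mini_plan):
        good = make_mini_dataset(n=40)
        s = compute_indicator(good, mini_schema, mini_plan, "granularity")
        assert s.raw == 1.0  # temp carries 1 decimal as required
        coarse = make_mini_dataset(n=40)
        coarse.records["temp"] = coarse.records["temp"].round(0)
        s = compute_indicator(coarse, mini_schema, mini_plan, "granularity")
        assert s.raw == 0.0

    def test_terminology_value_level(self, mini_schema, mini_plan):
        ds = make_mini_dataset(n=20, sex=["M"] * 15 + ["U"] * 5,
                               outcome=[0] * 20)
        s = compute_indicator(ds, mini_schema, mini_plan,
                              "value_terminology_compliance")
        assert s.raw == pytest.approx(35 / 40)  # sex 15/20 + outcome 20/20
        e = compute_indicator(ds, mini_schema, mini_plan,
                              "element_terminology_compliance")
        assert e.raw == pytest.approx(0.5)  # sex violated, outcome clean

    def test_method_tags(self, mini_schema, mini_plan):
        rows = [("A0", "hr", 80.0, None, None, "bpm", "monitor"),
                ("A1", "hr", 82.0, None, None, "bpm", "manual"),
                ("A0", "temp", 37.0, None, None, "C", "oral")]
        ds = make_mini_dataset(n=2, measurements=measurements(rows))
        s = compute_indicator(ds, mini_schema, mini_plan, "method_unambiguity")
        assert s.raw == pytest.approx(0.5)  # hr has two tags, temp one
        c = compute_indicator(ds, mini_schema, mini_plan, "method_consistency")
        assert c.raw == pytest.approx(0.5)

    def test_migration_binary(self, mini_schema, mini_plan):
        ds = make_mini_dataset()
        ds.source_manifest = ds.manifest()
        assert compute_indicator(ds, mini_schema, mini_plan,
                                 "reliable_migration").raw == 1.0
        ds.records.loc[0, "hr"] = np.nan  # working copy drifts from source
        score = compute_indicator(ds, mini_schema, mini_plan,
                                  "reliable_migration")
        assert score.raw == 0.0 and "hr" in score.diagnostics
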