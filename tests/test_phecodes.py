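"""Unit and property tests for phecode consolidation and status assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from equicomorb.phecodes import (
    CASE,
    CONTROL,
    MISSING,
    PhecodeMap,
    SchemaError,
    assign_status,
    compute_demographic_covariates,
    consolidate_phecodes,
)


def events_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "vocabulary", "code", "date"])


class TestConsolidation:
    def test_distinct_dates_counted(self, toy_map):
        ev = events_frame([
            ("a", "ICD9", "295.00", "2010-01-01"),
            ("a", "ICD9", "295.00", "2011-06-30"),
        ])
        counts = consolidate_phecodes(ev, toy_map)
        assert counts.set_index(["patient_id", "phecode"])["count"].to_dict() == {
            ("a", "295.1"): 2
        }

    def test_same_day_codes_collapse_to_one(self, toy_map):
        # two different ICD codes mapping to the same phecode on one date
        ev = events_frame([
            ("a", "ICD9", "295.00", "2010-01-01"),
            ("a", "ICD9", "295.01", "2010-01-01"),
        ])
        counts = consolidate_phecodes(ev, toy_map)
        assert counts["count"].tolist() == [1]

    def test_unmapped_codes_dropped(self, toy_map):
        ev = events_frame([("a", "ICD9", "999.99", "2010-01-01")])
        assert consolidate_phecodes(ev, toy_map).empty

    def test_unknown_vocabulary_rejected(self, toy_map):
        ev = events_frame([("a", "SNOMED", "295.00", "2010-01-01")])
        with pytest.raises(SchemaError, match="vocabulary"):
            consolidate_phecodes(ev, toy_map)

    def test_empty_map_rejected(self):
        with pytest.raises(SchemaError, match="empty"):
            PhecodeMap.from_frame(
                pd.DataFrame(columns=["code", "vocabulary", "phecode"])
            )

    def test_idempotent_on_deduplicated_stream(self, toy_map):
        ev = events_frame([
            ("a", "ICD9", "295.00", "2010-01-01"),
            ("a", "ICD10", "F20", "2010-02-01"),
            ("b", "ICD9", "401.0", "2010-01-01"),
        ])
        first = consolidate_phecodes(ev, toy_map)
        second = consolidate_phecodes(ev, toy_map)
        pd.testing.assert_frame_equal(first, second)

    def test_vocabulary_independence(self, toy_map):
        # "F20" exists only as an ICD-10 entry: tagged ICD9 it must not map
        ev = events_frame([
            ("a", "ICD9", "F20", "2010-01-01"),
            ("b", "ICD10", "F20", "2010-01-01"),
        ])
        counts = consolidate_phecodes(ev, toy_map)
        assert counts["patient_id"].tolist() == ["b"]


class TestStatusAssignment:
    def _status(self, toy_map, counts_rows, patients):
        counts = pd.DataFrame(counts_rows, columns=["patient_id", "phecode", "count"])
        return assign_status(counts, toy_map, patients=patients)

    def test_case_missing_control_rules(self, toy_map):
        status = self._status(
            toy_map,
            [("a", "295.1", 2), ("b", "295.1", 1)],
            patients=["a", "b", "c"],
        )
        col = status.status["295.1"]
        assert col["a"] == CASE
        assert col["b"] == MISSING
        assert col["c"] == CONTROL

    def test_exclusion_range_removes_controls_only(self, toy_map):
        # 401.2 lies in 401.1's exclusion range: carriers of 401.2 cannot be
        # 401.1 controls, but 401.1 cases are never demoted
        status = self._status(
            toy_map,
            [("a", "401.2", 2), ("b", "401.2", 2), ("b", "401.1", 2)],
            patients=["a", "b", "c"],
        )
        col = status.status["401.1"]
        assert col["a"] == MISSING
        assert col["b"] == CASE
        assert col["c"] == CONTROL

    def test_single_instance_exclusion_phecode_still_removes(self, toy_map):
        status = self._status(toy_map, [("a", "401.2", 1)], patients=["a"])
        assert status.status.loc["a", "401.1"] == MISSING

    def test_monotone_in_added_events(self, toy_map):
        ev = events_frame([("a", "ICD9", "295.00", "2010-01-01")])
        more = events_frame([
            ("a", "ICD9", "295.00", "2010-01-01"),
            ("a", "ICD9", "295.00", "2012-01-01"),
        ])
        rank = {CONTROL: 0, MISSING: 1, CASE: 2}
        s1 = assign_status(consolidate_phecodes(ev, toy_map), toy_map, ["a"])
        s2 = assign_status(consolidate_phecodes(more, toy_map), toy_map, ["a"])
        assert rank[s2.status.loc["a", "295.1"]] >= rank[s1.status.loc["a", "295.1"]]

    @given(
        counts=st.lists(
            st.tuples(
                st.integers(0, 5),  # patient index
                st.sampled_from(["295.1", "401.1", "401.2"]),
                st.integers(1, 4),
            ),
            max_size=12,
        )
    )
    def test_partition_property(self, counts):
        """Every (patient, phecode) cell is exactly one of case/control/missing
        and follows the count/exclusion rules."""
        frame = pd.DataFrame(
            [(f"p{i}", ph, c) for i, ph, c in counts],
            columns=["patient_id", "phecode", "count"],
        )
        frame = frame.groupby(["patient_id", "phecode"], as_index=False)["count"].max()
        toy_map = PhecodeMap.from_frame(
            pd.DataFrame(
                [
                    ("295.00", "ICD9", "295.1", ""),
                    ("401.0", "ICD9", "401.1", "401-401.99"),
                    ("401.9", "ICD9", "401.2", ""),
                ],
                columns=["code", "vocabulary", "phecode", "exclude_range"],
            )
        )
        patients = [f"p{i}" for i in range(6)]
        status = assign_status(frame, toy_map, patients=patients)
        lookup = frame.set_index(["patient_id", "phecode"])["count"]
        for patient in patients:
            for phecode in status.phecodes:
                val = status.status.loc[patient, phecode]
                assert val in (CASE, CONTROL, MISSING)
                n = int(lookup.get((patient, phecode), 0))
                if n >= 2:
                    assert val == CASE
                elif n == 1:
                    assert val == MISSING
                elif phecode == "401.1" and int(lookup.get((patient, "401.2"), 0)) >= 1:
                    assert val == MISSING
                else:
                    assert val == CONTROL


class TestCovariates:
    def test_unique_phecode_count_includes_single_instances(self, toy_map):
        counts = pd.DataFrame(
            [("a", "295.1", 2), ("a", "401.1", 1), ("b", "295.1", 1)],
            columns=["patient_id", "phecode", "count"],
        )
        status = assign_status(counts, toy_map, patients=["a", "b", "c"])
        ev = events_frame([
            ("a", "ICD9", "295.00", "2010-01-01"),
            ("a", "ICD9", "295.00", "2010-03-01"),
            ("a", "ICD9", "401.0", "2010-02-01"),
            ("b", "ICD9", "295.00", "2010-01-01"),
        ])
        demo_in = pd.DataFrame(
            {"patient_id": ["a", "b", "c"], "current_age": [50, 60, 40],
             "ehr_age": [49, 58, 40], "sex": ["male", None, "female"],
             "race": ["white", "", "white"]}
        )
        demo = compute_demographic_covariates(ev, demo_in, status)
        assert demo.loc["a", "unique_phecode_count"] == 2
        assert demo.loc["a", "record_length"] == 59
        assert demo.loc["b", "record_length"] == 0
        assert demo.loc["a", "log_unique_phecodes"] == pytest.approx(np.log(3))
        assert demo.loc["b", "log_unique_phecodes"] == pytest.approx(np.log(2))
        # zero-phecode patients sit at ln(1) = 0
        assert demo.loc["c", "log_unique_phecodes"] == 0.0
        assert demo.loc["b", "sex"] == "unknown"
        assert demo.loc["b", "race"] == "unknown"

    def test_ehr_age_cannot_exceed_current_age(self, toy_map):
        counts = pd.DataFrame(
            [("a", "295.1", 2)], columns=["patient_id", "phecode", "count"]
        )
        status = assign_status(counts, toy_map, patients=["a"])
        ev = events_frame([("a", "ICD9", "295.00", "2010-01-01")])
        demo_in = pd.DataFrame(
            {"patient_id": ["a"], "current_age": [50], "ehr_age": [55],
             "sex": ["male"], "race": ["white"]}
        )
        with pytest.raises(SchemaError, match="ehr_age"):
            compute_demographic_covariates(ev, demo_in, status)
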