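"""Event-log construction: parsing, modification merging, filtering, mapping."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from careflow.event_log import (
    ADJUVANT,
    ADVANCED,
    TreatmentRecord,
    build_event_log,
    filter_event_types,
    load_event_log,
    map_treatment_type,
    merge_modifications,
    read_tables,
)
from careflow.exceptions import ValidationError

from conftest import make_log


def d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)


class TestReadTables:
    def test_worked_example_rows(self, table1_paths):
        treatments, responses, patients, issues = read_tables(
            table1_paths["treatments"], table1_paths["responses"],
            table1_paths["patients"],
        )
        assert [r.line for r in treatments] == [1, 2, 2, 3, 3]
        assert [r.modification for r in treatments] == [1, 1, 2, 1, 2]
        assert treatments[0].setting == ADJUVANT
        assert all(r.setting == ADVANCED for r in treatments[1:])
        assert treatments[0].start_date == d("2016-07-01")
        assert treatments[0].stop_date == d("2016-12-15")
        assert responses == [] and len(patients) == 1 and issues == []

    def test_header_only_files_are_empty(self, tmp_path):
        t = tmp_path / "t.csv"
        t.write_text("patient_id,line,modification,treatment,type,start,stop,setting\n")
        r = tmp_path / "r.csv"
        r.write_text("patient_id,line,date,label\n")
        p = tmp_path / "p.csv"
        p.write_text("patient_id,sex,birth_date,death_date,last_followup_date\n")
        treatments, responses, patients, issues = read_tables(t, r, p)
        assert treatments == [] and responses == [] and patients == []
        assert issues == []

    def test_inverted_interval_is_reported(self, tmp_path, table1_paths):
        t = tmp_path / "bad.csv"
        t.write_text(
            "patient_id,line,modification,treatment,type,start,stop,setting\n"
            "9,1,1,X,PD1,15.03.2017,01.01.2017,\n"
        )
        treatments, _, _, issues = read_tables(
            t, table1_paths["responses"], table1_paths["patients"]
        )
        assert treatments == []
        assert [x.rule for x in issues] == ["start_after_stop"]
        with pytest.raises(ValidationError):
            read_tables(t, table1_paths["responses"], table1_paths["patients"],
                        strict=True)

    def test_bad_dates_and_enums_are_reported_with_rows(self, tmp_path, table1_paths):
        r = tmp_path / "r.csv"
        r.write_text(
            "patient_id,line,date,label\n"
            "1234,1,not-a-date,PD\n"
            "1234,1,01.02.2017,XX\n"
        )
        _, responses, _, issues = read_tables(
            table1_paths["treatments"], r, table1_paths["patients"]
        )
        assert responses == []
        assert sorted(x.row for x in issues) == [2, 3]

    def test_iso_dates_accepted(self, tmp_path, table1_paths):
        t = tmp_path / "t.csv"
        t.write_text(
            "patient_id,line,modification,treatment,type,start,stop,setting\n"
            "9,1,1,X,PD1,2017-01-01,2017-06-01,adjuvant\n"
        )
        treatments, _, _, issues = read_tables(
            t, table1_paths["responses"], table1_paths["patients"]
        )
        assert issues == []
        assert treatments[0].start_date == d("2017-01-01")


def rec(pid="1234", line=2, mod=1, ttype="CTLA4+PD1", start="2017-01-01",
        stop="2017-03-01", setting=ADVANCED):
    return TreatmentRecord(pid, line, mod, "drug", ttype, d(start),
                           None if stop is None else d(stop), setting)


class TestMergeModifications:
    def test_worked_example_line2_span_and_label(self, table1_paths):
        treatments, _, _, _ = read_tables(
            table1_paths["treatments"], table1_paths["responses"],
            table1_paths["patients"],
        )
        events, issues = merge_modifications(treatments)
        assert issues == []
        assert len(events) == 3  # three treatment lines for the patient
        by_line = {e.line: e for e in events}
        assert by_line[2].start_date == d("2017-01-01")
        assert by_line[2].stop_date == d("2017-12-31")
        # induction identity: the first modification's type names the line
        assert by_line[2].treatment_type == "CTLA4+PD1"
        assert by_line[1].setting == ADJUVANT

    def test_single_modification_is_identity(self):
        events, issues = merge_modifications([rec()])
        assert issues == []
        e = events[0]
        assert (e.start_date, e.stop_date) == (d("2017-01-01"), d("2017-03-01"))
        assert e.treatment_type == "CTLA4+PD1"

    def test_missing_stop_makes_merged_line_ongoing(self):
        events, _ = merge_modifications(
            [rec(mod=1, stop="2017-03-01"), rec(mod=2, start="2017-03-02", stop=None)]
        )
        assert events[0].stop_date is None

    def test_conflicting_settings_excluded(self):
        events, issues = merge_modifications(
            [rec(mod=1, setting=ADVANCED), rec(mod=2, setting=ADJUVANT)]
        )
        assert events == []
        assert [x.rule for x in issues] == ["conflicting_setting"]

    def test_duplicate_modification_reported(self):
        events, issues = merge_modifications([rec(mod=1), rec(mod=1)])
        assert [x.rule for x in issues] == ["duplicate_modification"]
        assert len(events) == 1

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 1000), st.integers(0, 500)), min_size=1, max_size=6,
    ), st.randoms(use_true_random=False))
    def test_shuffled_modifications_match_bruteforce_minmax(self, intervals, rnd):
        base = d("2015-01-01")
        records = [
            TreatmentRecord("p", 1, m + 1, "drug", "PD1",
                            base + dt.timedelta(days=s),
                            base + dt.timedelta(days=s + span), ADVANCED)
            for m, (s, span) in enumerate(intervals)
        ]
        shuffled = list(records)
        rnd.shuffle(shuffled)
        events, issues = merge_modifications(shuffled)
        assert issues == [] and len(events) == 1
        # brute-force scan over all rows
        assert events[0].start_date == min(r.start_date for r in records)
        assert events[0].stop_date == max(r.stop_date for r in records)
        assert events[0].treatment_type == records[0].treatment_type

    def test_merge_is_idempotent_and_conserves_lines(self):
        rows = [
            rec(line=1, mod=1, start="2016-01-01", stop="2016-02-01"),
            rec(line=1, mod=2, start="2016-02-02", stop="2016-04-01"),
            rec(line=2, mod=1, ttype="PD1", start="2016-06-01", stop="2016-09-01"),
            rec(pid="z", line=1, mod=1, start="2017-01-01", stop="2017-02-01"),
        ]
        events, _ = merge_modifications(rows)
        assert len(events) == len({(r.patient_id, r.line) for r in rows})
        # view merged events as single-modification rows and merge again
        again, _ = merge_modifications(
            [TreatmentRecord(e.patient_id, e.line, 1, "drug", e.treatment_type,
                             e.start_date, e.stop_date, e.setting) for e in events]
        )
        key = lambda e: (e.patient_id, e.line)
        assert sorted(map(repr, sorted(again, key=key))) == sorted(
            map(repr, sorted(events, key=key))
        )


class TestBuildEventLog:
    def test_worked_example_yields_three_ordered_events(self, table1_paths):
        log, issues = load_event_log(
            table1_paths["treatments"], table1_paths["responses"],
            table1_paths["patients"],
        )
        assert issues == []
        assert log.n_patients == 1
        events = log.events["1234"]
        assert [e.line for e in events] == [1, 2, 3]
        assert [e.label for e in events] == [
            ("PD1", ADJUVANT), ("CTLA4+PD1", ADVANCED), ("BRAFi+TT_MEKi", ADVANCED),
        ]

    def test_patient_without_treatments_kept_with_empty_sequence(self):
        events, _ = merge_modifications([rec(pid="a")])
        from careflow.event_log import PatientRecord

        patients = [
            PatientRecord("a", last_followup_date=d("2020-01-01")),
            PatientRecord("b", last_followup_date=d("2020-01-01")),
        ]
        log, issues = build_event_log(events, patients)
        assert log.events["b"] == []
        assert issues == []

    def test_unknown_patient_events_dropped_with_issue(self):
        events, _ = merge_modifications([rec(pid="ghost")])
        log, issues = build_event_log(events, [])
        assert log.n_patients == 0
        assert [x.rule for x in issues] == ["unknown_patient"]

    def test_line_order_inconsistent_with_dates_excludes_patient(self):
        from careflow.event_log import PatientRecord

        bad = [
            rec(pid="a", line=1, start="2018-01-01", stop="2018-02-01"),
            rec(pid="a", line=2, mod=1, start="2017-01-01", stop="2017-02-01"),
        ]
        events, _ = merge_modifications(bad)
        log, issues = build_event_log(
            events, [PatientRecord("a", last_followup_date=d("2020-01-01"))]
        )
        assert log.n_patients == 0
        assert [x.rule for x in issues] == ["line_date_order"]
        assert "a" in issues[0].message

    def test_orphan_and_mismatched_responses_ignored_with_warning(self):
        from careflow.event_log import PatientRecord, ResponseRecord

        events, _ = merge_modifications([rec(pid="a", line=1, setting=ADVANCED)])
        responses = [
            ResponseRecord("a", 5, d("2017-02-01"), "PD"),   # no such line
            ResponseRecord("a", 1, d("2017-02-01"), "RE"),   # adjuvant-only label
            ResponseRecord("a", 1, d("2017-02-01"), "PR"),   # valid
        ]
        log, issues = build_event_log(
            events, [PatientRecord("a", last_followup_date=d("2020-01-01"))],
            responses,
        )
        assert [r.label for r in log.responses["a"]] == ["PR"]
        assert sorted(x.rule for x in issues) == [
            "label_setting_mismatch", "orphan_response",
        ]


class TestFilterAndMap:
    def test_exclude_chemo_drops_only_chemo_events(self):
        log = make_log({"a": ["PD1", "chemo", "BRAFi+MEKi"]})
        out = filter_event_types(log, {"chemo"})
        assert [e.treatment_type for e in out.events["a"]] == ["PD1", "BRAFi+MEKi"]
        # original line indices survive the filter
        assert [e.line for e in out.events["a"]] == [1, 3]

    def test_empty_exclusion_is_identity(self):
        log = make_log({"a": ["PD1", "chemo"]})
        out = filter_event_types(log, set())
        assert out.events == log.events

    def test_patients_never_removed(self):
        log = make_log({"a": ["chemo"], "b": ["PD1"]})
        out = filter_event_types(log, {"chemo"})
        assert out.events["a"] == [] and len(out.events["b"]) == 1

    def test_unknown_token_rejected(self):
        log = make_log({"a": ["PD1"]})
        with pytest.raises(ValidationError):
            filter_event_types(log, {"PD-L1-typo"})

    def test_variant_token_mapping_and_identity(self):
        mapping = {"BRAFi+TT_MEKi": "BRAFi+MEKi"}
        assert map_treatment_type("BRAFi+TT_MEKi", mapping) == "BRAFi+MEKi"
        assert map_treatment_type("PD1", mapping) == "PD1"

    def test_unmapped_foreign_token_passes_through_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="careflow.event_log"):
            assert map_treatment_type("LAG3", {}) == "LAG3"
        assert any("LAG3" in rec.message for rec in caplog.records)

    def test_grouping_map_collapses_vocabulary(self):
        log = make_log({"a": ["PD1", "BRAFi+MEKi"], "b": ["CTLA4+PD1", "BRAFi"]})
        grouped = log.map_types(
            {"PD1": "ICI", "CTLA4+PD1": "ICI", "BRAFi": "TT", "BRAFi+MEKi": "TT"}
        )
        assert grouped.observed_types() == {"ICI", "TT"}
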