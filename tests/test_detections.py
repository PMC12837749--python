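"""Detection parsing, the 30-minute independence rule, and matrix building."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camtrapnet.detections import (
    DetectionEvent,
    DetectionRecord,
    MalformedRowError,
    build_matrix,
    filter_independent,
    read_detections,
    read_events_csv,
    write_events_csv,
)
from camtrapnet.datasets import events_from_community_table, load_community_table

from conftest import rec


class TestReadDetections:
    def test_well_formed_rows_parse_identically(self, make_detections_csv):
        path = make_detections_csv(
            [
                "S001,elephant,2022-06-01 08:30",
                "S001,elephant,2022-06-01 09:15",
                "S002,wild boar,2022-06-02 22:05",
            ]
        )
        records = read_detections(path)
        assert len(records) == 3
        assert records[0] == DetectionRecord("S001", "elephant", datetime(2022, 6, 1, 8, 30))
        assert records[2].species == "wild boar"

    def test_empty_file_with_header(self, make_detections_csv):
        assert read_detections(make_detections_csv([])) == []

    def test_invalid_month_is_a_row_level_error_with_line_number(self, make_detections_csv):
        path = make_detections_csv(
            ["S001,elephant,2022-06-01 08:30", "S001,elephant,2022-13-01 00:00"]
        )
        with pytest.raises(MalformedRowError) as exc:
            read_detections(path)
        assert exc.value.errors[0][0] == 3  # csv line number, header = line 1
        assert read_detections(path, skip_bad=True) == [
            DetectionRecord("S001", "elephant", datetime(2022, 6, 1, 8, 30))
        ]

    def test_missing_column_is_a_configuration_error(self, make_detections_csv):
        path = make_detections_csv(["S001,2022-06-01 08:30"], header="site_id,timestamp")
        with pytest.raises(KeyError, match="species"):
            read_detections(path)


class TestFilterIndependent:
    def test_records_within_window_merge_into_one_event(self):
        records = [
            rec("X", "sambar", "2022-06-01 00:00"),
            rec("X", "sambar", "2022-06-01 00:10"),
            rec("X", "sambar", "2022-06-01 00:40"),
        ]
        events = filter_independent(records)
        assert [(e.event_start.minute, e.n_records) for e in events] == [(0, 2), (40, 1)]

    def test_species_groups_are_independent(self):
        records = [
            rec("X", "sambar", "2022-06-01 00:00"),
            rec("X", "muntjac", "2022-06-01 00:10"),
            rec("X", "sambar", "2022-06-01 00:40"),
        ]
        assert len(filter_independent(records)) == 3

    def test_single_record_is_one_event(self):
        events = filter_independent([rec("X", "sambar", "2022-06-01 00:00")])
        assert len(events) == 1 and events[0].n_records == 1

    def test_exactly_30_minutes_opens_a_new_event(self):
        records = [rec("X", "sambar", "2022-06-01 00:00"), rec("X", "sambar", "2022-06-01 00:30")]
        assert len(filter_independent(records)) == 2

    def test_window_measured_from_event_start_not_last_record(self):
        # 00:00, 00:20, 00:35: third record is 15 min after the second but
        # 35 min after the event start, so it opens a new event
        records = [
            rec("X", "sambar", "2022-06-01 00:00"),
            rec("X", "sambar", "2022-06-01 00:20"),
            rec("X", "sambar", "2022-06-01 00:35"),
        ]
        events = filter_independent(records)
        assert [(e.event_start.minute, e.n_records) for e in events] == [(0, 2), (35, 1)]

    def test_species_matching_folds_case_and_whitespace(self):
        records = [
            rec("X", "Sambar", "2022-06-01 00:00"),
            rec("X", "sambar ", "2022-06-01 00:10"),
        ]
        records[1] = DetectionRecord("X", "sambar", records[1].timestamp)
        events = filter_independent(records)
        assert len(events) == 1 and events[0].n_records == 2


def brute_force_events(records, window_minutes=30):
    """Literal restatement of the rule, for oracle equivalence."""
    out = []
    keys = sorted({(r.site_id, r.species.casefold()) for r in records})
    for key in keys:
        group = sorted(
            (r for r in records if (r.site_id, r.species.casefold()) == key),
            key=lambda r: r.timestamp,
        )
        starts, counts = [], []
        for r in group:
            if not starts or (r.timestamp - starts[-1]) >= timedelta(minutes=window_minutes):
                starts.append(r.timestamp)
                counts.append(1)
            else:
                counts[-1] += 1
        out.extend((key[0], key[1], s, c) for s, c in zip(starts, counts))
    return out


@st.composite
def record_batches(draw):
    n = draw(st.integers(1, 20))
    base = datetime(2022, 6, 1)
    return [
        DetectionRecord(
            draw(st.sampled_from(["A", "B"])),
            draw(st.sampled_from(["sambar", "muntjac"])),
            base + timedelta(minutes=draw(st.integers(0, 300))),
        )
        for _ in range(n)
    ]


class TestFilterProperties:
    @settings(max_examples=100, deadline=None)
    @given(record_batches())
    def test_brute_force_oracle_equivalence(self, records):
        events = filter_independent(records)
        got = [(e.site_id, e.species.casefold(), e.event_start, e.n_records) for e in events]
        assert sorted(got) == sorted(brute_force_events(records))

    @settings(max_examples=50, deadline=None)
    @given(record_batches())
    def test_record_count_conserved(self, records):
        events = filter_independent(records)
        assert sum(e.n_records for e in events) == len(records)

    @settings(max_examples=50, deadline=None)
    @given(record_batches(), st.integers(1, 120), st.integers(1, 120))
    def test_wider_window_never_increases_events(self, records, w1, w2):
        lo, hi = sorted((w1, w2))
        assert len(filter_independent(records, hi)) <= len(filter_independent(records, lo))

    @settings(max_examples=50, deadline=None)
    @given(record_batches())
    def test_idempotent_on_event_starts(self, records):
        events = filter_independent(records)
        starts = [DetectionRecord(e.site_id, e.species, e.event_start) for e in events]
        again = filter_independent(starts)
        assert [(e.site_id, e.species, e.event_start) for e in again] == [
            (e.site_id, e.species, e.event_start) for e in events
        ]


class TestBuildMatrix:
    def test_counts_by_site_and_species(self):
        events = [
            DetectionEvent("X", "A", datetime(2022, 6, 1, 0)),
            DetectionEvent("X", "A", datetime(2022, 6, 1, 5)),
            DetectionEvent("Y", "B", datetime(2022, 6, 1, 2)),
        ]
        m = build_matrix(events)
        assert m.sites == ["X", "Y"] and m.species == ["A", "B"]
        assert m.counts.tolist() == [[2, 0], [0, 1]]
        assert m.presence.tolist() == [[True, False], [False, True]]

    def test_column_sums_equal_event_counts(self, rng):
        events = [
            DetectionEvent(f"S{rng.integers(5)}", f"sp{rng.integers(3)}", datetime(2022, 6, 1) + timedelta(hours=i))
            for i in range(40)
        ]
        m = build_matrix(events)
        assert m.counts.sum() == 40
        for sp in m.species:
            n = sum(1 for e in events if e.species == sp)
            assert m.event_counts()[sp] == n

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no detection events"):
            build_matrix([])

    def test_events_csv_round_trip(self, tmp_path):
        events = [DetectionEvent("X", "A", datetime(2022, 6, 1, 8, 30), 3)]
        write_events_csv(events, tmp_path / "e.csv")
        assert read_events_csv(tmp_path / "e.csv") == events


class TestCommunityTableFixture:
    def test_expanded_events_reproduce_published_occupancy(self):
        table = load_community_table()
        m = build_matrix(events_from_community_table(table, seed=0))
        occ = m.occupancy()
        for row in table.itertuples(index=False):
            assert occ[row.species] == row.occupancy
        assert occ["Rusa unicolor"] == 61
        assert occ["Elephas maximus"] == 50

    def test_expanded_events_reproduce_published_counts(self):
        table = load_community_table()
        m = build_matrix(events_from_community_table(table, seed=1))
        counts = m.event_counts()
        for row in table.itertuples(index=False):
            assert counts[row.species] == row.n_photographs
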