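import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from colonynet.events import (
    ClassRoster,
    FunctionalClass,
    NestTransitEvent,
    ObservationWindow,
    TrophallaxisEvent,
    ValidationError,
    SchemaError,
    classify_ants,
    cross_validate,
    presence_intervals,
    presence_seconds,
    read_event_log,
    write_event_log,
)
from conftest import ev, make_roster

AF = FunctionalClass.ACTIVE_FORAGER
IF = FunctionalClass.INACTIVE_FORAGER
NW = FunctionalClass.NEST_WORKER
Q = FunctionalClass.QUEEN


def _write_csv(path, rows):
    cols = ["colony", "night", "ant_a", "ant_b", "t_start_s", "t_end_s"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


class TestEventLog:
    def test_well_formed_file_parses_with_canonical_dyads(self, tmp_path):
        p = tmp_path / "events.csv"
        _write_csv(
            p,
            [
                ("C1", 1, "B", "A", 0.0, 10.0),
                ("C1", 1, "A", "C", 5.0, 8.0),
                ("C1", 1, "C", "B", 100.0, 130.0),
            ],
        )
        events = read_event_log(p)
        assert len(events) == 3
        assert events[0].dyad == ("A", "B")  # canonicalized
        assert all(e.ant_a <= e.ant_b for e in events)

    @pytest.mark.parametrize(
        "row, fragment",
        [
            (("C1", 1, "A", "B", 10.0, 10.0), "t_end"),
            (("C1", 1, "A", "B", 10.0, 10.5), "threshold"),  # 0.5 s < 1 s rule
            (("C1", 1, "A", "A", 10.0, 20.0), "self"),
            (("C1", 1, "A", "B", 1100.0, 1300.0), "window"),
        ],
    )
    def test_invalid_rows_rejected_with_row_index(self, tmp_path, row, fragment):
        p = tmp_path / "events.csv"
        _write_csv(p, [("C1", 1, "A", "B", 0.0, 10.0), row])
        with pytest.raises(ValidationError) as exc:
            read_event_log(p)
        assert exc.value.problems[0][0] == 1
        assert fragment in exc.value.problems[0][1]
        assert len(read_event_log(p, errors="skip")) == 1

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "events.csv"
        pd.DataFrame({"colony": ["C1"], "night": [1]}).to_csv(p, index=False)
        with pytest.raises(SchemaError):
            read_event_log(p)

    def test_round_trip_reproduces_events_exactly(self, tmp_path, small_colony):
        p = tmp_path / "events.csv"
        write_event_log(small_colony.events, p)
        assert read_event_log(p) == small_colony.events


class TestClassification:
    BASE = [("C1", "Q1", True)] + [("C1", f"W{i}", False) for i in range(1, 11)]

    def test_forager_history_controls_class_sequence(self):
        transits = [
            NestTransitEvent("C1", 3, "W1", 100.0, "exit"),
            NestTransitEvent("C1", 3, "W1", 400.0, "enter"),
        ]
        roster = classify_ants(transits, self.BASE, nights=[1, 2, 3, 4, 5])
        assert [roster.get("C1", n, "W1") for n in range(1, 6)] == [
            NW, NW, AF, IF, IF,
        ]

    def test_never_transiting_ants_stay_nest_workers(self):
        roster = classify_ants([], self.BASE, nights=[1, 2])
        for n in (1, 2):
            assert roster.members("C1", n, NW) == sorted(
                f"W{i}" for i in range(1, 11)
            )
            assert roster.members("C1", n, Q) == ["Q1"]

    def test_queen_transit_is_a_hard_error(self):
        transits = [NestTransitEvent("C1", 1, "Q1", 50.0, "exit")]
        with pytest.raises(ValidationError, match="queen"):
            classify_ants(transits, self.BASE, nights=[1])

    def test_classification_is_permutation_invariant(self):
        transits = [
            NestTransitEvent("C1", 2, "W2", 100.0, "exit"),
            NestTransitEvent("C1", 1, "W1", 300.0, "exit"),
            NestTransitEvent("C1", 1, "W1", 100.0, "exit"),
            NestTransitEvent("C1", 1, "W1", 200.0, "enter"),
        ]
        # W1 night 1 has exit/enter/exit -> must be sorted before validation
        a = classify_ants(transits, self.BASE, nights=[1, 2])
        b = classify_ants(list(reversed(transits)), self.BASE, nights=[1, 2])
        assert a.assignments == b.assignments

    @given(
        night_sets=hst.lists(
            hst.sets(hst.integers(min_value=1, max_value=6)), min_size=1, max_size=4
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_roster_monotonicity_property(self, night_sets):
        """Class sequences always match nest_worker* then forager classes."""
        base = [("C1", "Q1", True)] + [
            ("C1", f"W{i}", False) for i in range(len(night_sets))
        ]
        transits = []
        for i, nights_out in enumerate(night_sets):
            for n in sorted(nights_out):
                transits.append(NestTransitEvent("C1", n, f"W{i}", 10.0, "exit"))
                transits.append(NestTransitEvent("C1", n, f"W{i}", 20.0, "enter"))
        roster = classify_ants(transits, base, nights=list(range(1, 7)))
        for i in range(len(night_sets)):
            seq = [roster.get("C1", n, f"W{i}") for n in range(1, 7)]
            seen_forager = False
            for cls in seq:
                if cls in (AF, IF):
                    seen_forager = True
                else:
                    assert cls is NW and not seen_forager


class TestPresence:
    def test_no_transits_means_full_window(self, window):
        presence = presence_intervals([], window, ants=["A"])
        assert presence["A"] == [(0.0, 1200.0)]

    def test_exit_then_enter_splits_the_window(self, window):
        transits = [
            NestTransitEvent("C1", 1, "A", 300.0, "exit"),
            NestTransitEvent("C1", 1, "A", 900.0, "enter"),
        ]
        presence = presence_intervals(transits, window)
        assert presence["A"] == [(0.0, 300.0), (900.0, 1200.0)]
        assert presence_seconds(presence["A"]) == 600.0

    def test_first_enter_implies_outside_from_zero(self, window):
        transits = [NestTransitEvent("C1", 1, "A", 100.0, "enter")]
        assert presence_intervals(transits, window)["A"] == [(100.0, 1200.0)]

    def test_same_direction_transits_rejected(self, window):
        transits = [
            NestTransitEvent("C1", 1, "A", 100.0, "exit"),
            NestTransitEvent("C1", 1, "A", 200.0, "exit"),
        ]
        with pytest.raises(ValidationError, match="consecutive"):
            presence_intervals(transits, window)

    def test_in_plus_out_time_equals_window(self, window, small_colony):
        for night in (1, 2, 3):
            w = ObservationWindow("C1", night, 1200.0)
            presence = presence_intervals(
                small_colony.transits, w, small_colony.roster.classes_for("C1", night)
            )
            for ant, intervals in presence.items():
                total = presence_seconds(intervals)
                assert 0.0 <= total <= 1200.0


class TestCrossValidate:
    def test_event_during_absence_is_flagged(self, window):
        presence = {"A": [(300.0, 1200.0)], "B": [(0.0, 1200.0)]}
        report = cross_validate([ev("A", "B", 200.0, 250.0)], presence, window)
        assert len(report) == 1
        assert report[0]["ant"] == "A"
        assert report[0]["outside_overlap_s"] == pytest.approx(50.0)

    def test_consistent_logs_produce_empty_report(self, window):
        presence = {"A": [(0.0, 1200.0)], "B": [(0.0, 1200.0)]}
        assert cross_validate([ev("A", "B", 10.0, 60.0)], presence, window) == []

    def test_event_straddling_an_exit_reports_overlap_length(self, window):
        presence = {"A": [(0.0, 500.0)], "B": [(0.0, 1200.0)]}
        report = cross_validate([ev("A", "B", 450.0, 550.0)], presence, window)
        assert report[0]["outside_overlap_s"] == pytest.approx(50.0)
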