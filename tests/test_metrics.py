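"""Sessionization, per-app durations, windowed summaries, trigger labels."""

import pytest

from phonelog.events import EventStream, EventType, UsageEvent
from phonelog.metrics import (
    NonAlternatingScreenEvents,
    Session,
    TriggerParams,
    app_foreground_intervals,
    classify_triggers,
    per_app_durations,
    sessionize,
    usage_summary,
)

H = 3_600_000
D = 86_400_000


def ev(t, etype=EventType.SCREEN_ON, app=None):
    return UsageEvent(t, etype, app)


class TestSessionize:
    def test_single_pair_duration(self):
        s = sessionize(EventStream([ev(1_000), ev(61_000, EventType.SCREEN_OFF)]))
        assert len(s) == 1 and s[0].duration_ms == 60_000

    def test_empty_stream_gives_empty_list(self):
        assert sessionize(EventStream([])) == []

    def test_non_alternating_input_directs_to_repair(self):
        with pytest.raises(NonAlternatingScreenEvents, match="repair_sessions"):
            sessionize(EventStream([ev(1), ev(2)]))

    def test_matches_ground_truth_exactly(self, sim30):
        _, stream, truth = sim30
        sessions = sessionize(stream)
        assert [(s.start_ms, s.end_ms) for s in sessions] == [
            (s.start_ms, s.end_ms) for s in truth.true_sessions
        ]


class TestPerAppDurations:
    def test_forced_arithmetic(self):
        s = EventStream(
            [
                ev(0, EventType.SCREEN_ON),
                ev(0, EventType.APP_FOREGROUND, "A"),
                ev(10_000, EventType.APP_FOREGROUND, "B"),
                ev(25_000, EventType.SCREEN_OFF),
            ]
        )
        assert per_app_durations(s) == {"A": 10_000, "B": 15_000}

    def test_no_app_events_empty_map(self):
        s = EventStream([ev(0), ev(1000, EventType.SCREEN_OFF)])
        assert per_app_durations(s) == {}

    def test_matches_ground_truth_totals(self, sim30):
        _, stream, truth = sim30
        expected: dict[str, int] = {}
        for iv in truth.true_app_intervals:
            expected[iv.app_id] = expected.get(iv.app_id, 0) + iv.end_ms - iv.start_ms
        assert per_app_durations(stream) == expected

    def test_idle_episodes_excludable(self):
        from phonelog.clean import IdleEpisode

        s = EventStream(
            [
                ev(0, EventType.APP_FOREGROUND, "clock"),
                ev(7 * H, EventType.APP_BACKGROUND, "clock"),
            ]
        )
        assert per_app_durations(s) == {"clock": 7 * H}
        assert per_app_durations(s, exclude=[IdleEpisode("clock", 0, 7 * H)]) == {}

    def test_conservation_within_sessions(self, sim30):
        """Per-app durations within any session sum to the session
        duration: simulated foreground coverage is gapless."""
        _, stream, truth = sim30
        sessions = sessionize(stream)
        intervals = app_foreground_intervals(stream)
        i = 0
        for s in sessions:
            total = 0
            while i < len(intervals) and intervals[i].start_ms < s.end_ms:
                total += intervals[i].end_ms - intervals[i].start_ms
                i += 1
            assert total == s.duration_ms


class TestUsageSummary:
    def test_midnight_straddling_session_splits(self):
        s = [Session(D - 30 * 60_000, D + 30 * 60_000)]
        summary = usage_summary(s, granularity="day")
        assert [(r.total_use_ms, r.pickup_count) for r in summary.records] == [
            (30 * 60_000, 1),
            (30 * 60_000, 0),
        ]

    def test_no_sessions_all_zero(self):
        assert usage_summary([], granularity="day").records == []

    def test_hour_day_week_totals_agree(self, sim30):
        _, stream, _ = sim30
        sessions = sessionize(stream)
        expected = sum(s.duration_ms for s in sessions)
        for g in ("hour", "day", "week"):
            assert usage_summary(sessions, granularity=g).total_use_ms == expected

    def test_daily_total_bounded_by_day_length(self, sim30):
        _, stream, _ = sim30
        summary = usage_summary(sessionize(stream), granularity="day")
        assert all(r.total_use_ms <= D for r in summary.records)

    def test_pickups_equal_screen_on_count(self, sim30):
        _, stream, _ = sim30
        summary = usage_summary(sessionize(stream), granularity="day")
        assert sum(r.pickup_count for r in summary.records) == len(
            stream.of_type(EventType.SCREEN_ON)
        )

    def test_weeks_start_monday(self, sim30):
        import datetime as dt

        _, stream, _ = sim30
        summary = usage_summary(sessionize(stream), granularity="week")
        for r in summary.records:
            day = dt.datetime.fromtimestamp(r.window_start_ms / 1000, dt.timezone.utc)
            assert day.weekday() == 0 and day.hour == 0

    def test_timezone_offset_shifts_day_boundary(self):
        s = [Session(D - 30 * 60_000, D + 30 * 60_000)]
        # at UTC+1 the whole session falls in the later local day
        summary = usage_summary(s, granularity="day", tz_offset_hours=1.0)
        assert len(summary.records) == 1
        assert summary.records[0].total_use_ms == 60 * 60_000

    def test_per_app_windowing(self):
        from phonelog.simulate import AppInterval

        ivs = [AppInterval("a", D - 10_000, D + 20_000)]
        summary = usage_summary([], app_intervals=ivs, granularity="day")
        assert summary.per_app == {0: {"a": 10_000}, D: {"a": 20_000}}

    def test_unknown_granularity_rejected(self):
        with pytest.raises(ValueError, match="granularity"):
            usage_summary([], granularity="fortnight")


class TestClassifyTriggers:
    def _stream(self, notif_t, notif_app, first_app):
        return EventStream(
            [
                UsageEvent(notif_t, EventType.NOTIFICATION_POSTED, notif_app),
                ev(100_000, EventType.SCREEN_ON),
                ev(100_000, EventType.APP_FOREGROUND, first_app),
                ev(160_000, EventType.SCREEN_OFF),
            ]
        )

    def test_recent_notification_from_first_app_wins(self):
        s = classify_triggers(
            [Session(100_000, 160_000)], self._stream(95_000, "x", "x")
        )
        assert s[0].trigger == "notification" and s[0].trigger_app == "x"

    def test_stale_notification_means_self(self):
        s = classify_triggers(
            [Session(100_000, 160_000)], self._stream(40_000, "x", "x")
        )
        assert s[0].trigger == "self"

    def test_other_apps_notification_means_self(self):
        s = classify_triggers(
            [Session(100_000, 160_000)], self._stream(95_000, "y", "x")
        )
        assert s[0].trigger == "self"

    def test_no_notifications_leaves_unknown(self):
        stream = EventStream([ev(1), ev(2, EventType.SCREEN_OFF)])
        s = classify_triggers([Session(1, 2)], stream)
        assert s[0].trigger == "unknown"

    def test_accuracy_against_ground_truth(self, sim30):
        """Label accuracy >= 95% at defaults; errors only from slow
        responses or coincidental notifications."""
        _, stream, truth = sim30
        sessions = classify_triggers(sessionize(stream), stream, TriggerParams())
        agree = sum(
            1
            for s, t in zip(sessions, truth.true_sessions)
            if s.trigger == t.trigger
        )
        assert agree / len(sessions) >= 0.95
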