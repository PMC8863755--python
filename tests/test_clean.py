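"""Cleaning rules: double counts, idle episodes, session repair."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phonelog.clean import (
    CleaningParams,
    dedupe,
    flag_idle,
    repair_sessions,
)
from phonelog.events import EventStream, EventType, UsageEvent

H = 3_600_000


def ev(t, etype=EventType.SCREEN_ON, app=None):
    return UsageEvent(t, etype, app)


class TestDedupe:
    def test_pair_within_window_collapses(self):
        out, removed = dedupe(EventStream([ev(1000), ev(1003)]))
        assert [e.timestamp_ms for e in out] == [1000] and removed == 1

    def test_pair_outside_window_kept(self):
        out, removed = dedupe(EventStream([ev(1000), ev(6000)]))
        assert len(out) == 2 and removed == 0

    def test_distinct_types_never_compared(self):
        out, removed = dedupe(
            EventStream([ev(1000), ev(1001, EventType.SCREEN_OFF)])
        )
        assert len(out) == 2 and removed == 0

    def test_distinct_apps_never_compared(self):
        out, removed = dedupe(
            EventStream(
                [
                    ev(1000, EventType.APP_FOREGROUND, "a"),
                    ev(1001, EventType.APP_FOREGROUND, "b"),
                ]
            )
        )
        assert len(out) == 2 and removed == 0

    def test_transitive_run_collapses_to_first(self):
        out, removed = dedupe(
            EventStream([ev(1000), ev(1090), ev(1180), ev(1270)])
        )
        assert [e.timestamp_ms for e in out] == [1000] and removed == 3

    def test_removed_count_is_the_difference(self, sim60_dirty):
        _, dirty, _ = sim60_dirty
        out, removed = dedupe(dirty)
        assert removed == len(dirty) - len(out)

    def test_removes_exactly_injected_duplicates(self, sim60_dirty):
        """On a stream with injected double counts, dedupe recovers the
        pre-artifact stream plus the (non-duplicate) clock episodes."""
        clean, dirty, truth = sim60_dirty
        out, removed = dedupe(dirty)
        assert removed == len(truth.injected_duplicates)
        assert len(out) == len(clean) + 2 * len(truth.injected_clock_nights)

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=60))
    def test_idempotent(self, times):
        stream = EventStream([ev(t) for t in sorted(times)])
        once, _ = dedupe(stream)
        twice, removed = dedupe(once)
        assert removed == 0 and twice.events == once.events


class TestFlagIdle:
    def test_overnight_clock_app_flagged_once(self):
        s = EventStream(
            [
                ev(0, EventType.APP_FOREGROUND, "clock"),
                ev(7 * H, EventType.APP_BACKGROUND, "clock"),
            ]
        )
        flags = flag_idle(s)
        assert len(flags) == 1
        assert flags[0].app_id == "clock" and flags[0].duration_ms == 7 * H

    def test_short_episodes_not_flagged(self, sim30):
        _, stream, _ = sim30
        assert flag_idle(stream) == []

    def test_flags_match_injected_clock_nights(self, sim60_dirty):
        _, dirty, truth = sim60_dirty
        deduped, _ = dedupe(dirty)
        flags = flag_idle(deduped)
        assert [(f.start_ms, f.end_ms) for f in flags] == truth.injected_clock_nights

    def test_threshold_is_configurable(self):
        s = EventStream(
            [
                ev(0, EventType.APP_FOREGROUND, "a"),
                ev(2 * H, EventType.SCREEN_OFF),
            ]
        )
        assert flag_idle(s) == []
        assert len(flag_idle(s, CleaningParams(idle_threshold_ms=H))) == 1


class TestRepairSessions:
    def test_unclosed_on_closed_at_shutdown(self):
        s = EventStream(
            [
                ev(1000),
                ev(2000, EventType.DEVICE_SHUTDOWN),
                ev(3000, EventType.DEVICE_BOOT),
                ev(4000),
                ev(5000, EventType.SCREEN_OFF),
            ]
        )
        out, repairs = repair_sessions(s)
        screen = [(e.timestamp_ms, e.type) for e in out
                  if e.type in (EventType.SCREEN_ON, EventType.SCREEN_OFF)]
        assert screen == [
            (1000, EventType.SCREEN_ON),
            (2000, EventType.SCREEN_OFF),
            (4000, EventType.SCREEN_ON),
            (5000, EventType.SCREEN_OFF),
        ]
        assert len(repairs) == 1 and repairs[0].action == "closed_at_shutdown"

    def test_drop_policy_drops_orphan_on(self):
        s = EventStream([ev(1000), ev(4000), ev(5000, EventType.SCREEN_OFF)])
        out, repairs = repair_sessions(
            s, CleaningParams(repair_policy="drop_unmatched")
        )
        ons = out.of_type(EventType.SCREEN_ON)
        assert len(ons) == 1 and ons[0].timestamp_ms == 4000
        assert repairs[0].action == "dropped_on"

    def test_paired_stream_needs_no_repair(self, sim30):
        _, stream, _ = sim30
        out, repairs = repair_sessions(stream)
        assert repairs == [] and out.events == stream.events

    def test_screen_events_alternate_after_repair(self, sim60_dirty):
        _, dirty, _ = sim60_dirty
        deduped, _ = dedupe(dirty)
        out, _ = repair_sessions(deduped)
        state = 0
        for e in out:
            if e.type is EventType.SCREEN_ON:
                assert state == 0
                state = 1
            elif e.type is EventType.SCREEN_OFF:
                assert state == 1
                state = 0
        assert state == 0

    def test_dropout_window_repairs_match_truncated_sessions(self):
        """Deleting a dropout window orphans exactly the sessions whose
        OFF (or ON) fell inside it; repair accounts for each."""
        from phonelog.simulate import (
            ArtifactParams,
            BehaviorParams,
            inject_artifacts,
            simulate_usage_log,
        )

        params = BehaviorParams(n_days=7, seed=5)
        stream, truth = simulate_usage_log(params)
        lo = params.start_ms + 2 * 86_400_000 + 12 * H
        hi = lo + 6 * H
        dirty = inject_artifacts(
            stream, truth, ArtifactParams(dropout_windows=((lo, hi),))
        )
        out, repairs = repair_sessions(dirty, CleaningParams(repair_policy="drop_unmatched"))

        def inside(t):
            return lo <= t < hi

        orphaned = [
            s for s in truth.true_sessions
            if inside(s.start_ms) != inside(s.end_ms)
        ]
        assert len(repairs) == len(orphaned)
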