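"""Usage metrics: sessions, per-app durations, windowed summaries, triggers.

The elementary quantity is the *session*: the half-open interval
[screen-on, screen-off) whose length is the duration of one episode of
device use, and whose count per day is the pickup rate. Comparing the
screen-event timestamps gives total screen time; doing the same between
consecutive app-foreground events apportions it across apps; bucketing
either by hour, day (local midnight) or week (Monday start) yields the
descriptive summaries studies actually report. Finally, each session is
classified as *notification-driven* — a notification from the session's
first app landed within ``tau_ms`` before pickup — or *self-initiated*,
the distinction between usage that interrupts and usage that is sought.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .events import EventStream, EventType
from .simulate import AppInterval

__all__ = [
    "Session",
    "TriggerParams",
    "UsageSummary",
    "WindowRecord",
    "NonAlternatingScreenEvents",
    "sessionize",
    "per_app_durations",
    "app_foreground_intervals",
    "usage_summary",
    "classify_triggers",
]

MS_PER_HOUR = 3_600_000
MS_PER_DAY = 86_400_000
MS_PER_WEEK = 7 * MS_PER_DAY

_WINDOW_MS = {"hour": MS_PER_HOUR, "day": MS_PER_DAY, "week": MS_PER_WEEK}


class NonAlternatingScreenEvents(ValueError):
    """Screen events do not strictly alternate; repair the stream first."""


@dataclass(frozen=True)
class Session:
    """One screen-on→screen-off episode; interval is half-open [start, end)."""

    start_ms: int
    end_ms: int
    trigger: str = "unknown"  # "notification" | "self" | "unknown"
    trigger_app: str | None = None

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("session end must follow its start")

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class TriggerParams:
    """``tau_ms``: how stale a notification may be and still explain a pickup."""

    tau_ms: int = 30_000

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be positive")


@dataclass(frozen=True)
class WindowRecord:
    window_start_ms: int
    total_use_ms: int
    pickup_count: int


@dataclass
class UsageSummary:
    """Windowed totals, pickup counts, and per-app durations."""

    granularity: str
    tz_offset_hours: float
    records: list[WindowRecord] = field(default_factory=list)
    per_app: dict[int, dict[str, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                (r.window_start_ms, r.total_use_ms, r.pickup_count)
                for r in self.records
            ],
            columns=["window_start_ms", "total_use_ms", "pickup_count"],
        )
        df["window_start"] = pd.to_datetime(df["window_start_ms"], unit="ms", utc=True)
        return df

    def per_app_frame(self) -> pd.DataFrame:
        rows = [
            (w, app, ms)
            for w, apps in sorted(self.per_app.items())
            for app, ms in sorted(apps.items())
        ]
        return pd.DataFrame(rows, columns=["window_start_ms", "app", "duration_ms"])

    @property
    def total_use_ms(self) -> int:
        return sum(r.total_use_ms for r in self.records)


def sessionize(stream: EventStream) -> list[Session]:
    """Pair screen events into sessions.

    Requires a cleaned, repaired stream in which SCREEN_ON and SCREEN_OFF
    strictly alternate; raises :class:`NonAlternatingScreenEvents`
    otherwise, pointing at the repair step. Sessions that straddle an
    aggregation window are split later, at aggregation time, not here.
    """
    sessions: list[Session] = []
    pending_on: int | None = None
    for ev in stream.events:
        if ev.type is EventType.SCREEN_ON:
            if pending_on is not None:
                raise NonAlternatingScreenEvents(
                    f"SCREEN_ON at {ev.timestamp_ms} follows an unclosed SCREEN_ON "
                    f"at {pending_on}; run repair_sessions first"
                )
            pending_on = ev.timestamp_ms
        elif ev.type is EventType.SCREEN_OFF:
            if pending_on is None:
                raise NonAlternatingScreenEvents(
                    f"SCREEN_OFF at {ev.timestamp_ms} without a preceding "
                    "SCREEN_ON; run repair_sessions first"
                )
            sessions.append(Session(pending_on, ev.timestamp_ms))
            pending_on = None
    if pending_on is not None:
        raise NonAlternatingScreenEvents(
            f"unclosed SCREEN_ON at {pending_on}; run repair_sessions first"
        )
    return sessions


def app_foreground_intervals(
    stream: EventStream, span: tuple[int, int] | None = None
) -> list[AppInterval]:
    """Per-app foreground intervals.

    Each APP_FOREGROUND opens an interval that closes at the next
    APP_FOREGROUND (any app), an APP_BACKGROUND of the same app, a
    SCREEN_OFF/DEVICE_SHUTDOWN, or the span end. Intervals are clipped
    to ``span`` when given.
    """
    intervals: list[AppInterval] = []
    open_app: str | None = None
    open_t = 0

    def close(at: int) -> None:
        nonlocal open_app
        if open_app is not None and at > open_t:
            intervals.append(AppInterval(open_app, open_t, at))
        open_app = None

    for ev in stream.events:
        if ev.type is EventType.APP_FOREGROUND:
            close(ev.timestamp_ms)
            open_app, open_t = ev.app_id, ev.timestamp_ms
        elif ev.type is EventType.APP_BACKGROUND and ev.app_id == open_app:
            close(ev.timestamp_ms)
        elif ev.type in (EventType.SCREEN_OFF, EventType.DEVICE_SHUTDOWN):
            close(ev.timestamp_ms)
    if open_app is not None:
        end = span[1] if span else (stream.end_ms or open_t)
        close(end)

    if span is not None:
        lo, hi = span
        intervals = [
            AppInterval(iv.app_id, max(iv.start_ms, lo), min(iv.end_ms, hi))
            for iv in intervals
            if iv.end_ms > lo and iv.start_ms < hi
        ]
    return intervals


def per_app_durations(
    stream: EventStream,
    span: tuple[int, int] | None = None,
    exclude: Iterable = (),
) -> dict[str, int]:
    """Total foreground milliseconds per app.

    Durations come from differences between consecutive events, summed
    independently per app. Episodes in ``exclude`` (e.g. idle flags from
    the cleaning stage) are subtracted where they overlap.
    """
    excl = [(e.app_id, e.start_ms, e.end_ms) for e in exclude]
    totals: dict[str, int] = {}
    for iv in app_foreground_intervals(stream, span):
        dur = iv.end_ms - iv.start_ms
        for app, lo, hi in excl:
            if app == iv.app_id:
                overlap = min(hi, iv.end_ms) - max(lo, iv.start_ms)
                if overlap > 0:
                    dur -= overlap
        if dur > 0:
            totals[iv.app_id] = totals.get(iv.app_id, 0) + dur
    return totals


def _window_start(t_ms: int, granularity: str, tz_offset_ms: int) -> int:
    local = t_ms + tz_offset_ms
    return (local // _WINDOW_MS[granularity]) * _WINDOW_MS[granularity] - tz_offset_ms


def usage_summary(
    sessions: list[Session],
    app_intervals: Iterable[AppInterval] | None = None,
    granularity: str = "day",
    tz_offset_hours: float = 0.0,
) -> UsageSummary:
    """Bucket sessions (and optionally app intervals) into local windows.

    Sessions straddling a boundary contribute duration to every window
    they touch, but count as a *pickup* only in the window containing
    their start. Days begin at local midnight; weeks begin Monday local
    time (the epoch is aligned so week boundaries fall on Mondays).
    """
    if granularity not in _WINDOW_MS:
        raise ValueError(f"granularity must be one of {sorted(_WINDOW_MS)}")
    tz_ms = int(tz_offset_hours * MS_PER_HOUR)
    # Unix epoch (1970-01-01) is a Thursday; add 3 days so that the weekly
    # floor lands on Mondays (1970-01-05 was the first epoch Monday).
    if granularity == "week":
        tz_ms += 3 * MS_PER_DAY
    w_ms = _WINDOW_MS[granularity]

    totals: dict[int, int] = {}
    pickups: dict[int, int] = {}
    for s in sessions:
        w = _window_start(s.start_ms, granularity, tz_ms)
        pickups[w] = pickups.get(w, 0) + 1
        pos = s.start_ms
        while pos < s.end_ms:
            w = _window_start(pos, granularity, tz_ms)
            w_end = w + w_ms
            chunk = min(s.end_ms, w_end) - pos
            totals[w] = totals.get(w, 0) + chunk
            pos += chunk

    per_app: dict[int, dict[str, int]] = {}
    for iv in app_intervals or ():
        pos = iv.start_ms
        while pos < iv.end_ms:
            w = _window_start(pos, granularity, tz_ms)
            w_end = w + w_ms
            chunk = min(iv.end_ms, w_end) - pos
            per_app.setdefault(w, {})
            per_app[w][iv.app_id] = per_app[w].get(iv.app_id, 0) + chunk
            pos += chunk

    keys = sorted(set(totals) | set(pickups))
    records = [
        WindowRecord(w, totals.get(w, 0), pickups.get(w, 0)) for w in keys
    ]
    return UsageSummary(granularity, tz_offset_hours, records, per_app)


def classify_triggers(
    sessions: list[Session],
    stream: EventStream,
    params: TriggerParams | None = None,
) -> list[Session]:
    """Label each session notification-driven or self-initiated.

    A session is ``notification`` iff some NOTIFICATION_POSTED fell in
    ``(start − tau_ms, start]`` *and* the session's first foreground app
    is the notifying app; otherwise ``self``. With no notification
    events in the stream at all, labels stay ``unknown`` — the tracking
    switch for notifications may simply have been off.
    """
    params = params or TriggerParams()
    notifs = [
        (e.timestamp_ms, e.app_id)
        for e in stream.events
        if e.type is EventType.NOTIFICATION_POSTED
    ]
    if not notifs:
        return [replace(s, trigger="unknown", trigger_app=None) for s in sessions]

    fgs = [
        (e.timestamp_ms, e.app_id)
        for e in stream.events
        if e.type is EventType.APP_FOREGROUND
    ]

    import bisect

    notif_times = [t for t, _ in notifs]
    fg_times = [t for t, _ in fgs]

    out: list[Session] = []
    for s in sessions:
        i = bisect.bisect_left(fg_times, s.start_ms)
        first_app = fgs[i][1] if i < len(fgs) and fgs[i][0] < s.end_ms else None
        label, t_app = "self", None
        if first_app is not None:
            lo = bisect.bisect_right(notif_times, s.start_ms - params.tau_ms)
            hi = bisect.bisect_right(notif_times, s.start_ms)
            for t, app in notifs[lo:hi]:
                if app == first_app:
                    label, t_app = "notification", app
                    break
        out.append(replace(s, trigger=label, trigger_app=t_app))
    return out
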