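"""Cleaning rules applied to raw exports before any metric is computed.

Three defects occur in practice and each gets a rule:

* **Double counts.** Retrospective OS extractions sometimes log the same
  interaction twice within a few milliseconds. When consecutive rows
  share type and app and sit within ``epsilon_ms`` of each other, the
  repeat is certainly a double count and only the earliest survives.
* **Idle episodes.** A single app foregrounded for multiple hours — the
  classic case is a clock app left on while charging — reflects a device
  left on, not active use. Such episodes are *flagged*, not deleted, so
  the analyst decides their fate.
* **Unpaired screen-ons.** A screen-on with no matching screen-off (a
  crash, a shutdown, a logging dropout) is either closed at the next
  device shutdown/boot or dropped, by policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .events import EventStream, EventType, UsageEvent

__all__ = [
    "CleaningParams",
    "IdleEpisode",
    "SessionRepair",
    "dedupe",
    "flag_idle",
    "repair_sessions",
    "foreground_episodes",
]

MS_PER_HOUR = 3_600_000


@dataclass(frozen=True)
class CleaningParams:
    """Tunable thresholds; defaults are deliberately generous.

    ``epsilon_ms`` bounds the double-count window ("a few milliseconds",
    widened to 100 ms to absorb OS scheduling jitter); ``idle_threshold_ms``
    is the longest plausible genuinely-active single-app stretch (3 h).
    """

    epsilon_ms: int = 100
    idle_threshold_ms: int = 3 * MS_PER_HOUR
    repair_policy: str = "close_at_shutdown"  # or "drop_unmatched"

    def __post_init__(self) -> None:
        if self.epsilon_ms <= 0 or self.idle_threshold_ms <= 0:
            raise ValueError("thresholds must be positive")
        if self.repair_policy not in ("close_at_shutdown", "drop_unmatched"):
            raise ValueError(f"unknown repair_policy {self.repair_policy!r}")


@dataclass(frozen=True)
class IdleEpisode:
    app_id: str
    start_ms: int
    end_ms: int

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class SessionRepair:
    action: str  # "closed_at_shutdown" | "dropped_on" | "dropped_off"
    timestamp_ms: int
    closed_at_ms: int | None = None


def dedupe(
    stream: EventStream, params: CleaningParams | None = None
) -> tuple[EventStream, int]:
    """Collapse double-count runs; returns ``(cleaned, removed_count)``.

    Runs are found within each ``(type, app_id)`` subsequence — a screen
    event and its double count stay a pair even when an app event of the
    same millisecond is interleaved between them. Successive events of
    one subsequence whose gaps are each within ``epsilon_ms`` form a run
    and only the run's first member survives (transitive). Events of
    distinct type or app are never compared, and the operation is
    idempotent.
    """
    params = params or CleaningParams()
    kept: list[UsageEvent] = []
    removed = 0
    # per-(type, app): timestamp of the most recent member of the open run
    last_ts: dict[tuple, int] = {}
    for ev in stream.events:
        key = (ev.type, ev.app_id)
        prev = last_ts.get(key)
        if prev is not None and ev.timestamp_ms - prev <= params.epsilon_ms:
            removed += 1
            last_ts[key] = ev.timestamp_ms  # transitive within the run
            continue
        kept.append(ev)
        last_ts[key] = ev.timestamp_ms
    return EventStream(kept, source=stream.source), removed


def foreground_episodes(stream: EventStream) -> list[IdleEpisode]:
    """Maximal single-app foreground intervals.

    An APP_FOREGROUND opens an interval; the next APP_FOREGROUND (any
    app), an APP_BACKGROUND of the same app, or a SCREEN_OFF closes it.
    Consecutive intervals of the same app merge into one episode.
    """
    raw: list[IdleEpisode] = []
    open_app: str | None = None
    open_t = 0
    for ev in stream.events:
        if ev.type is EventType.APP_FOREGROUND:
            if open_app is not None:
                raw.append(IdleEpisode(open_app, open_t, ev.timestamp_ms))
            open_app, open_t = ev.app_id, ev.timestamp_ms
        elif ev.type is EventType.APP_BACKGROUND and ev.app_id == open_app:
            raw.append(IdleEpisode(open_app, open_t, ev.timestamp_ms))
            open_app = None
        elif ev.type in (EventType.SCREEN_OFF, EventType.DEVICE_SHUTDOWN):
            if open_app is not None:
                raw.append(IdleEpisode(open_app, open_t, ev.timestamp_ms))
                open_app = None
    merged: list[IdleEpisode] = []
    for ep in raw:
        if merged and merged[-1].app_id == ep.app_id and merged[-1].end_ms == ep.start_ms:
            merged[-1] = IdleEpisode(ep.app_id, merged[-1].start_ms, ep.end_ms)
        else:
            merged.append(ep)
    return merged


def flag_idle(
    stream: EventStream, params: CleaningParams | None = None
) -> list[IdleEpisode]:
    """Flag (never delete) single-app foreground episodes longer than the
    idle threshold. Durations must be derivable first, so the stream
    should already be deduped."""
    params = params or CleaningParams()
    return [
        ep
        for ep in foreground_episodes(stream)
        if ep.duration_ms > params.idle_threshold_ms
    ]


def repair_sessions(
    stream: EventStream, params: CleaningParams | None = None
) -> tuple[EventStream, list[SessionRepair]]:
    """Make SCREEN_ON/SCREEN_OFF strictly alternate.

    A SCREEN_ON with no SCREEN_OFF before the next SCREEN_ON is closed at
    the intervening DEVICE_SHUTDOWN (restarts always bound a session) when
    one exists and policy is ``close_at_shutdown``, else the orphan ON is
    dropped. Orphan SCREEN_OFFs (an OFF with no preceding ON) are dropped.
    A trailing unclosed ON at end of stream is treated the same way.
    Non-screen events pass through untouched.
    """
    params = params or CleaningParams()
    out: list[UsageEvent] = []
    repairs: list[SessionRepair] = []
    pending_on: UsageEvent | None = None
    pending_shutdown: UsageEvent | None = None
    pending_tail: list[UsageEvent] = []  # events after pending ON, awaiting resolution

    def resolve(drop_always: bool = False) -> None:
        nonlocal pending_on, pending_shutdown
        if pending_on is None:
            return
        if (
            not drop_always
            and params.repair_policy == "close_at_shutdown"
            and pending_shutdown is not None
        ):
            out.append(pending_on)
            out.append(
                UsageEvent(
                    pending_shutdown.timestamp_ms,
                    EventType.SCREEN_OFF,
                    source=pending_on.source,
                )
            )
            repairs.append(
                SessionRepair(
                    "closed_at_shutdown",
                    pending_on.timestamp_ms,
                    pending_shutdown.timestamp_ms,
                )
            )
        else:
            repairs.append(SessionRepair("dropped_on", pending_on.timestamp_ms))
        pending_on = None
        pending_shutdown = None

    for ev in stream.events:
        if ev.type is EventType.SCREEN_ON:
            if pending_on is not None:
                # previous ON never closed
                tail = pending_tail[:]
                pending_tail.clear()
                resolve()
                out.extend(tail)
            pending_on = ev
            pending_shutdown = None
        elif ev.type is EventType.SCREEN_OFF:
            if pending_on is None:
                repairs.append(SessionRepair("dropped_off", ev.timestamp_ms))
                continue
            out.append(pending_on)
            out.extend(pending_tail)
            pending_tail.clear()
            out.append(ev)
            pending_on = None
            pending_shutdown = None
        else:
            if ev.type is EventType.DEVICE_SHUTDOWN and pending_on is not None:
                if pending_shutdown is None:
                    pending_shutdown = ev
            if pending_on is not None:
                pending_tail.append(ev)
            else:
                out.append(ev)

    tail = pending_tail[:]
    pending_tail.clear()
    resolve()
    out.extend(tail)
    out.sort(key=UsageEvent.sort_key)
    return EventStream(out, source=stream.source), repairs
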