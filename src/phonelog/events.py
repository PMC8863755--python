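"""Event taxonomy and stream containers for smartphone usage logs.

A usage logger records one row per device interaction: a UNIX-millisecond
timestamp, an event type, and (for app-level events) the reverse-domain
package identifier of the app involved. Two export kinds carry these rows:
the *continuous* log (prospective capture after install) and the *past
usage* log (the retrospective history the operating system maintains).
This module defines the closed event taxonomy, the validated stream
container, and the merge of the two sources into one timeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

__all__ = [
    "EventType",
    "UsageEvent",
    "EventStream",
    "ContextSnapshot",
    "ContextEntry",
    "RowRejection",
    "MergePolicy",
    "APP_EVENT_TYPES",
    "validate_stream",
    "filter_event_types",
    "merge_sources",
]


class EventType(Enum):
    """Closed enumeration of loggable device interactions."""

    SCREEN_ON = "SCREEN_ON"
    SCREEN_OFF = "SCREEN_OFF"
    APP_FOREGROUND = "APP_FOREGROUND"
    APP_BACKGROUND = "APP_BACKGROUND"
    USER_INTERACTION = "USER_INTERACTION"
    APP_INSTALLED = "APP_INSTALLED"
    APP_UNINSTALLED = "APP_UNINSTALLED"
    NOTIFICATION_POSTED = "NOTIFICATION_POSTED"
    NOTIFICATION_REMOVED = "NOTIFICATION_REMOVED"
    DEVICE_BOOT = "DEVICE_BOOT"
    DEVICE_SHUTDOWN = "DEVICE_SHUTDOWN"
    CONFIG_CHANGE = "CONFIG_CHANGE"
    FLUSH_TO_DISK = "FLUSH_TO_DISK"


#: Event types that must carry an app identifier.
APP_EVENT_TYPES = frozenset(
    {
        EventType.APP_FOREGROUND,
        EventType.APP_BACKGROUND,
        EventType.APP_INSTALLED,
        EventType.APP_UNINSTALLED,
        EventType.NOTIFICATION_POSTED,
        EventType.NOTIFICATION_REMOVED,
    }
)

_TYPE_ORDER = {t: i for i, t in enumerate(EventType)}
_SOURCE_ORDER = {"continuous": 0, "past": 1}


@dataclass(frozen=True)
class UsageEvent:
    """One timestamped device interaction.

    Parameters
    ----------
    timestamp_ms : int
        UNIX epoch milliseconds; must be positive.
    type : EventType
        The interaction kind.
    app_id : str or None
        Reverse-domain package identifier; required for app-level events
        (foreground/background, install/uninstall, notifications) and
        absent otherwise.
    source : str
        Which export the row came from: ``"continuous"`` or ``"past"``.
    """

    timestamp_ms: int
    type: EventType
    app_id: str | None = None
    source: str = "continuous"

    def sort_key(self) -> tuple:
        # Stable tie-break: continuous before past, then enum order.
        return (
            self.timestamp_ms,
            _SOURCE_ORDER.get(self.source, 2),
            _TYPE_ORDER[self.type],
        )


@dataclass(frozen=True)
class RowRejection:
    """A malformed row dropped during validation, with the reason."""

    index: int
    reason: str
    raw: object = None


@dataclass
class EventStream:
    """Ordered sequence of :class:`UsageEvent` from one (or a merged) source."""

    events: list[UsageEvent] = field(default_factory=list)
    source: str = "continuous"

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[UsageEvent]:
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventStream)
            and self.events == other.events
            and self.source == other.source
        )

    @property
    def start_ms(self) -> int | None:
        return self.events[0].timestamp_ms if self.events else None

    @property
    def end_ms(self) -> int | None:
        return self.events[-1].timestamp_ms if self.events else None

    def of_type(self, *types: EventType) -> list[UsageEvent]:
        keep = set(types)
        return [e for e in self.events if e.type in keep]


@dataclass(frozen=True)
class ContextEntry:
    app_id: str
    permissions_requested: tuple[str, ...]
    permissions_granted: tuple[str, ...]


@dataclass
class ContextSnapshot:
    """One-time inventory of installed apps and their permission state.

    Per entry, granted permissions are a subset of requested ones and
    app identifiers are unique across entries.
    """

    captured_at_ms: int
    entries: list[ContextEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.app_id in seen:
                raise ValueError(f"duplicate app_id in context snapshot: {e.app_id}")
            seen.add(e.app_id)
            if not set(e.permissions_granted) <= set(e.permissions_requested):
                raise ValueError(
                    f"granted permissions not a subset of requested for {e.app_id}"
                )


def validate_stream(
    stream: EventStream | Iterable[UsageEvent],
) -> tuple[EventStream, list[RowRejection]]:
    """Sort a stream by timestamp and reject malformed rows.

    Sorting is stable for timestamp ties (continuous source first, then
    event-type declaration order). Rows are rejected — with a reason —
    when the timestamp is not a positive integer, or when the app_id
    presence contract is violated (app-level events need one, others must
    not carry one). An empty input yields an empty stream, not an error.

    Idempotent: validating a validated stream returns it unchanged.
    """
    if isinstance(stream, EventStream):
        events: Sequence = stream.events
        source = stream.source
    else:
        events = list(stream)
        source = "continuous"

    kept: list[UsageEvent] = []
    rejections: list[RowRejection] = []
    for i, ev in enumerate(events):
        if not isinstance(ev, UsageEvent):
            rejections.append(RowRejection(i, "not a UsageEvent", ev))
            continue
        if not isinstance(ev.timestamp_ms, int) or isinstance(ev.timestamp_ms, bool):
            rejections.append(RowRejection(i, "non-integer timestamp", ev))
            continue
        if ev.timestamp_ms <= 0:
            rejections.append(RowRejection(i, "non-positive timestamp", ev))
            continue
        if ev.type in APP_EVENT_TYPES and not ev.app_id:
            rejections.append(RowRejection(i, "missing app_id", ev))
            continue
        if ev.type not in APP_EVENT_TYPES and ev.app_id:
            kept.append(replace(ev, app_id=None))
            warnings.warn(
                f"row {i}: app_id dropped from {ev.type.name} event", stacklevel=2
            )
            continue
        kept.append(ev)
    kept.sort(key=UsageEvent.sort_key)
    return EventStream(kept, source=source), rejections


def filter_event_types(stream: EventStream, keep: set[EventType]) -> EventStream:
    """Keep only events whose type is in ``keep``; order is preserved.

    The choice of relevant event types is study-specific — a screen-time
    analysis keeps screen events, an app-usage analysis keeps foreground
    transitions — so this is the first processing step after export.
    """
    if not keep:
        raise ValueError("keep must be a non-empty set of EventType")
    return EventStream(
        [e for e in stream.events if e.type in keep], source=stream.source
    )


@dataclass(frozen=True)
class MergePolicy:
    """How continuous and past exports are reconciled.

    Both exports come from the same device clock, so drift is assumed
    zero; ``window_ms`` absorbs OS-scheduling jitter between the two
    recording paths.
    """

    window_ms: int = 1000


def merge_sources(
    continuous: EventStream,
    past: EventStream,
    policy: MergePolicy | None = None,
) -> EventStream:
    """Merge continuous and past-usage exports into one timeline.

    Past usage is the retrospective history the OS keeps; it overlaps the
    continuously logged window and extends before it. Within the overlap
    the continuous record wins: each past event with a same-type, same-app
    continuous counterpart within ``policy.window_ms`` is treated as a
    duplicate observation of the same interaction and dropped (one-to-one,
    order-preserving matching). Past events with no counterpart — before
    logging started, or inside a logging dropout — fill the gaps. Source
    provenance is retained on every kept event.

    Contradictory adjacent states across sources (two SCREEN_ON with no
    intervening SCREEN_OFF further apart than the window) are kept, with
    a warning.
    """
    policy = policy or MergePolicy()

    # One-to-one greedy matching per (type, app): both sides time-sorted,
    # advance two pointers, pair when within the window.
    from collections import defaultdict

    cont_by_key: dict[tuple, list[UsageEvent]] = defaultdict(list)
    for e in continuous.events:
        cont_by_key[(e.type, e.app_id)].append(e)

    past_kept: list[UsageEvent] = []
    past_by_key: dict[tuple, list[UsageEvent]] = defaultdict(list)
    for e in past.events:
        past_by_key[(e.type, e.app_id)].append(e)

    for key, past_list in past_by_key.items():
        cont_list = cont_by_key.get(key, [])
        j = 0
        for pe in past_list:
            # advance past continuous events too early to match
            while (
                j < len(cont_list)
                and cont_list[j].timestamp_ms < pe.timestamp_ms - policy.window_ms
            ):
                j += 1
            if (
                j < len(cont_list)
                and abs(cont_list[j].timestamp_ms - pe.timestamp_ms)
                <= policy.window_ms
            ):
                j += 1  # matched: continuous copy kept, past copy dropped
            else:
                past_kept.append(pe)

    merged = sorted(
        list(continuous.events) + past_kept, key=UsageEvent.sort_key
    )

    _warn_contradictory_states(merged, policy.window_ms)
    return EventStream(merged, source="merged")


def _warn_contradictory_states(events: list[UsageEvent], window_ms: int) -> None:
    last_on: UsageEvent | None = None
    for e in events:
        if e.type is EventType.SCREEN_ON:
            if (
                last_on is not None
                and e.source != last_on.source
                and e.timestamp_ms - last_on.timestamp_ms > window_ms
            ):
                warnings.warn(
                    "contradictory screen state across sources: two SCREEN_ON "
                    f"at {last_on.timestamp_ms} ({last_on.source}) and "
                    f"{e.timestamp_ms} ({e.source}) with no SCREEN_OFF between; "
                    "both kept",
                    stacklevel=3,
                )
            last_on = e
        elif e.type is EventType.SCREEN_OFF:
            last_on = None
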