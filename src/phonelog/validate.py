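"""Timestamp validation: aligning prompted actions with logged events.

A validator app drives the device through a scripted action sequence and
records the true time of each action; the logger under test records the
same actions through its own listener. Aligning the two streams per
event type — k-th prompt to k-th record, justified because actions are
detected in the order they occur — yields per-event discrepancies
``recorded − prompted`` in milliseconds. These can be *negative*: the
kernel may hand the logger the event before the action itself is
scheduled. The per-type n/mean/SD table of those discrepancies is the
standard report format for this kind of validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .events import EventStream, EventType
from .simulate import PromptRecord, ValidationProtocol

__all__ = [
    "MatchedPair",
    "AlignmentResult",
    "DiscrepancyReport",
    "TypeStats",
    "CountCheck",
    "align_events",
    "discrepancy_stats",
    "verify_counts",
]


@dataclass(frozen=True)
class MatchedPair:
    event_type: EventType
    prompted_ms: int
    recorded_ms: int

    @property
    def diff_ms(self) -> int:
        """Logger minus validator; negative when the logger fired early."""
        return self.recorded_ms - self.prompted_ms


@dataclass
class AlignmentResult:
    pairs: list[MatchedPair] = field(default_factory=list)
    misses: list[PromptRecord] = field(default_factory=list)
    surplus: dict[EventType, int] = field(default_factory=dict)


@dataclass(frozen=True)
class TypeStats:
    event_type: EventType
    n: int
    mean_ms: float
    sd_ms: float | None  # sample SD (n−1); absent when n == 1


@dataclass
class DiscrepancyReport:
    per_type: list[TypeStats] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Table with event types as rows: event, n, mean_ms, sd_ms."""
        return pd.DataFrame(
            [
                (s.event_type.value, s.n, s.mean_ms, s.sd_ms)
                for s in self.per_type
            ],
            columns=["event", "n", "mean_ms", "sd_ms"],
        )

    def stats_for(self, t: EventType) -> TypeStats | None:
        for s in self.per_type:
            if s.event_type is t:
                return s
        return None


def align_events(
    prompted: list[PromptRecord], recorded: EventStream
) -> AlignmentResult:
    """Order-preserving per-type alignment of prompts to recorded events.

    Within each event type the k-th prompt pairs with the k-th recorded
    event. Prompts with no recorded counterpart are misses; recorded
    events beyond the prompt count are surplus (reported, never paired).
    Nearest-neighbor matching is deliberately not the default: in-order
    detection is part of what a passing validation establishes.
    """
    rec_by_type: dict[EventType, list[int]] = {}
    for ev in recorded.events:
        rec_by_type.setdefault(ev.type, []).append(ev.timestamp_ms)

    used: dict[EventType, int] = {t: 0 for t in rec_by_type}
    result = AlignmentResult()
    for p in prompted:
        times = rec_by_type.get(p.event_type, [])
        k = used.get(p.event_type, 0)
        if k < len(times):
            result.pairs.append(MatchedPair(p.event_type, p.prompted_ms, times[k]))
            used[p.event_type] = k + 1
        else:
            result.misses.append(p)
    n_prompted: dict[EventType, int] = {}
    for p in prompted:
        n_prompted[p.event_type] = n_prompted.get(p.event_type, 0) + 1
    for t, times in rec_by_type.items():
        extra = len(times) - n_prompted.get(t, 0)
        if extra > 0:
            result.surplus[t] = extra
    return result


def discrepancy_stats(pairs: list[MatchedPair]) -> DiscrepancyReport:
    """Per-type n, mean and sample SD (n−1 denominator) of ``diff_ms``.

    Types appear as rows in first-seen order. With a single pair of a
    type, the SD is reported as absent rather than zero.
    """
    order: list[EventType] = []
    diffs: dict[EventType, list[int]] = {}
    for p in pairs:
        if p.event_type not in diffs:
            order.append(p.event_type)
            diffs[p.event_type] = []
        diffs[p.event_type].append(p.diff_ms)

    per_type: list[TypeStats] = []
    for t in order:
        d = diffs[t]
        n = len(d)
        mean = sum(d) / n
        if n > 1:
            sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
        else:
            sd = None
        per_type.append(TypeStats(t, n, mean, sd))
    return DiscrepancyReport(per_type)


@dataclass(frozen=True)
class CountCheck:
    event_type: EventType
    expected: int
    observed: int

    @property
    def ok(self) -> bool:
        return self.expected == self.observed


def verify_counts(
    recorded: EventStream, protocol: ValidationProtocol
) -> list[CountCheck]:
    """Observed vs expected event counts for a protocol replay."""
    observed: dict[EventType, int] = {}
    for ev in recorded.events:
        observed[ev.type] = observed.get(ev.type, 0) + 1
    return [
        CountCheck(t, exp, observed.get(t, 0))
        for t, exp in protocol.expected_counts().items()
    ]
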