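"""Behaviorally structured simulation of smartphone usage event streams.

No public corpus of raw usage-logger exports exists, so every downstream
stage (cleaning, sessionization, metrics, validation statistics) is
exercised against simulated streams with known ground truth.

The behavioral model:

* **Pickups.** Self-initiated pickups follow an inhomogeneous Poisson
  process with daily intensity ``daily_pickup_rate`` distributed over the
  24 hours by ``circadian_weights`` (zero inside the sleep window). The
  default rate is 80/day, the figure commonly cited for general-population
  smartphone use. A pickup urge arriving while a session is already open
  is deferred to just after that session ends, so daily counts are
  conserved.
* **Sessions.** Each pickup opens a screen-on→screen-off session with
  log-normal duration; within a session the user switches apps as a
  Markov chain with a constant per-minute switch hazard, apps drawn by
  popularity weight.
* **Notifications.** Apps post notifications as independent Poisson
  processes. During waking hours a notification triggers a pickup with
  probability ``notif_response_prob`` after an exponential latency; the
  triggered session opens on the notifying app. This is what lets the
  trigger classifier be scored against truth.
* **Alarm clock.** Optionally, one fixed-time clock-app session per day —
  the regular daily marker participants recognize in their own data.

Everything is reproducible from ``(params, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .events import (
    ContextEntry,
    ContextSnapshot,
    EventStream,
    EventType,
    UsageEvent,
)

__all__ = [
    "BehaviorParams",
    "ArtifactParams",
    "GroundTruth",
    "TrueSession",
    "AppInterval",
    "ValidationProtocol",
    "PromptRecord",
    "DEFAULT_APPS",
    "SIM_EPOCH_MS",
    "simulate_usage_log",
    "inject_artifacts",
    "derive_past_view",
    "simulate_validation_protocol",
    "simulate_context",
    "default_circadian_weights",
]

MS_PER_DAY = 86_400_000
MS_PER_HOUR = 3_600_000

#: Simulation origin: a Monday 00:00 UTC, so week windows start cleanly.
SIM_EPOCH_MS = 1_609_718_400_000  # 2021-01-04T00:00:00Z

#: Default app repertoire: (reverse-domain id, popularity weight).
DEFAULT_APPS: tuple[tuple[str, float], ...] = (
    ("com.whatsapp", 0.30),
    ("com.instagram.android", 0.18),
    ("com.zhiliaoapp.musically", 0.14),
    ("com.google.android.youtube", 0.12),
    ("com.android.chrome", 0.10),
    ("com.google.android.gm", 0.07),
    ("com.spotify.music", 0.05),
    ("com.android.vending", 0.04),
)

CLOCK_APP = "com.android.deskclock"

_PAST_DEFAULT_TYPES = frozenset(
    {
        EventType.SCREEN_ON,
        EventType.SCREEN_OFF,
        EventType.APP_FOREGROUND,
        EventType.APP_BACKGROUND,
        EventType.DEVICE_BOOT,
        EventType.DEVICE_SHUTDOWN,
        EventType.CONFIG_CHANGE,
        EventType.FLUSH_TO_DISK,
    }
)


def default_circadian_weights(sleep_window: tuple[int, int] = (23, 7)) -> np.ndarray:
    """Hourly activity weights: zero while asleep, peaked morning/lunch/evening."""
    base = np.array(
        [0.0] * 24, dtype=float
    )
    shape = {
        7: 0.5, 8: 0.9, 9: 0.8, 10: 0.7, 11: 0.7, 12: 1.0, 13: 0.9,
        14: 0.7, 15: 0.7, 16: 0.8, 17: 1.0, 18: 1.1, 19: 1.2, 20: 1.3,
        21: 1.2, 22: 0.8, 23: 0.3, 0: 0.1,
    }
    for h, w in shape.items():
        base[h] = w
    for h in _hours_in_window(sleep_window):
        base[h] = 0.0
    total = base.sum()
    if total <= 0:
        raise ValueError("sleep window leaves no waking hours")
    return base / total


def _hours_in_window(window: tuple[int, int]) -> list[int]:
    start, end = window
    if start == end:
        return []
    if start < end:
        return list(range(start, end))
    return list(range(start, 24)) + list(range(0, end))


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the generative usage model. Rates are per day."""

    n_days: int = 30
    daily_pickup_rate: float = 80.0
    circadian_weights: tuple[float, ...] | None = None
    sleep_window: tuple[int, int] = (23, 7)
    session_mu: float = math.log(30.0)  # log-seconds; median 30 s
    session_sigma: float = 1.0
    app_repertoire: tuple[tuple[str, float], ...] = DEFAULT_APPS
    switch_hazard: float = 0.25  # per-minute in-session app-switch probability
    notification_rate: float = 5.0  # per app per day
    notif_response_prob: float = 0.25
    notif_response_latency_mean_s: float = 10.0
    alarm_time: tuple[int, int] | None = None  # (hour, minute) or absent
    system_noise_rate: float = 5.0  # CONFIG_CHANGE/FLUSH_TO_DISK rows per day
    start_ms: int = SIM_EPOCH_MS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.daily_pickup_rate < 0 or self.notification_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.notif_response_prob <= 1.0:
            raise ValueError("notif_response_prob must be in [0, 1]")
        if not self.app_repertoire:
            raise ValueError("app_repertoire must be non-empty")

    def weights(self) -> np.ndarray:
        if self.circadian_weights is not None:
            w = np.asarray(self.circadian_weights, dtype=float)
            if w.shape != (24,) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("circadian_weights must be 24 non-negative values")
            w = w.copy()
            for h in _hours_in_window(self.sleep_window):
                w[h] = 0.0
            return w / w.sum()
        return default_circadian_weights(self.sleep_window)


@dataclass(frozen=True)
class ArtifactParams:
    """Logging artifacts layered onto a clean stream.

    * ``duplicate_prob`` — probability a row is double-logged a few
      milliseconds later, the double-count defect retrospective OS
      extractions are prone to.
    * ``clock_on_prob`` — per-night probability the clock app stays
      foregrounded across the sleep window (screen set to stay on while
      charging), producing an idle multi-hour episode.
    * ``restart_rate`` — device restarts per day (shutdown/boot pairs).
    * ``dropout_windows`` — (start_ms, end_ms) spans where continuous
      logging was paused (app force-closed, permission revoked).
    """

    duplicate_prob: float = 0.0  # every defect is opt-in; defaults are identity
    duplicate_gap_ms_max: int = 10
    clock_on_prob: float = 0.0
    restart_rate: float = 0.0
    dropout_windows: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.duplicate_prob, self.clock_on_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not 1 <= self.duplicate_gap_ms_max <= 10:
            raise ValueError("duplicate gap must be within a few (<=10) milliseconds")


@dataclass(frozen=True)
class TrueSession:
    start_ms: int
    end_ms: int
    trigger: str  # "notification" | "self"
    notification_index: int | None = None
    trigger_app: str | None = None

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class AppInterval:
    app_id: str
    start_ms: int
    end_ms: int


@dataclass
class GroundTruth:
    """Simulator bookkeeping: the oracle downstream metrics are scored against."""

    true_sessions: list[TrueSession] = field(default_factory=list)
    true_app_intervals: list[AppInterval] = field(default_factory=list)
    injected_duplicates: list[UsageEvent] = field(default_factory=list)
    injected_clock_nights: list[tuple[int, int]] = field(default_factory=list)

    def sessions_per_day(self, n_days: int, trigger: str | None = None) -> float:
        sessions = [
            s for s in self.true_sessions if trigger is None or s.trigger == trigger
        ]
        return len(sessions) / n_days


def _inhomogeneous_poisson_times(
    rng: np.random.Generator,
    n_days: int,
    daily_rate: float,
    hourly_weights: np.ndarray,
    start_ms: int,
) -> np.ndarray:
    """Arrival times (ms) for intensity daily_rate × weights, by thinning."""
    if daily_rate <= 0:
        return np.array([], dtype=np.int64)
    lam_hour = daily_rate * hourly_weights  # expected arrivals per hour-of-day
    lam_max = lam_hour.max()
    horizon_h = n_days * 24
    n_cand = rng.poisson(lam_max * horizon_h)
    t_h = np.sort(rng.uniform(0, horizon_h, size=n_cand))
    hour_of_day = (t_h % 24).astype(int)
    keep = rng.uniform(0, lam_max, size=n_cand) < lam_hour[hour_of_day]
    return (start_ms + (t_h[keep] * MS_PER_HOUR)).astype(np.int64)


def simulate_usage_log(params: BehaviorParams) -> tuple[EventStream, GroundTruth]:
    """Generate a continuous-logging event stream and its ground truth.

    Returns a validated, time-sorted stream containing screen, app,
    notification and system events, together with the true session list
    (with trigger labels) and the true per-app foreground intervals that
    tile each session.
    """
    if params.n_days <= 0:
        raise ValueError("n_days must be positive")
    rng = np.random.default_rng(params.seed)
    weights = params.weights()
    t0 = params.start_ms
    t_end = t0 + params.n_days * MS_PER_DAY

    apps = [a for a, _ in params.app_repertoire]
    app_w = np.array([w for _, w in params.app_repertoire], dtype=float)
    app_w = app_w / app_w.sum()

    # --- candidate pickups ---------------------------------------------
    self_times = _inhomogeneous_poisson_times(
        rng, params.n_days, params.daily_pickup_rate, weights, t0
    )
    candidates: list[tuple[int, str, int | None, str | None]] = [
        (int(t), "self", None, None) for t in self_times
    ]

    # --- notifications --------------------------------------------------
    # Per-app homogeneous Poisson; enforce >=2 s spacing per app so that
    # genuine repeats can never masquerade as double-count artifacts.
    notifications: list[tuple[int, str]] = []  # (t_ms, app)
    for app, _w in params.app_repertoire:
        n = rng.poisson(params.notification_rate * params.n_days)
        times = np.sort(rng.uniform(t0, t_end, size=n).astype(np.int64))
        prev = -10_000
        for t in times:
            t = int(max(t, prev + 2000))
            if t >= t_end:
                break
            notifications.append((t, app))
            prev = t
    notifications.sort()

    waking_hours = set(range(24)) - set(_hours_in_window(params.sleep_window))
    for idx, (t_notif, app) in enumerate(notifications):
        hour = int((t_notif - t0) % MS_PER_DAY // MS_PER_HOUR)
        if hour not in waking_hours:
            continue  # asleep: notification unanswered
        if rng.uniform() < params.notif_response_prob:
            latency_ms = int(
                rng.exponential(params.notif_response_latency_mean_s) * 1000
            ) + 500
            candidates.append((t_notif + latency_ms, "notification", idx, app))

    # --- alarm-clock sessions -------------------------------------------
    if params.alarm_time is not None:
        h, m = params.alarm_time
        for d in range(params.n_days):
            t = t0 + d * MS_PER_DAY + h * MS_PER_HOUR + m * 60_000
            candidates.append((t, "alarm", None, CLOCK_APP))

    candidates.sort(key=lambda c: c[0])

    # --- realize sessions (non-overlapping by construction) -------------
    refractory_ms = 1000
    sessions: list[TrueSession] = []
    intervals: list[AppInterval] = []
    current_end = -(10**18)
    for t, trigger, notif_idx, first_app in candidates:
        if t < current_end + refractory_ms:
            if trigger == "notification":
                continue  # phone already in hand; no separate pickup
            t = current_end + refractory_ms + int(rng.integers(0, 2000))
        if t >= t_end:
            continue
        dur_ms = int(rng.lognormal(params.session_mu, params.session_sigma) * 1000)
        dur_ms = max(dur_ms, 2000)
        end = min(t + dur_ms, t_end - 1)
        if end <= t:
            continue
        label = "notification" if trigger == "notification" else "self"
        # app chain tiling [t, end)
        chain: list[AppInterval] = []
        pos = t
        app = first_app if first_app is not None else apps[rng.choice(len(apps), p=app_w)]
        while pos < end:
            gap_ms = int(rng.exponential(60.0 / max(params.switch_hazard, 1e-9)) * 1000)
            gap_ms = max(gap_ms, 1000)
            nxt = min(pos + gap_ms, end)
            chain.append(AppInterval(app, pos, nxt))
            pos = nxt
            if pos < end:
                others = [a for a in apps if a != app] or apps
                app = others[int(rng.integers(len(others)))]
        sessions.append(
            TrueSession(t, end, label, notif_idx, chain[0].app_id if chain else None)
        )
        intervals.extend(chain)
        current_end = end

    # --- emit events -----------------------------------------------------
    events: list[UsageEvent] = [UsageEvent(t0, EventType.DEVICE_BOOT)]
    for s in sessions:
        events.append(UsageEvent(s.start_ms, EventType.SCREEN_ON))
        events.append(UsageEvent(s.end_ms, EventType.SCREEN_OFF))
    for iv in intervals:
        events.append(UsageEvent(iv.start_ms, EventType.APP_FOREGROUND, iv.app_id))

    session_by_notif = {
        s.notification_index: s for s in sessions if s.notification_index is not None
    }
    for idx, (t_notif, app) in enumerate(notifications):
        events.append(UsageEvent(t_notif, EventType.NOTIFICATION_POSTED, app))
        if idx in session_by_notif:
            t_rm = session_by_notif[idx].start_ms + int(rng.integers(1000, 5000))
        else:
            t_rm = t_notif + int(rng.integers(60_000, 3_600_000))
        if t_rm < t_end:
            events.append(UsageEvent(t_rm, EventType.NOTIFICATION_REMOVED, app))

    # System housekeeping rows; spaced >=500 ms apart per type so genuine
    # repeats stay distinguishable from injected double-count artifacts.
    n_noise = rng.poisson(params.system_noise_rate * params.n_days)
    noise_last: dict[EventType, int] = {}
    for t in np.sort(rng.uniform(t0, t_end, size=n_noise).astype(np.int64)):
        kind = (
            EventType.FLUSH_TO_DISK
            if rng.uniform() < 0.8
            else EventType.CONFIG_CHANGE
        )
        t = int(max(t, noise_last.get(kind, -(10**18)) + 500))
        if t >= t_end:
            continue
        noise_last[kind] = t
        events.append(UsageEvent(t, kind))

    events.sort(key=UsageEvent.sort_key)
    truth = GroundTruth(true_sessions=sessions, true_app_intervals=intervals)
    return EventStream(events, source="continuous"), truth


def inject_artifacts(
    stream: EventStream, truth: GroundTruth, params: ArtifactParams
) -> EventStream:
    """Layer logging defects onto a clean stream; ground truth is unchanged
    except for artifact bookkeeping (which the cleaning oracle reads).

    Duplicates land 1..duplicate_gap_ms_max ms after their originals;
    clock-on nights insert a clock-app foreground spanning each night's
    sleep window (closed by an APP_BACKGROUND); restarts insert
    shutdown/boot pairs; dropout windows delete the events inside them.
    """
    rng = np.random.default_rng(params.seed)
    out: list[UsageEvent] = []
    duplicates: list[UsageEvent] = []
    for ev in stream.events:
        out.append(ev)
        if params.duplicate_prob > 0 and rng.uniform() < params.duplicate_prob:
            gap = int(rng.integers(1, params.duplicate_gap_ms_max + 1))
            dup = replace(ev, timestamp_ms=ev.timestamp_ms + gap)
            out.append(dup)
            duplicates.append(dup)

    if params.clock_on_prob > 0 and stream.events:
        t0 = stream.events[0].timestamp_ms
        t_last = stream.events[-1].timestamp_ms
        n_days = max(1, math.ceil((t_last - t0) / MS_PER_DAY))
        for d in range(n_days):
            if rng.uniform() < params.clock_on_prob:
                night_start = t0 + d * MS_PER_DAY + 23 * MS_PER_HOUR
                night_end = night_start + 8 * MS_PER_HOUR
                if night_end > t_last:
                    continue
                out.append(
                    UsageEvent(night_start, EventType.APP_FOREGROUND, CLOCK_APP)
                )
                out.append(
                    UsageEvent(night_end, EventType.APP_BACKGROUND, CLOCK_APP)
                )
                truth.injected_clock_nights.append((night_start, night_end))

    if params.restart_rate > 0 and stream.events:
        t0 = stream.events[0].timestamp_ms
        t_last = stream.events[-1].timestamp_ms
        span_days = (t_last - t0) / MS_PER_DAY
        n_restarts = rng.poisson(params.restart_rate * span_days)
        for t in rng.uniform(t0, t_last, size=n_restarts).astype(np.int64):
            out.append(UsageEvent(int(t), EventType.DEVICE_SHUTDOWN))
            out.append(UsageEvent(int(t) + 30_000, EventType.DEVICE_BOOT))

    if params.dropout_windows:
        out = [
            ev
            for ev in out
            if not any(a <= ev.timestamp_ms < b for a, b in params.dropout_windows)
        ]

    truth.injected_duplicates.extend(duplicates)
    out.sort(key=UsageEvent.sort_key)
    return EventStream(out, source=stream.source)


def derive_past_view(
    stream: EventStream,
    retention_days: int = 5,
    keep_types: frozenset[EventType] | set[EventType] = _PAST_DEFAULT_TYPES,
) -> EventStream:
    """Project a continuous stream into what the OS history would return.

    The device's retrospective usage database keeps only the recent past
    — here the running partial day plus the trailing ``retention_days``
    complete days, measured from the last event — and only screen, app
    and system lifecycle rows (notification and install events are not
    part of the history). Events are relabeled ``source="past"``.

    Idempotent: re-deriving with the same arguments is a no-op.
    """
    if retention_days <= 0:
        raise ValueError("retention_days must be positive")
    if not stream.events:
        return EventStream([], source="past")
    t_last = stream.events[-1].timestamp_ms
    day_floor = (t_last // MS_PER_DAY) * MS_PER_DAY
    cutoff = day_floor - retention_days * MS_PER_DAY
    kept = [
        replace(ev, source="past")
        for ev in stream.events
        if ev.type in keep_types and ev.timestamp_ms >= cutoff
    ]
    return EventStream(kept, source="past")


# ---------------------------------------------------------------------------
# Validation-protocol replay
# ---------------------------------------------------------------------------

VALIDATOR_APP = "org.example.validator.target"


@dataclass(frozen=True)
class PromptRecord:
    """One action the validator app prompted, with its true timestamp."""

    index: int
    event_type: EventType
    prompted_ms: int
    app_id: str | None = None


@dataclass(frozen=True)
class ValidationProtocol:
    """The scripted action sequence a validator app drives on-device.

    Defaults mirror the standard protocol: 20 screen toggles (10 on / 10
    off, strictly alternating), 2 installs and 2 uninstalls of an
    identical app, 10 notifications posted and removed (interleaved
    post/remove pairs), and 20 opens of a fresh app. Inter-action gaps
    default to an exponential 5 s. The jitter model is per event type,
    normal(bias_ms, sd_ms) and sign-unrestricted: the logger can time-
    stamp an action *before* it happens, an artifact of kernel event
    scheduling.
    """

    n_screen_toggles: int = 20
    n_installs: int = 2
    n_uninstalls: int = 2
    n_notifications: int = 10
    n_app_opens: int = 20
    gap_mean_s: float = 5.0
    jitter: tuple[tuple[EventType, float, float], ...] = ()
    default_bias_ms: float = 0.0
    default_sd_ms: float = 500.0
    start_ms: int = SIM_EPOCH_MS

    def __post_init__(self) -> None:
        for n in (
            self.n_screen_toggles,
            self.n_installs,
            self.n_uninstalls,
            self.n_notifications,
            self.n_app_opens,
        ):
            if n < 0:
                raise ValueError("protocol counts must be non-negative")

    def jitter_for(self, t: EventType) -> tuple[float, float]:
        for et, bias, sd in self.jitter:
            if et is t:
                return bias, sd
        return self.default_bias_ms, self.default_sd_ms

    def expected_counts(self) -> dict[EventType, int]:
        on = (self.n_screen_toggles + 1) // 2
        off = self.n_screen_toggles // 2
        return {
            EventType.SCREEN_ON: on,
            EventType.SCREEN_OFF: off,
            EventType.APP_INSTALLED: self.n_installs,
            EventType.APP_UNINSTALLED: self.n_uninstalls,
            EventType.NOTIFICATION_POSTED: self.n_notifications,
            EventType.NOTIFICATION_REMOVED: self.n_notifications,
            EventType.APP_FOREGROUND: self.n_app_opens,
        }


def simulate_validation_protocol(
    protocol: ValidationProtocol, seed: int = 0
) -> tuple[list[PromptRecord], EventStream]:
    """Replay the validator protocol: prompted actions plus the jittered
    stream a logger would have recorded.

    Prompted actions are emitted in protocol order; the recorded stream
    holds exactly one event per prompt at ``prompted + jitter`` (jitter
    may be negative). Prompt/record correspondence is by order within
    each event type.
    """
    rng = np.random.default_rng(seed)
    prompts: list[PromptRecord] = []
    t = protocol.start_ms

    def advance() -> int:
        nonlocal t
        t += max(500, int(rng.exponential(protocol.gap_mean_s) * 1000))
        return t

    seq: list[tuple[EventType, str | None]] = []
    for i in range(protocol.n_screen_toggles):
        seq.append((EventType.SCREEN_ON if i % 2 == 0 else EventType.SCREEN_OFF, None))
    for _ in range(protocol.n_installs):
        seq.append((EventType.APP_INSTALLED, VALIDATOR_APP))
    for _ in range(protocol.n_uninstalls):
        seq.append((EventType.APP_UNINSTALLED, VALIDATOR_APP))
    for _ in range(protocol.n_notifications):
        seq.append((EventType.NOTIFICATION_POSTED, VALIDATOR_APP))
        seq.append((EventType.NOTIFICATION_REMOVED, VALIDATOR_APP))
    for _ in range(protocol.n_app_opens):
        seq.append((EventType.APP_FOREGROUND, VALIDATOR_APP))

    for i, (etype, app) in enumerate(seq):
        prompts.append(PromptRecord(i, etype, advance(), app))

    recorded: list[UsageEvent] = []
    for p in prompts:
        bias, sd = protocol.jitter_for(p.event_type)
        jitter = int(round(rng.normal(bias, sd))) if sd > 0 else int(round(bias))
        recorded.append(
            UsageEvent(p.prompted_ms + jitter, p.event_type, p.app_id)
        )
    recorded.sort(key=UsageEvent.sort_key)
    return prompts, EventStream(recorded, source="continuous")


# ---------------------------------------------------------------------------
# Contextual snapshot
# ---------------------------------------------------------------------------

PERMISSION_VOCABULARY: tuple[str, ...] = (
    "android.permission.CAMERA",
    "android.permission.RECORD_AUDIO",
    "android.permission.ACCESS_FINE_LOCATION",
    "android.permission.ACCESS_COARSE_LOCATION",
    "android.permission.READ_CONTACTS",
    "android.permission.READ_EXTERNAL_STORAGE",
    "android.permission.WRITE_EXTERNAL_STORAGE",
    "android.permission.READ_SMS",
    "android.permission.POST_NOTIFICATIONS",
    "android.permission.BLUETOOTH_CONNECT",
)


def simulate_context(
    params: BehaviorParams,
    seed: int = 0,
    permission_vocabulary: Sequence[str] = PERMISSION_VOCABULARY,
) -> ContextSnapshot:
    """One snapshot entry per repertoire app: a random subset of the
    permission vocabulary requested, and a random subset of those granted."""
    rng = np.random.default_rng(seed)
    entries: list[ContextEntry] = []
    vocab = list(permission_vocabulary)
    for app, _w in params.app_repertoire:
        if vocab:
            req_mask = rng.uniform(size=len(vocab)) < 0.5
            requested = tuple(p for p, m in zip(vocab, req_mask) if m)
            grant_mask = rng.uniform(size=len(requested)) < 0.7
            granted = tuple(p for p, m in zip(requested, grant_mask) if m)
        else:
            requested = granted = ()
        entries.append(ContextEntry(app, requested, granted))
    return ContextSnapshot(params.start_ms, entries)
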